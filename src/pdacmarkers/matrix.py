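"""Gene x sample expression matrix container.

The matrix is the common currency of the package: genes as rows, samples as
columns, with an explicit scale flag so that log2-dependent statistics
(pairwise similarity, concordance, cell scores) can refuse linear input
instead of silently producing nonsense.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DuplicateGeneError, MissingGeneError, PdacMarkersError


class Scale(str, Enum):
    LINEAR = "linear"
    LOG2 = "log2"


class GeneClass(str, Enum):
    ENDOGENOUS = "endogenous"
    HOUSEKEEPING = "housekeeping"
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-trimmed, uppercase."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """Expression values for ``gene_ids`` (rows) across ``sample_ids`` (columns).

    Parameters
    ----------
    gene_ids, sample_ids
        Unique identifiers; gene symbols are uppercased and trimmed.
    values
        ``(n_genes, n_samples)`` float array. Linear-scale values must be
        non-negative; log2-scale values must be finite.
    scale
        Whether ``values`` are linear counts/abundances or log2 units.
    gene_class
        Optional probe class per gene (endogenous by default); populated by
        the RCC reader and used to build permutation pools and detection
        thresholds.
    groups
        Optional sample -> group-label mapping for group comparisons.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: Scale = Scale.LINEAR
    gene_class: dict[str, GeneClass] = field(default_factory=dict)
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [normalize_symbol(g) for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.scale = Scale(self.scale)
        self.gene_class = {normalize_symbol(g): GeneClass(c) for g, c in self.gene_class.items()}
        self._validate()
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def _validate(self) -> None:
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise DuplicateGeneError(dupes)
        sdupes = _duplicates(self.sample_ids)
        if sdupes:
            raise PdacMarkersError(f"duplicate sample identifiers: {', '.join(sorted(sdupes))}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise PdacMarkersError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise PdacMarkersError("expression values must be finite")
        if self.scale is Scale.LINEAR and np.any(self.values < 0):
            raise PdacMarkersError("linear-scale expression values must be >= 0")
        unknown = set(self.gene_class) - set(self.gene_ids)
        if unknown:
            raise MissingGeneError(f"gene_class refers to absent genes: {', '.join(sorted(unknown))}")
        if self.groups is not None:
            missing = set(self.groups) - set(self.sample_ids)
            if missing:
                raise PdacMarkersError(f"groups refer to absent samples: {', '.join(sorted(missing))}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._index

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        key = normalize_symbol(gene)
        if key not in self._index:
            raise MissingGeneError(f"gene {key!r} not in matrix")
        return self.values[self._index[key]]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        keys = [normalize_symbol(g) for g in genes]
        missing = [g for g in keys if g not in self._index]
        if missing:
            raise MissingGeneError(f"genes not in matrix: {', '.join(missing)}")
        idx = [self._index[g] for g in keys]
        return replace(
            self,
            gene_ids=keys,
            values=self.values[idx],
            gene_class={g: c for g, c in self.gene_class.items() if g in set(keys)},
        )

    def class_of(self, gene: str) -> GeneClass:
        return self.gene_class.get(normalize_symbol(gene), GeneClass.ENDOGENOUS)

    def genes_of_class(self, cls: GeneClass) -> list[str]:
        return [g for g in self.gene_ids if self.class_of(g) is cls]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for it in items:
        if it in seen:
            dupes.add(it)
        seen.add(it)
    return dupes
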