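"""Cell-type scores, relative abundance against CD45+, and group comparison.

A cell score is the per-sample arithmetic mean of the log2 expression of a
cell type's marker genes. To correct for total immune infiltration, scores
are reported relative to a reference cell type (CD45+, the pan-leukocyte
marker PTPRC, by default) — either as a ratio of log2 means (the literal
published convention) or as a log2 difference (the standard log-scale
normalization). Group differences are tested with two-sided Welch t-tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GeneSetCatalog
from .errors import DegenerateInputError, MarkerWarning, PdacMarkersError
from .matrix import ExpressionMatrix, Scale

DEFAULT_REFERENCE = "CD45+"


@dataclass
class CellScoreTable:
    """Per-sample cell-type scores (samples x cell types)."""

    sample_ids: list[str]
    cell_types: list[str]
    scores: np.ndarray
    missing_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.cell_types)):
            raise PdacMarkersError("scores shape does not match (samples, cell types)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=self.cell_types)

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_types.index(cell_type)
        except ValueError:
            raise PdacMarkersError(f"cell type {cell_type!r} not in score table") from None
        return self.scores[:, j]


@dataclass
class RelativeAbundanceTable:
    """Group-level cell scores relative to the reference cell type."""

    group_labels: list[str]
    cell_types: list[str]
    values: np.ndarray
    mode: str
    reference: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_labels, columns=self.cell_types)


@dataclass
class GroupComparisonResult:
    cell_type: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def cell_scores(m: ExpressionMatrix, catalog: GeneSetCatalog) -> CellScoreTable:
    """Average log2 marker expression per sample and cell type.

    Catalog genes absent from the matrix are recorded in ``missing_genes``;
    a cell type with no measured gene is excluded with a warning.
    """
    if m.scale is not Scale.LOG2:
        raise PdacMarkersError("cell scores are defined on log2-scale matrices")
    cell_types: list[str] = []
    cols: list[np.ndarray] = []
    missing: dict[str, list[str]] = {}
    skipped: list[str] = []
    for entry in catalog:
        present = [g for g in entry.genes if g in m]
        absent = [g for g in entry.genes if g not in m]
        if absent:
            missing[entry.name] = absent
        if not present:
            skipped.append(entry.name)
            continue
        cell_types.append(entry.name)
        cols.append(m.subset_genes(present).values.mean(axis=0))
    if skipped:
        warnings.warn(
            f"cell types with no measured marker excluded from scores: {', '.join(skipped)}",
            MarkerWarning,
            stacklevel=2,
        )
    if not cell_types:
        raise PdacMarkersError("no catalog cell type has any gene in the matrix")
    return CellScoreTable(
        sample_ids=list(m.sample_ids),
        cell_types=cell_types,
        scores=np.column_stack(cols),
        missing_genes=missing,
    )


def relative_scores(
    t: CellScoreTable, reference: str = DEFAULT_REFERENCE, mode: str = "ratio"
) -> CellScoreTable:
    """Per-sample scores relative to the reference cell type.

    ratio mode divides each score by the sample's reference score; log_diff
    subtracts it. These per-sample values feed the group t-tests.
    """
    _check_mode(mode)
    ref = t.column(reference)
    if mode == "ratio" and np.any(ref == 0.0):
        raise DegenerateInputError(f"reference {reference!r} score is 0 for some sample; use log_diff")
    rel = t.scores / ref[:, None] if mode == "ratio" else t.scores - ref[:, None]
    return CellScoreTable(
        sample_ids=list(t.sample_ids),
        cell_types=list(t.cell_types),
        scores=rel,
        missing_genes=dict(t.missing_genes),
    )


def relative_abundance(
    t: CellScoreTable,
    groups: dict[str, str],
    reference: str = DEFAULT_REFERENCE,
    mode: str = "ratio",
) -> RelativeAbundanceTable:
    """Group-mean cell score relative to the group-mean reference score."""
    _check_mode(mode)
    labels = _group_labels(t, groups)
    ref = t.column(reference)
    values = np.empty((len(labels), len(t.cell_types)))
    for i, label in enumerate(labels):
        mask = np.array([groups[s] == label for s in t.sample_ids])
        group_means = t.scores[mask].mean(axis=0)
        ref_mean = ref[mask].mean()
        if mode == "ratio":
            if ref_mean == 0.0:
                raise DegenerateInputError(f"group {label!r} has zero mean reference score")
            values[i] = group_means / ref_mean
        else:
            values[i] = group_means - ref_mean
    return RelativeAbundanceTable(
        group_labels=labels, cell_types=list(t.cell_types), values=values, mode=mode, reference=reference
    )


def compare_groups(
    t: CellScoreTable, groups: dict[str, str], baseline_group: str
) -> list[GroupComparisonResult]:
    """Two-sided Welch t-tests of each group's scores against the baseline.

    Returns one result per (cell type, non-baseline group). Identical
    zero-variance groups with equal means report t=0, p=1 by convention.
    """
    labels = _group_labels(t, groups)
    if baseline_group not in labels:
        raise PdacMarkersError(f"baseline group {baseline_group!r} not among groups {labels}")
    masks = {
        label: np.array([groups[s] == label for s in t.sample_ids], dtype=bool) for label in labels
    }
    for label, mask in masks.items():
        if mask.sum() < 2:
            raise PdacMarkersError(f"group {label!r} has fewer than 2 samples")
    results: list[GroupComparisonResult] = []
    base = masks[baseline_group]
    for j, cell_type in enumerate(t.cell_types):
        b = t.scores[base, j]
        for label in labels:
            if label == baseline_group:
                continue
            a = t.scores[masks[label], j]
            if np.var(a) == 0.0 and np.var(b) == 0.0:
                if a.mean() == b.mean():
                    tstat, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
                else:
                    tstat = np.inf if a.mean() > b.mean() else -np.inf
                    df, p = float(len(a) + len(b) - 2), 0.0
            else:
                res = stats.ttest_ind(a, b, equal_var=False)
                tstat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
            results.append(
                GroupComparisonResult(
                    cell_type=cell_type,
                    group_a=label,
                    group_b=baseline_group,
                    mean_a=float(a.mean()),
                    mean_b=float(b.mean()),
                    t_statistic=tstat,
                    degrees_of_freedom=df,
                    p_value=p,
                )
            )
    return results


def comparison_table(results: list[GroupComparisonResult], adjust: bool = False) -> pd.DataFrame:
    """Tabulate comparisons; optional Benjamini-Hochberg column (off by default)."""
    df = pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "group": r.group_a,
                "baseline": r.group_b,
                "mean_group": r.mean_a,
                "mean_baseline": r.mean_b,
                "t_statistic": r.t_statistic,
                "df": r.degrees_of_freedom,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
    if adjust and len(df):
        df["p_adjusted"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _check_mode(mode: str) -> None:
    if mode not in ("ratio", "log_diff"):
        raise PdacMarkersError(f"unknown relative-abundance mode {mode!r}")


def _group_labels(t: CellScoreTable, groups: dict[str, str]) -> list[str]:
    unlabelled = [s for s in t.sample_ids if s not in groups]
    if unlabelled:
        raise PdacMarkersError(f"samples without a group label: {', '.join(unlabelled)}")
    seen: dict[str, None] = {}
    for s in t.sample_ids:
        seen.setdefault(groups[s])
    return list(seen)
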