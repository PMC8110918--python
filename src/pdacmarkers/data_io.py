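"""Reading, writing and preprocessing of expression matrices.

Covers plain TSV/CSV matrices, NanoString RCC files (one sample per file),
the log2 transform, a housekeeping-geometric-mean normalization in the
spirit of nSolver (documented approximation, not a parity implementation),
and the above-background detection filter.
"""
from __future__ import annotations

import csv
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateGeneError,
    MarkerWarning,
    MissingGeneError,
    ParseError,
    PdacMarkersError,
    ScaleError,
)
from .matrix import ExpressionMatrix, GeneClass, Scale, normalize_symbol

# -- plain matrices ------------------------------------------------------------


def read_expression(path, dialect: str = "tsv", scale: Scale | str = Scale.LINEAR) -> ExpressionMatrix:
    """Read a gene x sample matrix: first column gene symbols, header samples.

    Non-numeric body cells and duplicate gene symbols are hard errors with
    the offending position/symbols named.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise PdacMarkersError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    # keep_default_na: "NA" etc. must surface as parse errors, never as NaN
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    genes = [normalize_symbol(g) for g in df.index]
    counts = pd.Series(genes).value_counts()
    dupes = set(counts[counts > 1].index)
    if dupes:
        raise DuplicateGeneError(dupes)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # slow path only to name the offending cell
        for gene, row in zip(genes, df.itertuples(index=False)):
            for col, cell in zip(df.columns, row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric value {cell!r} at gene {gene!r}, sample {col!r}"
                    ) from None
        raise
    return ExpressionMatrix(
        gene_ids=genes, sample_ids=list(df.columns), values=values, scale=Scale(scale)
    )


def write_expression(m: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = m.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep=sep)


# -- NanoString RCC ------------------------------------------------------------

_RCC_CLASS = {
    "endogenous": GeneClass.ENDOGENOUS,
    "housekeeping": GeneClass.HOUSEKEEPING,
    "positive": GeneClass.POSITIVE_CONTROL,
    "negative": GeneClass.NEGATIVE_CONTROL,
}


def _parse_rcc(path) -> tuple[str, list[tuple[str, GeneClass, float]]]:
    """Parse one RCC file into (sample id, [(gene, class, count), ...])."""
    sections: dict[str, list[list[str]]] = {}
    current: str | None = None
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh), start=1):
            if not raw or not any(f.strip() for f in raw):
                continue
            head = raw[0].strip()
            if head.startswith("<") and head.endswith(">"):
                tag = head.strip("<>").strip()
                if tag.startswith("/"):
                    current = None
                else:
                    current = tag
                    sections.setdefault(current, [])
                continue
            if current is not None:
                sections[current].append([f.strip() for f in raw])
    if "Code_Summary" not in sections:
        raise ParseError(f"{path}: RCC file has no Code_Summary section")
    sample_id = None
    for row in sections.get("Sample_Attributes", []):
        if row and row[0].lower() == "id" and len(row) > 1:
            sample_id = row[1]
    if not sample_id:
        raise ParseError(f"{path}: Sample_Attributes section has no ID field")
    rows = sections["Code_Summary"]
    if not rows or [c.lower() for c in rows[0][:4]] != ["codeclass", "name", "accession", "count"]:
        raise ParseError(f"{path}: Code_Summary header must be CodeClass,Name,Accession,Count")
    records = []
    for row in rows[1:]:
        if len(row) < 4:
            raise ParseError(f"{path}: malformed Code_Summary row {row!r}")
        cls = _RCC_CLASS.get(row[0].lower())
        if cls is None:
            raise ParseError(f"{path}: unknown CodeClass {row[0]!r}")
        try:
            count = float(row[3])
        except ValueError:
            raise ParseError(f"{path}: non-numeric count {row[3]!r} for probe {row[1]!r}") from None
        records.append((normalize_symbol(row[1]), cls, count))
    return sample_id, records


def read_rcc(paths: Sequence) -> ExpressionMatrix:
    """Merge per-sample RCC files into one linear-scale ExpressionMatrix.

    All files must share an identical probe panel (same genes in the same
    classes); gene_class is populated from the CodeClass column.
    """
    if not paths:
        raise PdacMarkersError("read_rcc needs at least one file")
    sample_ids: list[str] = []
    panel: list[tuple[str, GeneClass]] | None = None
    columns: list[list[float]] = []
    for path in paths:
        sample_id, records = _parse_rcc(path)
        this_panel = [(g, c) for g, c, _ in records]
        if panel is None:
            panel = this_panel
        elif this_panel != panel:
            raise ParseError(f"{path}: probe panel differs from {paths[0]}")
        sample_ids.append(sample_id)
        columns.append([count for _, _, count in records])
    assert panel is not None
    return ExpressionMatrix(
        gene_ids=[g for g, _ in panel],
        sample_ids=sample_ids,
        values=np.array(columns, dtype=float).T,
        scale=Scale.LINEAR,
        gene_class={g: c for g, c in panel},
    )


# -- transforms and filters ----------------------------------------------------


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return a log2(x + offset) copy of a linear-scale matrix.

    Refuses matrices already on the log2 scale so a pipeline cannot silently
    double-transform.
    """
    if m.scale is not Scale.LINEAR:
        raise ScaleError("matrix is already log2-scale; refusing a second transform")
    if offset < 0:
        raise PdacMarkersError("offset must be >= 0")
    values = np.log2(m.values + offset)
    if not np.all(np.isfinite(values)):
        raise PdacMarkersError("log2 transform produced non-finite values (zero value with offset 0?)")
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=values,
        scale=Scale.LOG2,
        gene_class=dict(m.gene_class),
        groups=dict(m.groups) if m.groups else None,
    )


def normalize_housekeeping(m: ExpressionMatrix, hk_genes: Iterable[str]) -> ExpressionMatrix:
    """Scale each sample by housekeeping content (geometric-mean method).

    Per sample, the geometric mean of the housekeeping genes is computed;
    each sample is multiplied by (arithmetic mean across samples of those
    geometric means) / (its own geometric mean). Housekeeping-stable samples
    are left nearly unchanged.
    """
    if m.scale is not Scale.LINEAR:
        raise ScaleError("housekeeping normalization applies to linear-scale matrices")
    hk = [normalize_symbol(g) for g in hk_genes]
    missing = [g for g in hk if g not in m]
    if missing:
        raise MissingGeneError(f"housekeeping genes absent from matrix: {', '.join(missing)}")
    sub = m.subset_genes(hk).values
    if np.any(sub <= 0):
        raise PdacMarkersError("housekeeping genes must be strictly positive in every sample")
    geo = np.exp(np.mean(np.log(sub), axis=0))
    factors = geo.mean() / geo
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=m.values * factors[None, :],
        scale=Scale.LINEAR,
        gene_class=dict(m.gene_class),
        groups=dict(m.groups) if m.groups else None,
    )


def negative_control_threshold(m: ExpressionMatrix, n_sd: float = 2.0) -> float:
    """Background detection threshold: mean + n_sd * SD of negative controls."""
    neg = m.genes_of_class(GeneClass.NEGATIVE_CONTROL)
    if not neg:
        raise MissingGeneError("matrix has no negative-control genes; supply a threshold explicitly")
    vals = m.subset_genes(neg).values
    return float(vals.mean() + n_sd * vals.std(ddof=1))


def detection_filter(
    m: ExpressionMatrix, threshold: float, min_fraction: float = 0.5
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes above ``threshold`` in at least ``min_fraction`` of samples.

    The boundary is inclusive on the fraction: a gene detected in exactly
    half the samples passes ``min_fraction=0.5``. ``threshold`` must be on
    the same scale as the matrix. Returns (filtered matrix, dropped genes).
    """
    if not 0 < min_fraction <= 1:
        raise PdacMarkersError("min_fraction must be in (0, 1]")
    detected = (m.values > threshold).mean(axis=1)
    keep = detected >= min_fraction
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    kept = [g for g, k in zip(m.gene_ids, keep) if k]
    if not kept:
        raise PdacMarkersError("detection filter removed every gene; threshold too high?")
    return m.subset_genes(kept), dropped


def intersect_catalog(m: ExpressionMatrix, catalog) -> "tuple":
    """Restrict a catalog to genes present in the matrix.

    Returns (restricted catalog, mapping cell type -> absent genes). Cell
    types with no measured gene are dropped with a warning, mirroring the
    panel's unmeasured (asterisked) genes.
    """
    from .catalog import CellTypeDef, GeneSetCatalog

    entries = []
    missing: dict[str, list[str]] = {}
    for e in catalog:
        absent = [g for g in e.genes if g not in m]
        present = [g for g in e.genes if g in m]
        if absent:
            missing[e.name] = absent
        if present:
            entries.append(
                CellTypeDef(
                    name=e.name,
                    genes=present,
                    parent=e.parent if any(x.name == e.parent for x in entries) else None,
                    source=e.source,
                    provenance={g: p for g, p in e.provenance.items() if g in set(present)},
                )
            )
    if missing:
        detail = "; ".join(f"{ct}: {', '.join(gs)}" for ct, gs in missing.items())
        warnings.warn(f"catalog genes absent from matrix — {detail}", MarkerWarning, stacklevel=2)
    return GeneSetCatalog(entries, catalog_name=catalog.catalog_name, version=catalog.version), missing
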