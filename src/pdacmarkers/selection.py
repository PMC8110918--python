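"""Marker-gene selection by pairwise-similarity thresholding.

Candidates for each cell type are filtered so that the retained genes form
a mutually similar block (threshold 0.6 by default). Two aggregation modes
are provided, because a pairwise threshold alone does not determine a
per-gene keep/drop rule:

``prune_mean`` (default)
    Iteratively remove the gene with the lowest mean off-diagonal
    similarity to the other remaining candidates until every remaining
    gene's mean similarity meets the threshold (or fewer than 2 remain).
``all_pairs``
    Largest candidate subset in which *every pair* meets the threshold
    (maximum clique in the thresholded similarity graph); ties broken by
    higher mean similarity, then lexicographically.

Cell types whose catalog lists a single candidate pass through flagged
``single_gene`` — retained but low-confidence, as for NK cells or
Helper 1 T cells, whose definitions rest on one marker.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

import numpy as np
import pandas as pd

from .catalog import CellTypeDef, GeneSetCatalog
from .data_io import intersect_catalog
from .errors import PdacMarkersError
from .matrix import ExpressionMatrix, Scale
from .similarity import SimilarityMatrix, mean_pairwise_similarity, similarity_matrix


class SelectionStatus(str, Enum):
    OK = "ok"
    SINGLE_GENE = "single_gene"
    EMPTY = "empty"
    DEGENERATE = "degenerate"


@dataclass
class SelectionResult:
    """Outcome of marker selection for one cell type."""

    cell_type: str
    candidates: list[str]
    selected: list[str]
    per_gene_mean_similarity: dict[str, float] = field(default_factory=dict)
    set_mean_similarity: float | None = None
    status: SelectionStatus = SelectionStatus.OK
    missing: list[str] = field(default_factory=list)


def _off_diagonal_means(S: np.ndarray) -> np.ndarray:
    k = S.shape[0]
    return (S.sum(axis=1) - np.diag(S)) / (k - 1)


def _prune_mean(sm: SimilarityMatrix, threshold: float) -> tuple[list[str], dict[str, float]]:
    genes = list(sm.genes)
    S = sm.S.copy()
    removal_means: dict[str, float] = {}
    while len(genes) >= 2:
        means = _off_diagonal_means(S)
        if np.all(means >= threshold):
            return genes, {**removal_means, **dict(zip(genes, means))}
        # drop the weakest gene; ties resolved lexicographically
        worst = min(range(len(genes)), key=lambda i: (means[i], genes[i]))
        removal_means[genes[worst]] = float(means[worst])
        genes.pop(worst)
        S = np.delete(np.delete(S, worst, axis=0), worst, axis=1)
    if genes:
        removal_means.setdefault(genes[0], float("nan"))
    return [], removal_means


def _all_pairs(sm: SimilarityMatrix, threshold: float) -> list[str]:
    """Maximum clique of the graph with edges S >= threshold.

    Candidate lists are short (typically <= a dozen genes), so exhaustive
    search from the largest size down is both exact and fast.
    """
    genes = sm.genes
    k = len(genes)
    adj = sm.S >= threshold
    np.fill_diagonal(adj, True)
    best: list[tuple[float, tuple[str, ...]]] = []
    for size in range(k, 1, -1):
        for combo in combinations(range(k), size):
            sub = adj[np.ix_(combo, combo)]
            if sub.all():
                names = tuple(genes[i] for i in combo)
                best.append((mean_pairwise_similarity(sm, list(names)), names))
        if best:
            best.sort(key=lambda t: (-t[0], t[1]))
            return list(best[0][1])
    return []


def select_markers(
    m: ExpressionMatrix,
    catalog: GeneSetCatalog,
    threshold: float = 0.6,
    mode: str = "prune_mean",
) -> tuple[list[SelectionResult], GeneSetCatalog]:
    """Apply the similarity filter to every cell type of a candidate catalog.

    Returns the per-cell-type results and a derived catalog of the selected
    markers, ready for :func:`pdacmarkers.scoring.cell_scores`. Entirely
    deterministic: no randomness is involved.
    """
    if m.scale is not Scale.LOG2:
        raise PdacMarkersError("selection runs on log2-scale matrices; apply log2_transform first")
    if not 0 < threshold <= 1:
        raise PdacMarkersError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("prune_mean", "all_pairs"):
        raise PdacMarkersError(f"unknown mode {mode!r}")

    present_catalog, missing_map = intersect_catalog(m, catalog)
    present_by_name = {e.name: e for e in present_catalog}

    results: list[SelectionResult] = []
    derived_entries: list[CellTypeDef] = []
    for entry in catalog:
        missing = missing_map.get(entry.name, [])
        present = present_by_name.get(entry.name)
        res = SelectionResult(
            cell_type=entry.name, candidates=list(entry.genes), selected=[], missing=missing
        )
        if present is None:
            res.status = SelectionStatus.EMPTY
        elif len(present.genes) == 1:
            res.status = SelectionStatus.SINGLE_GENE
            res.selected = list(present.genes)
        else:
            sm = similarity_matrix(m, present.genes)
            if len(sm.degenerate) == len(present.genes):
                res.status = SelectionStatus.DEGENERATE
            else:
                if mode == "prune_mean":
                    selected, means = _prune_mean(sm, threshold)
                    res.per_gene_mean_similarity = means
                else:
                    selected = _all_pairs(sm, threshold)
                    if selected:
                        full_means = dict(zip(sm.genes, _off_diagonal_means(sm.S)))
                        res.per_gene_mean_similarity = {g: float(full_means[g]) for g in sm.genes}
                res.selected = selected
                if len(selected) >= 2:
                    res.status = SelectionStatus.OK
                    res.set_mean_similarity = mean_pairwise_similarity(sm, selected)
                else:
                    res.status = SelectionStatus.EMPTY
        if res.selected:
            derived_entries.append(
                CellTypeDef(
                    name=entry.name,
                    genes=list(res.selected),
                    parent=entry.parent if any(e.name == entry.parent for e in derived_entries) else None,
                    source=f"selected from {catalog.catalog_name} at threshold {threshold} ({mode})",
                    provenance={g: p for g, p in entry.provenance.items() if g in set(res.selected)},
                )
            )
        results.append(res)
    derived = GeneSetCatalog(
        derived_entries, catalog_name=f"{catalog.catalog_name}_selected", version=catalog.version
    )
    return results, derived


def selection_report(results: list[SelectionResult]) -> pd.DataFrame:
    """Per-cell-type summary plus a totals row with unique-gene counts."""
    rows = [
        {
            "cell_type": r.cell_type,
            "n_candidates": len(r.candidates),
            "n_selected": len(r.selected),
            "set_mean_similarity": r.set_mean_similarity,
            "status": r.status.value,
        }
        for r in results
    ]
    unique_cand = {g for r in results for g in r.candidates}
    unique_sel = {g for r in results for g in r.selected}
    rows.append(
        {
            "cell_type": "TOTAL (unique genes)",
            "n_candidates": len(unique_cand),
            "n_selected": len(unique_sel),
            "set_mean_similarity": None,
            "status": "",
        }
    )
    return pd.DataFrame(
        rows, columns=["cell_type", "n_candidates", "n_selected", "set_mean_similarity", "status"]
    )
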