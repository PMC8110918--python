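"""Slope-penalizing pairwise similarity between gene expression vectors.

For log2 expression vectors x, y over n samples the similarity is

    similarity(x, y) = sum((x - mean(x)) * (y - mean(y)))
                       / ( (n-1)/2 * (var(x) + var(y)) )
                     = 2 * cov(x, y) / (var(x) + var(y))

with unbiased (n-1) sample variance and covariance. Unlike Pearson's r,
which is invariant to rescaling either vector, this statistic divides by
the arithmetic rather than geometric mean of the two variances, so it
penalizes slope: for y = a*x + b it equals 2a / (1 + a^2), which is 1 only
at a = 1. Two ideal co-expressed marker genes of one cell type therefore
score 1, and by the AM-GM inequality |similarity| <= |Pearson r| always.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MarkerWarning, PdacMarkersError
from .matrix import ExpressionMatrix, Scale, normalize_symbol


def pairwise_similarity(x, y) -> float:
    """Slope-penalized similarity of two expression vectors (see module docs).

    Raises
    ------
    PdacMarkersError
        If the vectors differ in length or have fewer than 3 samples.
    DegenerateInputError
        If both vectors have zero variance (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise PdacMarkersError(f"vectors must be 1-D of equal length, got {x.shape} and {y.shape}")
    n = x.size
    if n < 3:
        raise PdacMarkersError(f"need at least 3 samples, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PdacMarkersError("vectors must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = (np.dot(xc, xc) + np.dot(yc, yc)) / 2.0  # == (n-1)/2 * (var x + var y)
    if denom == 0.0:
        raise DegenerateInputError("both vectors have zero variance; similarity undefined")
    return float(np.dot(xc, yc) / denom)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise-similarity matrix over an ordered gene list.

    ``degenerate`` lists zero-variance genes: their off-diagonal entries
    (and diagonal) are reported as 0 rather than raising, so one flat gene
    cannot abort a catalog-wide run.
    """

    genes: list[str]
    S: np.ndarray
    n_samples: int
    degenerate: set[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (len(self.genes), len(self.genes)):
            raise PdacMarkersError("similarity matrix shape does not match gene list")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def value(self, gene_a: str, gene_b: str) -> float:
        return float(self.S[self._index[normalize_symbol(gene_a)], self._index[normalize_symbol(gene_b)]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.genes, columns=self.genes)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


def similarity_matrix(m: ExpressionMatrix, genes: list[str]) -> SimilarityMatrix:
    """All-pairs similarity among ``genes`` of a log2-scale matrix."""
    if m.scale is not Scale.LOG2:
        raise PdacMarkersError("similarity is defined on log2-scale matrices; apply log2_transform first")
    keys = [normalize_symbol(g) for g in genes]
    if len(keys) < 2:
        raise PdacMarkersError("need at least 2 genes for a similarity matrix")
    if len(set(keys)) != len(keys):
        raise PdacMarkersError("gene list contains duplicates")
    X = m.subset_genes(keys).values
    n = X.shape[1]
    if n < 3:
        raise PdacMarkersError(f"need at least 3 samples, got {n}")
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)  # per-gene centered sum of squares
    # zero-variance up to float round-off of the mean (SD <= ~1e-12 units)
    sd_tol = 1e-12 * (1.0 + np.abs(X.mean(axis=1)))
    flat = ss <= (n - 1) * sd_tol**2
    degenerate = {g for g, f in zip(keys, flat) if f}
    if degenerate:
        warnings.warn(
            f"zero-variance genes treated as similarity 0: {', '.join(sorted(degenerate))}",
            MarkerWarning,
            stacklevel=2,
        )
    cross = Xc @ Xc.T
    denom = (ss[:, None] + ss[None, :]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0.0, cross / np.where(denom > 0.0, denom, 1.0), 0.0)
    # degenerate genes: all entries (including the diagonal) reported as 0
    S[flat, :] = 0.0
    S[:, flat] = 0.0
    for i, g in enumerate(keys):
        if g not in degenerate:
            S[i, i] = 1.0
    return SimilarityMatrix(genes=keys, S=S, n_samples=n, degenerate=degenerate)


def mean_pairwise_similarity(sm: SimilarityMatrix, genes: list[str] | None = None) -> float:
    """Mean of the off-diagonal upper-triangle entries among ``genes``.

    Single-gene sets have no pairs; this raises so callers can report the
    value as not applicable (blank, as in single-marker cell types).
    """
    keys = [normalize_symbol(g) for g in genes] if genes is not None else list(sm.genes)
    missing = [g for g in keys if g not in sm._index]
    if missing:
        raise PdacMarkersError(f"genes not in similarity matrix: {', '.join(missing)}")
    if len(keys) < 2:
        raise PdacMarkersError("mean pairwise similarity needs at least 2 genes")
    idx = [sm._index[g] for g in keys]
    sub = sm.S[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())
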