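"""Gene-set concordance statistic and its permutation test.

For a gene set with log2 expression matrix X (p genes x n samples) the
concordance is the Rayleigh quotient of the sample covariance matrix
Cov(X) along the equal-weights unit vector u = (p^-1/2, ..., p^-1/2):

    concordance(X) = u' Cov(X) u / trace(Cov(X))

It equals 1 when all genes are perfectly correlated with slope 1 (up to
additive per-gene constants) and decays towards 0 as that pattern weakens;
p mutually uncorrelated equal-variance genes give 1/p in expectation.

The permutation test compares the observed concordance against random
gene sets of the same size drawn from a pool (by default all endogenous
genes of the matrix): the p-value is the fraction of random sets with
strictly greater concordance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, PdacMarkersError
from .matrix import ExpressionMatrix, GeneClass, Scale, normalize_symbol


def concordance_statistic(X) -> float:
    """Concordance of a p x n log2 expression sub-matrix (rows = genes)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise PdacMarkersError("X must be a 2-D (genes x samples) array")
    p, n = X.shape
    if p < 2:
        raise PdacMarkersError(f"need at least 2 genes, got {p}")
    if n < 3:
        raise PdacMarkersError(f"need at least 3 samples, got {n}")
    if not np.all(np.isfinite(X)):
        raise PdacMarkersError("X must be finite")
    Xc = X - X.mean(axis=1, keepdims=True)
    # u'Cu = |sum of centered rows|^2 / (p (n-1));  trace C = sum |row|^2 / (n-1)
    num = float(np.dot(Xc.sum(axis=0), Xc.sum(axis=0))) / p
    den = float(np.einsum("ij,ij->", Xc, Xc))
    if den == 0.0:
        raise DegenerateInputError("all genes constant; concordance undefined")
    return float(min(max(num / den, 0.0), 1.0))


@dataclass
class ConcordanceResult:
    """Observed concordance of one gene set plus its permutation null."""

    cell_type: str
    genes: list[str]
    concordance: float
    p_value: float
    n_permutations: int
    pool_size: int
    seed: int

    @property
    def p(self) -> int:
        return len(self.genes)


def default_pool(m: ExpressionMatrix) -> list[str]:
    """Endogenous genes of the matrix (controls and housekeeping excluded)."""
    return m.genes_of_class(GeneClass.ENDOGENOUS)


def concordance_pvalue(
    m: ExpressionMatrix,
    genes: list[str],
    *,
    n_permutations: int = 1000,
    pool: list[str] | None = None,
    seed: int = 0,
    exclude_tested: bool = False,
    conservative: bool = False,
    cell_type: str = "",
) -> ConcordanceResult:
    """Permutation p-value of a gene set's concordance.

    Parameters
    ----------
    m
        log2-scale expression matrix.
    genes
        The gene set to test (all present in ``m``), size p >= 2.
    n_permutations
        Number of random size-p gene sets drawn from ``pool``.
    pool
        Sampling pool; defaults to all endogenous genes of ``m``. Genes are
        drawn without replacement within a draw.
    exclude_tested
        Drop the tested genes from the pool before sampling (default keeps
        them, mirroring a comparison against "a randomly selected gene set
        of similar size").
    conservative
        Use the (r+1)/(n+1) estimator instead of the plain r/n proportion;
        avoids exact-zero p-values at the cost of a positive bias.
    """
    if m.scale is not Scale.LOG2:
        raise PdacMarkersError("concordance is defined on log2-scale matrices")
    keys = [normalize_symbol(g) for g in genes]
    if len(keys) < 2:
        raise PdacMarkersError("gene set must have at least 2 genes")
    p = len(keys)
    pool_genes = default_pool(m) if pool is None else [normalize_symbol(g) for g in pool]
    if exclude_tested:
        tested = set(keys)
        pool_genes = [g for g in pool_genes if g not in tested]
    if len(set(pool_genes)) != len(pool_genes):
        raise PdacMarkersError("pool contains duplicate genes")
    if len(pool_genes) < p:
        raise PdacMarkersError(f"pool of {len(pool_genes)} genes is smaller than the set size {p}")

    observed = concordance_statistic(m.subset_genes(keys).values)

    P = m.subset_genes(pool_genes).values
    Pc = P - P.mean(axis=1, keepdims=True)
    row_ss = np.einsum("ij,ij->i", Pc, Pc)

    rng = np.random.default_rng(seed)
    # each row of `draws` is a uniformly random size-p subset of the pool
    draws = np.argpartition(rng.random((n_permutations, len(pool_genes))), p - 1, axis=1)[:, :p]
    sums = Pc[draws].sum(axis=1)  # (n_perm, n_samples)
    num = np.einsum("ij,ij->i", sums, sums) / p
    den = row_ss[draws].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        null = np.where(den > 0.0, num / np.maximum(den, 1e-300), 0.0)

    exceed = int(np.sum(null > observed))
    if conservative:
        p_value = (exceed + 1) / (n_permutations + 1)
    else:
        p_value = exceed / n_permutations
    return ConcordanceResult(
        cell_type=cell_type,
        genes=keys,
        concordance=observed,
        p_value=float(p_value),
        n_permutations=n_permutations,
        pool_size=len(pool_genes),
        seed=seed,
    )


def concordance_table(results: list[ConcordanceResult]) -> pd.DataFrame:
    """Tabulate results: one row per cell type, exportable as TSV."""
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "p": r.p,
                "concordance": r.concordance,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
                "pool_size": r.pool_size,
                "seed": r.seed,
            }
            for r in results
        ]
    )
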