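"""Synthetic expression matrices with planted marker-gene structure.

The generator emulates the co-expression pattern the selection method
assumes: each simulated cell type k has a latent per-sample abundance
L[k, s] ~ Normal(group shift, 1) on the log2 scale, and each of its marker
genes g reads

    value[g, s] = baseline_g + loading_g * L[k, s] + Normal(0, noise_sd)

so within a block all markers track the same latent signal. A loading of 1
for every marker makes the block's population pairwise similarity 1 in the
zero-noise limit; mixed loadings a and 1 give 2a/(1+a^2). Decoy ("noise")
genes are independent unit-SD draws around a uniform baseline, and
housekeeping genes are near-constant. Group-level latent shifts plant
treatment effects for the group-comparison machinery.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import CellTypeDef, GeneSetCatalog
from .errors import ConfigError
from .matrix import ExpressionMatrix, GeneClass, Scale

HOUSEKEEPING_SD = 0.05  # residual wobble of "constant" housekeeping genes
NOISE_GENE_SD = 1.0  # decoy genes: comparable spread to a loading-1 marker


@dataclass
class CellBlock:
    """One planted cell type: its marker count, loading(s) and baselines."""

    cell_type: str
    n_genes: int
    loading: float | Sequence[float] = 1.0
    baseline_range: tuple[float, float] = (6.0, 10.0)

    def loadings(self) -> np.ndarray:
        a = np.asarray(self.loading, dtype=float)
        if a.ndim == 0:
            return np.full(self.n_genes, float(a))
        if a.shape != (self.n_genes,):
            raise ConfigError(
                f"block {self.cell_type!r}: {len(a)} loadings for {self.n_genes} genes"
            )
        return a


@dataclass
class SimulationConfig:
    n_samples: int = 50
    cell_blocks: list[CellBlock] = field(default_factory=list)
    n_noise_genes: int = 0
    noise_sd: float = 0.1
    group_effects: dict[str, dict[str, float]] | None = None
    n_housekeeping: int = 0
    seed: int = 0
    baseline_range: tuple[float, float] = (6.0, 10.0)
    cross_loading: float = 0.0

    def validate(self) -> None:
        problems = []
        if self.n_samples < 3:
            problems.append(f"n_samples must be >= 3, got {self.n_samples}")
        if self.noise_sd < 0:
            problems.append(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_noise_genes < 0:
            problems.append("n_noise_genes must be >= 0")
        if self.n_housekeeping < 0:
            problems.append("n_housekeeping must be >= 0")
        names = [b.cell_type for b in self.cell_blocks]
        if len(set(names)) != len(names):
            problems.append("cell_blocks have duplicate cell-type labels")
        for b in self.cell_blocks:
            if b.n_genes < 1:
                problems.append(f"block {b.cell_type!r} must have >= 1 gene")
            lo, hi = b.baseline_range
            if not lo <= hi:
                problems.append(f"block {b.cell_type!r}: empty baseline range")
        if self.group_effects is not None:
            known = set(names)
            for grp, shifts in self.group_effects.items():
                for ct in shifts:
                    if ct not in known:
                        problems.append(f"group {grp!r} shifts unknown cell type {ct!r}")
        if problems:
            raise ConfigError("invalid simulation config: " + "; ".join(problems))


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    truth: dict[str, list[str]]
    latents: np.ndarray  # (n_cell_types, n_samples)
    latent_cell_types: list[str]
    config: SimulationConfig

    def noise_genes(self) -> list[str]:
        planted = {g for gs in self.truth.values() for g in gs}
        return [
            g
            for g in self.matrix.gene_ids
            if g not in planted and self.matrix.class_of(g) is GeneClass.ENDOGENOUS
        ]

    def candidate_catalog(self, decoys_per_type: int = 0) -> GeneSetCatalog:
        """Planted markers per cell type, padded with decoy noise genes.

        Decoys are assigned deterministically in gene order, so the catalog
        is reproducible without extra randomness.
        """
        noise = self.noise_genes()
        need = decoys_per_type * len(self.truth)
        if need > len(noise):
            raise ConfigError(f"need {need} decoys but only {len(noise)} noise genes simulated")
        entries = []
        cursor = 0
        for ct, genes in self.truth.items():
            decoys = noise[cursor : cursor + decoys_per_type]
            cursor += decoys_per_type
            entries.append(
                CellTypeDef(name=ct, genes=list(genes) + decoys, source="simulated candidates")
            )
        return GeneSetCatalog(entries, catalog_name="simulated_candidates")


def _sanitize(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "", label).upper() or "CT"


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the latent-factor block model (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    groups: dict[str, str] | None = None
    sample_group: list[str] | None = None
    if config.group_effects:
        labels = list(config.group_effects)
        counts = [n // len(labels)] * len(labels)
        for i in range(n - sum(counts)):
            counts[i] += 1
        sample_group = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    if sample_group is not None:
        groups = dict(zip(sample_ids, sample_group))

    cell_types = [b.cell_type for b in config.cell_blocks]
    latents = rng.standard_normal((len(cell_types), n))
    if sample_group is not None:
        for k, ct in enumerate(cell_types):
            shifts = np.array(
                [config.group_effects[g].get(ct, 0.0) for g in sample_group]  # type: ignore[index]
            )
            latents[k] += shifts

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    gene_class: dict[str, GeneClass] = {}
    truth: dict[str, list[str]] = {}
    for k, block in enumerate(config.cell_blocks):
        prefix = _sanitize(block.cell_type)
        loadings = block.loadings()
        baselines = rng.uniform(*block.baseline_range, size=block.n_genes)
        names = [f"{prefix}MK{i + 1:02d}" for i in range(block.n_genes)]
        signal = latents[k]
        if config.cross_loading and len(cell_types) > 1:
            others = np.delete(np.arange(len(cell_types)), k)
            signal = signal + config.cross_loading * latents[others].mean(axis=0)
        for name, a, b0 in zip(names, loadings, baselines):
            rows.append(b0 + a * signal + rng.normal(0.0, config.noise_sd, size=n))
            gene_ids.append(name)
        truth[block.cell_type] = names

    lo, hi = config.baseline_range
    for i in range(config.n_noise_genes):
        name = f"NOISE{i + 1:04d}"
        rows.append(rng.uniform(lo, hi) + rng.normal(0.0, NOISE_GENE_SD, size=n))
        gene_ids.append(name)

    for i in range(config.n_housekeeping):
        name = f"HK{i + 1:02d}"
        rows.append(rng.uniform(lo, hi) + rng.normal(0.0, HOUSEKEEPING_SD, size=n))
        gene_ids.append(name)
        gene_class[name] = GeneClass.HOUSEKEEPING

    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.vstack(rows) if rows else np.empty((0, n)),
        scale=Scale.LOG2,
        gene_class=gene_class,
        groups=groups,
    )
    return SimulatedDataset(
        matrix=matrix, truth=truth, latents=latents, latent_cell_types=cell_types, config=config
    )


# -- named fixtures used across the test suite and examples -------------------


def fixture_suite() -> dict[str, SimulatedDataset]:
    """Deterministic small datasets exercising each analysis path.

    clean_block
        One 5-marker slope-1 block plus 6 decoys: selection recovery.
    null_pool
        500 independent genes, no structure: concordance calibration.
    two_groups
        Four 3-marker cell types, one with a +2 latent shift in the
        treated group: group-comparison sanity.
    degenerate
        Zero-noise blocks including constant (loading-0) genes.
    """
    return {
        "clean_block": simulate(
            SimulationConfig(
                n_samples=50,
                cell_blocks=[CellBlock("B cells", 5)],
                n_noise_genes=6,
                noise_sd=0.1,
                n_housekeeping=3,
                seed=101,
            )
        ),
        "null_pool": simulate(
            SimulationConfig(n_samples=50, cell_blocks=[], n_noise_genes=500, seed=202)
        ),
        "two_groups": simulate(
            SimulationConfig(
                n_samples=30,
                cell_blocks=[
                    CellBlock("T cells", 3),
                    CellBlock("B cells", 3),
                    CellBlock("Macrophages", 3),
                    CellBlock("CD45+", 1),
                ],
                n_noise_genes=20,
                noise_sd=0.2,
                group_effects={"control": {}, "treated": {"T cells": 3.0}},
                n_housekeeping=3,
                seed=303,
            )
        ),
        "degenerate": simulate(
            SimulationConfig(
                n_samples=20,
                cell_blocks=[CellBlock("Marker", 3), CellBlock("Flat", 3, loading=0.0)],
                n_noise_genes=5,
                noise_sd=0.0,
                seed=404,
            )
        ),
    }
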