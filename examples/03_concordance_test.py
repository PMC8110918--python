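"""Permutation concordance test of a gene set against random sets.

A co-expressed slope-1 gene set has concordance near 1; the p-value is the
fraction of 1000 equally sized random gene sets from the matrix that score
higher. A random set from the null pool is shown for contrast.
"""
import numpy as np

from pdacmarkers import (
    ExpressionMatrix,
    Scale,
    concordance_pvalue,
    fixture_suite,
    simulate,
    SimulationConfig,
    CellBlock,
)

ds = simulate(
    SimulationConfig(
        n_samples=50,
        cell_blocks=[CellBlock("planted", 5)],
        n_noise_genes=500,
        noise_sd=0.1,
        seed=11,
    )
)

planted = concordance_pvalue(ds.matrix, ds.truth["planted"], n_permutations=1000, seed=1)
print(f"planted set : concordance={planted.concordance:.3f}  p={planted.p_value:.3f}")

random_set = ds.noise_genes()[:5]
null = concordance_pvalue(ds.matrix, random_set, n_permutations=1000, seed=1)
print(f"random set  : concordance={null.concordance:.3f}  p={null.p_value:.3f}")

# The planted set captures nearly all of its covariance trace along the
# equal-weights direction (concordance ~0.99) and no random set beats it
# (p = 0). The random set's concordance sits near 1/p = 0.2 and its p-value
# is unremarkable, as expected under the null.
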