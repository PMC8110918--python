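import numpy as np
import pytest
from hypothesis import settings

from pdacmarkers import ExpressionMatrix, Scale, fixture_suite

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixtures():
    """The deterministic named simulation fixtures, built once per session."""
    return fixture_suite()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_log2_matrix():
    """4 genes x 6 samples on the log2 scale, hand-enterable values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [2.0, 3.0, 4.0, 5.0, 6.0, 7.0],  # GENEA + 1
            [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],  # 2 * GENEA
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],  # constant
        ]
    )
    return ExpressionMatrix(
        gene_ids=["GENEA", "GENEB", "GENEC", "GENED"],
        sample_ids=[f"S{i}" for i in range(1, 7)],
        values=values,
        scale=Scale.LOG2,
    )
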