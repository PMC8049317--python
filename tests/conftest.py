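import numpy as np
import pytest

from protmiss.matrix import ProteinMatrix
from protmiss.simulate import ckd_like_preset, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_masked_matrix():
    """4 samples × 3 proteins with two masked cells."""
    values = np.array(
        [
            [14.0, 15.0, 13.5],
            [np.nan, 15.5, 13.0],
            [14.2, np.nan, 12.8],
            [13.8, 15.2, 13.1],
        ]
    )
    return ProteinMatrix.from_values(values)


@pytest.fixture
def mcar_matrix(rng):
    """60 × 12 Gaussian matrix with 15% MCAR missingness and ground truth."""
    truth = rng.normal(14.0, 1.5, (60, 12))
    mask = rng.random(truth.shape) < 0.15
    values = truth.copy()
    values[mask] = np.nan
    return ProteinMatrix.from_values(values), truth


@pytest.fixture(scope="session")
def ckd_small_dataset():
    """The small plasma-cohort preset (100 × 200, ~56% MNAR missing)."""
    return simulate(ckd_like_preset(small=True, seed=7))
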