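import numpy as np
import pytest

from arterymech import GHOParams


@pytest.fixture(scope="session")
def cn_params() -> GHOParams:
    """Control-group GHO constants (study Table row)."""
    return GHOParams(mu=35.0, k1=73.0, k2=0.07, kappa=0.27, gamma=74.5)


@pytest.fixture(scope="session")
def mn_params() -> GHOParams:
    """Melatonin-group GHO constants."""
    return GHOParams(mu=33.0, k1=79.0, k2=0.06, kappa=0.26, gamma=52.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240911)


def exact_mean_sem_sample(mean: float, sem: float, n: int) -> np.ndarray:
    """Symmetric sample with exactly the requested mean and SEM.

    Uses values mean ± d (plus the mean itself when n is odd) with
    d = sem * sqrt(n*(n-1)/(2*floor(n/2))), which makes the sample sd with
    n-1 denominator equal sem*sqrt(n) exactly.
    """
    half = n // 2
    d = sem * np.sqrt(n * (n - 1) / (2 * half)) if sem > 0 else 0.0
    vals = [mean - d] * half + [mean] * (n - 2 * half) + [mean + d] * half
    return np.asarray(vals, dtype=float)
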