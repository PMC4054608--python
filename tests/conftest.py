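import numpy as np
import pytest

from methdiff import BetaParams, MethCount


@pytest.fixture
def rng():
    return np.random.default_rng(20140224)


@pytest.fixture
def uniform_prior():
    return BetaParams(1.0, 1.0)


def ks_distance(sample: np.ndarray, grid) -> float:
    """Kolmogorov-Smirnov distance between an empirical sample and a DensityGrid."""
    x = np.sort(sample)
    n = x.size
    f = np.asarray(grid.cdf(x))
    return float(
        max(np.max(np.arange(1, n + 1) / n - f), np.max(f - np.arange(n) / n))
    )
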