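import numpy as np
import pytest

from prism_rarity import HyperExpResults, SurvivalCurve, survival_probability


@pytest.fixture
def bla_fit():
    """Published-style fit for the calibration enzyme (L=263)."""
    return HyperExpResults.from_params(0.104, 0.019,
                                       sigma_alpha=0.02, sigma_beta=0.004)


@pytest.fixture
def gfp_fit():
    """Published-style fit for the fluorescent protein (L=238)."""
    return HyperExpResults.from_params(-0.047, 0.054,
                                       sigma_alpha=0.003, sigma_beta=0.001)


@pytest.fixture
def hisa_fit():
    """Published-style fit for the isomerase (L=254)."""
    return HyperExpResults.from_params(0.096, 0.039,
                                       sigma_alpha=0.033, sigma_beta=0.013)


@pytest.fixture
def noiseless_curve():
    """Exact model curve: fitting it must recover the parameters."""
    n = tuple(range(15))
    p = tuple(float(survival_probability(0.104, 0.019, k)) for k in n)
    return SurvivalCurve(n, p)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
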