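import numpy as np
import pytest

from cuebias import ObserverParams, make_conflict_pairs, make_target_grid


@pytest.fixture(scope="session")
def unit_grid():
    """The 36-value unit-range target grid used by the power study."""
    return make_target_grid(0.15, 0.85, 0.02)


@pytest.fixture(scope="session")
def conflict_pairs():
    """The 72 ordered conflict pairs from the 9-value grid 0.4..0.6."""
    return make_conflict_pairs(make_target_grid(0.4, 0.6, 0.025))


@pytest.fixture
def biased_observer():
    """A unit-range observer with a moderate central bias."""
    return ObserverParams(sigma1=0.05, sigma2=0.1, sigma_n=0.01, w_pc=0.3, mu=0.5)


def variance_se(variance: float, n: int) -> float:
    """Monte-Carlo standard error of a sample variance of n Gaussian draws."""
    return variance * np.sqrt(2.0 / n)


def sensory_se(fit) -> float:
    """Delta-method SE of the slope-corrected variance ``resid_var / beta**2``.

    Combines the sampling error of the residual variance with the propagated
    error of the fitted slope.
    """
    var = (fit.resid_var / fit.beta**2) ** 2 * 2.0 / (fit.n - 2)
    var += (2.0 * fit.resid_var / fit.beta**3) ** 2 * fit.se_beta**2
    return float(np.sqrt(var))
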