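import numpy as np
import pytest

from qicsim import DeviceParams, fixtures


@pytest.fixture
def strong_high() -> DeviceParams:
    return fixtures("strong-high-regulated")


@pytest.fixture
def strong_high_unreg() -> DeviceParams:
    return fixtures("strong-high-unregulated")


@pytest.fixture
def unit_params() -> DeviceParams:
    """All rate constants equal to one (λ/β = 1, k = 1): hand-checkable."""
    return DeviceParams(
        T=1.0, D=1.0, kappa_gfp=1.0, kappa_ecf=1.0, Ts=1.0,
        delta=1.0, lam=1.0, beta=1.0, R=1.0, gamma=1.0,
    )


def random_device_params(rng: np.random.Generator) -> DeviceParams:
    """A randomized but well-posed regulated parameter set.

    Rates are drawn log-uniformly within physiologic-looking ranges; the
    coupled-decay rate is kept large relative to delta so the fixed point
    is stable and reachable by integration.
    """

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return DeviceParams(
        T=logu(20.0, 500.0),
        D=float(rng.integers(1, 30)),
        kappa_gfp=logu(10.0, 300.0),
        kappa_ecf=logu(5.0, 300.0),
        Ts=logu(5.0, 50.0),
        delta=logu(1.0, 15.0),
        lam=logu(200.0, 2000.0),
        beta=logu(5.0, 50.0),
        R=logu(200.0, 3000.0),
        gamma=logu(0.5, 3.0),
    )
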