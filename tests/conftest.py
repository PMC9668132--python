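import numpy as np
import pytest

import rdthresh as rt

C = 10.0
H = rt.PRESET_BANDWIDTH  # 5.0


@pytest.fixture(scope="session")
def canonical_data():
    """One canonical sharp dataset at the preset study conditions."""
    return rt.generate_sharp(rt.scenario_preset("canonical", n=500, sigma=1.0, seed=11))


@pytest.fixture(scope="session")
def canonical_fits(canonical_data):
    return rt.fit_both_sides(canonical_data, H)


@pytest.fixture(scope="session")
def canonical_curve(canonical_fits):
    below, above = canonical_fits
    return rt.effect_curve(below, above, H)


@pytest.fixture(scope="session")
def canonical_density(canonical_data):
    return rt.estimate_density(canonical_data)


def make_side_fit(alpha, beta, side, *, cov=None, c=C, h=H, sigma2=0.0, n_used=50):
    """Synthetic SideFit with prescribed coefficients (zero covariance by
    default) for closed-form arithmetic checks."""
    cov = np.zeros((2, 2)) if cov is None else np.asarray(cov, float)
    return rt.SideFit(
        alpha=alpha, beta=beta, cov=cov, sigma2=sigma2, n_used=n_used, side=side,
        c=c, h=h,
    )


@pytest.fixture
def synthetic_fits():
    return make_side_fit
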