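import numpy as np
import pytest

from biswater import (
    ColeParams,
    SimConfig,
    Subject,
    make_frequency_grid,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def grid():
    return make_frequency_grid()


@pytest.fixture
def man():
    return Subject(id="m1", sex="male", age=40, height_cm=180, weight_kg=80)


@pytest.fixture
def woman():
    return Subject(id="w1", sex="female", age=40, height_cm=165, weight_kg=60)


@pytest.fixture
def cole_params():
    return ColeParams(r0_ohm=600, rinf_ohm=400, fc_hz=50e3, alpha=1.0, td_ns=0.0)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noiseless cohort, Td = 0: exact mixture closure holds per subject."""
    cfg = SimConfig(
        n_subjects=60,
        seed=7,
        spectrum_noise_sd=0.0,
        td_mean_ns=0.0,
        td_sd_ns=0.0,
        reference_cv=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-condition cohort with measurement and reference noise."""
    return simulate_cohort(SimConfig(n_subjects=120, seed=11))


def quintic_oracle(re_ohm, ri_ohm, rho_i, rho_e, n_grid=200_000, x_max=20.0):
    """Independent dense-grid + hand-rolled-bisection root of the ratio relation.

    Scans g(x) = (1+x)^2.5 - k(1+r x) on a uniform grid for the first sign
    change, then bisects; shares no code with the package solver.
    """
    k = (re_ohm + ri_ohm) / ri_ohm
    r = rho_i / rho_e
    xs = np.linspace(0.0, x_max, n_grid)
    g = (1.0 + xs) ** 2.5 - k * (1.0 + r * xs)
    sign_change = np.nonzero((g[:-1] <= 0) & (g[1:] > 0))[0]
    if sign_change.size == 0:
        raise ValueError("oracle: no sign change in grid")
    lo, hi = xs[sign_change[0]], xs[sign_change[0] + 1]
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        gm = (1.0 + mid) ** 2.5 - k * (1.0 + r * mid)
        if gm <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
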