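import numpy as np
import pytest

from tiapbms import CohortDesign, DecayConstants, generate_cohort
from tiapbms.cohort import TimeActivityCohort


@pytest.fixture(scope="session")
def decay():
    return DecayConstants()


@pytest.fixture(scope="session")
def default_sim():
    """One default-design synthetic cohort (f3a truth, seed-fixed)."""
    return generate_cohort(seed=42)


@pytest.fixture(scope="session")
def noisefree_f2a_sim():
    """Noise-free mono-exponential cohort: omega = 0, residual ~ 0."""
    design = CohortDesign(truth_function="f2a",
                          truth_tvp={"A1": 0.04, "lambda1": 3e-4},
                          omega=0.0, sigma_res=1e-6)
    return generate_cohort(design, seed=3)


@pytest.fixture()
def tiny_cohort():
    """Three patients, three points each, from a known f2a curve + noise."""
    rng = np.random.default_rng(7)
    t_all, y_all, g_all = [], [], []
    decay = DecayConstants()
    from tiapbms.functions import get_function

    fn = get_function("f2a")
    for i in range(3):
        eta = rng.normal(0, 0.2)
        t = np.array([60.0, 1200.0, 9800.0]) * rng.uniform(0.9, 1.1, 3)
        f = fn.evaluate({"A1": 0.04 * np.exp(eta), "lambda1": 3e-4}, t, decay)
        y = f * np.exp(rng.normal(0, 0.15, 3))
        t_all += list(t)
        y_all += list(y)
        g_all += [f"P{i}"] * 3
    return TimeActivityCohort.from_arrays(t_all, y_all, g_all)
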