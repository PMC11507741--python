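import numpy as np
import pytest

import steinshrink as ss


@pytest.fixture(scope="session")
def kinematic_cohort():
    """Default treadmill cohort (k=8, 100 steps) with generative truths."""
    return ss.simulate_kinematic_cohort(ss.default_kinematic_spec(seed=11))


@pytest.fixture(scope="session")
def walking_cohort():
    """Default circle-walking metabolic cohort (k=11)."""
    return ss.simulate_metabolic_cohort(ss.default_walking_spec(seed=11))


@pytest.fixture(scope="session")
def resting_cohort():
    """Default quiet-sitting cohort (k=27)."""
    return ss.simulate_metabolic_cohort(ss.default_resting_spec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_cohort_estimates(values, variances, method="resting_mean"):
    values = np.asarray(values, dtype=float)
    variances = np.broadcast_to(np.asarray(variances, dtype=float),
                                values.shape)
    return ss.CohortEstimates([
        ss.PointEstimate(f"P{i:02d}", float(v), float(s2), 10, method)
        for i, (v, s2) in enumerate(zip(values, variances))])
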