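import numpy as np
import pytest

import ipdpool as ip


@pytest.fixture
def toy_cohort():
    """times (1,2,3) with events (1,0,1): S = 2/3, 2/3, 0."""
    return ip.IPDCohort.from_arrays(
        time=[1.0, 2.0, 3.0],
        event=[1, 0, 1],
        arm=["treatment"] * 3,
        study="toy",
    )


@pytest.fixture
def two_arm_cohort():
    rng = np.random.default_rng(42)
    n = 400
    arm = np.array(["treatment"] * (n // 2) + ["control"] * (n // 2))
    rate = np.where(arm == "treatment", 0.7, 1.0) * (np.log(2) / 12.0)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(5, 40, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return ip.IPDCohort.from_arrays(time=time, event=event, arm=arm, study="sim")


@pytest.fixture
def small_scenario():
    """A fast-to-simulate two-subgroup trial with distinct subgroup effects."""
    return ip.TrialScenario(
        name="small",
        n_treatment=150,
        n_control=150,
        subgroup_prevalence=0.6,
        baseline_median={"high": 11.0, "low": 13.0},
        hr_high=0.7,
        hr_low=1.0,
        censor_rate=0.01,
        max_followup=36.0,
        seed=7,
    )
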