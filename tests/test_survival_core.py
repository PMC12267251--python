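"""Kaplan-Meier, log-rank and Cox engine checks against hand calculations,
brute-force oracles and lifelines."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ipdpool as ip
from ipdpool.survival_core import PartialLikelihood, cox_newton


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_hand_product_limit(toy_cohort):
    km = ip.fit_km(toy_cohort)
    assert np.allclose(km.event_times, [1.0, 3.0])
    assert km.survival_at(1.0) == pytest.approx(2 / 3)
    assert km.survival_at(2.0) == pytest.approx(2 / 3)
    assert km.survival_at(3.0) == pytest.approx(0.0)
    assert km.survival_at(0.5) == 1.0


def test_km_all_censored_flat_curve():
    cohort = ip.IPDCohort.from_arrays(
        time=[1, 2, 3], event=[0, 0, 0], arm=["control"] * 3
    )
    km = ip.fit_km(cohort)
    assert len(km.event_times) == 0
    assert km.survival_at(99.0) == 1.0
    assert math.isinf(km.median)


def test_km_median_of_large_exponential_sample():
    rng = np.random.default_rng(1)
    t = rng.exponential(12.0 / np.log(2), size=20_000)
    cohort = ip.IPDCohort.from_arrays(time=t, event=np.ones(len(t), int),
                                      arm=["treatment"] * len(t))
    km = ip.fit_km(cohort)
    assert abs(km.median - 12.0) < 0.3


def test_km_risk_set_accounting_identity():
    rng = np.random.default_rng(5)
    t = np.round(rng.exponential(10, 300), 0) + 1  # heavy ties
    e = (rng.random(300) < 0.7).astype(int)
    km = ip.fit_km(ip.IPDCohort.from_arrays(time=t, event=e, arm=["control"] * 300))
    for k in range(len(km.event_times) - 1):
        assert km.n_at_risk[k + 1] == km.n_at_risk[k] - km.n_events[k] - km.n_censored[k]
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert np.all(np.diff(km.n_at_risk) <= 0)


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(9)
    t = np.round(rng.exponential(10, 200), 1) + 0.1
    e = (rng.random(200) < 0.6).astype(int)
    km = ip.fit_km(ip.IPDCohort.from_arrays(time=t, event=e, arm=["control"] * 200))
    kmf = KaplanMeierFitter().fit(t, e)
    ours = np.asarray(km.survival_at(km.event_times), dtype=float)
    theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
    assert np.allclose(ours, theirs, atol=1e-12)


# ---------------------------------------------------------------------------
# Median and its confidence interval
# ---------------------------------------------------------------------------


def test_median_step_curve():
    # S = 1, 0.6, 0.4 at t = 0, 5, 9 -> median 9 (smallest t with S <= 0.5)
    cohort = ip.IPDCohort.from_arrays(
        time=[5, 5, 9, 10, 10], event=[1, 1, 1, 0, 0], arm=["treatment"] * 5
    )
    km = ip.fit_km(cohort)
    assert km.survival_at(5.0) == pytest.approx(0.6)
    assert km.survival_at(9.0) == pytest.approx(0.4)
    assert km.median == 9.0


def test_median_undefined_when_curve_stays_high():
    cohort = ip.IPDCohort.from_arrays(
        time=[1, 2, 3, 4], event=[1, 0, 0, 0], arm=["treatment"] * 4
    )
    med, lo, hi = ip.median_survival_ci(cohort)
    assert math.isinf(med)
    assert math.isinf(hi)


def test_median_ci_coverage_exponential():
    """Brookmeyer-Crowley CI covers the true exponential median ~95% of the
    time (300 replicates at n=500)."""
    rng = np.random.default_rng(11)
    true_median = 12.0
    covered = 0
    reps = 300
    for _ in range(reps):
        t = rng.exponential(true_median / np.log(2), 500)
        c = rng.uniform(10, 60, 500)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        cohort = ip.IPDCohort.from_arrays(time=time, event=event, arm=["treatment"] * 500)
        _, lo, hi = ip.median_survival_ci(cohort)
        covered += lo <= true_median <= hi
    assert 0.91 <= covered / reps <= 0.985


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


def _logrank_oracle(t1, e1, t2, e2):
    """Brute-force O-E/V from the 2x2 table at every distinct event time."""
    events = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O = E = V = 0.0
    for t in events:
        n1 = (t1 >= t).sum()
        n2 = (t2 >= t).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        d2 = ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_identical_cohorts_is_null(two_arm_cohort):
    a = two_arm_cohort.filter(arm="treatment")
    chi2, p = ip.logrank_test(a, a)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_bruteforce_tables():
    t1 = np.array([1.0, 3.0, 5.0, 7.0])
    e1 = np.array([1, 1, 0, 1])
    t2 = np.array([2.0, 3.0, 6.0, 9.0])
    e2 = np.array([1, 1, 1, 0])
    a = ip.IPDCohort.from_arrays(time=t1, event=e1, arm=["treatment"] * 4)
    b = ip.IPDCohort.from_arrays(time=t2, event=e2, arm=["control"] * 4)
    chi2, _ = ip.logrank_test(a, b)
    assert chi2 == pytest.approx(_logrank_oracle(t1, e1, t2, e2), rel=1e-9)


def test_logrank_no_events_is_defined():
    a = ip.IPDCohort.from_arrays(time=[1, 2], event=[0, 0], arm=["treatment"] * 2)
    b = ip.IPDCohort.from_arrays(time=[1, 3], event=[0, 0], arm=["control"] * 2)
    assert ip.logrank_test(a, b) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def test_cox_toy_matches_grid_search_oracle():
    """beta-hat equals the argmax of the partial likelihood on a dense grid."""
    time = np.array([2.0, 4.0, 6.0])
    event = np.array([1, 1, 1])
    x = np.array([1.0, 0.0, 1.0])

    def pll(beta):  # no ties: straightforward product over risk sets
        order = np.argsort(time)
        ll = 0.0
        for i in order:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return ll

    grid = np.linspace(-5, 5, 20_001)
    beta_grid = grid[np.argmax([pll(b) for b in grid])]
    cohort = ip.IPDCohort.from_arrays(time=time, event=event,
                                      arm=np.where(x == 1, "treatment", "control"))
    fit = ip.fit_cox(cohort)
    assert fit.log_hr == pytest.approx(beta_grid, abs=1e-3)


def test_cox_null_and_known_rate_ratio():
    rng = np.random.default_rng(21)
    n = 5000
    arm = np.array(["treatment"] * n + ["control"] * n)
    # null
    t = rng.exponential(12, 2 * n)
    fit0 = ip.fit_cox(ip.IPDCohort.from_arrays(time=t, event=np.ones(2 * n, int), arm=arm))
    assert abs(fit0.log_hr) < 0.05
    # true rate ratio 0.7
    rate = np.where(arm == "treatment", 0.7, 1.0) / 12.0
    t = rng.exponential(1.0 / rate)
    fit = ip.fit_cox(ip.IPDCohort.from_arrays(time=t, event=np.ones(2 * n, int), arm=arm))
    assert 0.66 <= fit.hr <= 0.74
    assert fit.ci95[0] < fit.hr < fit.ci95[1]


def test_cox_matches_lifelines_with_ties():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(3)
    n = 300
    t = np.round(rng.exponential(10, n), 0) + 1
    e = (rng.random(n) < 0.8).astype(int)
    x = rng.integers(0, 2, n).astype(float)
    beta, cov, *_ = cox_newton(t, e, x)
    cph = CoxPHFitter().fit(
        pd.DataFrame({"T": t, "E": e, "x": x}), "T", "E"
    )
    # agreement to the two optimizers' joint convergence precision
    assert beta[0] == pytest.approx(cph.params_.iloc[0], abs=1e-4)
    assert math.sqrt(cov[0, 0]) == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-4)


def test_cox_score_zero_and_efron_equals_breslow_without_ties(two_arm_cohort):
    x = (two_arm_cohort.data["arm"] == "treatment").to_numpy(float)
    t, e = two_arm_cohort.time, two_arm_cohort.event
    assert len(np.unique(t[e == 1])) == e.sum()  # no tied event times
    b_e, *_ = cox_newton(t, e, x, ties="efron")
    b_b, *_ = cox_newton(t, e, x, ties="breslow")
    assert b_e[0] == pytest.approx(b_b[0], abs=1e-9)
    pl = PartialLikelihood(t, e, x)
    _, score, _ = pl.loglik_score_info(np.array([b_e[0]]))
    assert abs(score[0]) < 1e-8


def test_cox_invariances(two_arm_cohort):
    fit = ip.fit_cox(two_arm_cohort)
    # time rescaling by a positive constant
    scaled = ip.IPDCohort.from_arrays(
        time=two_arm_cohort.time * 3.7,
        event=two_arm_cohort.event,
        arm=two_arm_cohort.data["arm"].tolist(),
    )
    assert ip.fit_cox(scaled).log_hr == pytest.approx(fit.log_hr, abs=1e-9)
    # patient relabeling
    relabeled = ip.IPDCohort.from_arrays(
        time=two_arm_cohort.time,
        event=two_arm_cohort.event,
        arm=two_arm_cohort.data["arm"].tolist(),
        patient_id=[f"Z{i}" for i in range(len(two_arm_cohort))],
    )
    assert ip.fit_cox(relabeled).log_hr == pytest.approx(fit.log_hr, abs=1e-12)


def test_cox_complete_separation_is_flagged():
    # all treatment events precede all control events: monotone likelihood
    cohort = ip.IPDCohort.from_arrays(
        time=[1, 2, 3, 10, 11, 12],
        event=[1, 1, 1, 1, 1, 1],
        arm=["treatment"] * 3 + ["control"] * 3,
    )
    fit = ip.fit_cox(cohort)
    assert not fit.converged
    assert "separation" in fit.message or "converge" in fit.message


def test_cox_requires_events_and_variation():
    c = ip.IPDCohort.from_arrays(time=[1, 2], event=[0, 0],
                                 arm=["treatment", "control"])
    with pytest.raises(ValueError, match="no events"):
        ip.fit_cox(c)
    c2 = ip.IPDCohort.from_arrays(time=[1, 2], event=[1, 1],
                                  arm=["treatment", "treatment"])
    with pytest.raises(ValueError, match="constant"):
        ip.fit_cox(c2)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def test_cohort_validation_errors():
    empty = ip.IPDCohort(pd.DataFrame(columns=ip.survival_core.IPD_COLUMNS))
    with pytest.raises(ValueError, match="empty"):
        ip.fit_km(empty)
    with pytest.raises(ValueError, match="invalid time"):
        ip.IPDCohort.from_arrays(time=[-1.0], event=[1], arm=["treatment"])
    with pytest.raises(ValueError, match="endpoint"):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b"], "time": [1.0, 2.0], "event": [1, 0],
                "arm": ["treatment", "control"], "study": "s",
                "subgroup": "unknown", "endpoint": ["OS", "PFS"],
            }
        )
        ip.IPDCohort(df)


def test_record_invariants():
    with pytest.raises(ValueError):
        ip.SurvivalRecord("p1", -1.0, 1, "treatment")
    with pytest.raises(ValueError):
        ip.SurvivalRecord("p1", 1.0, 2, "treatment")
    rec = ip.SurvivalRecord("p1", 1.0, 1, "treatment", subgroup="high")
    assert rec.subgroup == "high"
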