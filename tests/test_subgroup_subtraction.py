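"""Optimal matching, complement derivation and Monte Carlo error limits,
checked against a brute-force assignment oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ipdpool as ip
from ipdpool.subgroup_subtraction import STATUS_PENALTY_SCALE, _match_one_arm


def _cohort(times, events, arm="treatment", subgroup="unknown", prefix="p"):
    return ip.IPDCohort.from_arrays(
        time=times, event=events, arm=[arm] * len(times),
        subgroup=subgroup, patient_id=[f"{prefix}{i}" for i in range(len(times))],
    )


def _bruteforce_assignment_cost(cost: np.ndarray) -> float:
    """Exact optimum of the rectangular assignment problem by bitmask DP
    over the larger side (feasible up to ~12 columns)."""
    r, n = cost.shape
    assert r <= n <= 14
    full = 1 << n
    INF = float("inf")
    dp = np.full(full, INF)
    dp[0] = 0.0
    # process subgroup rows in order; dp over subsets of used columns
    best = INF
    counts = np.array([bin(m).count("1") for m in range(full)])
    for m in range(full):
        k = counts[m]
        if dp[m] == INF or k > r:
            continue
        if k == r:
            best = min(best, dp[m])
            continue
        for j in range(n):
            if not m & (1 << j):
                nm = m | (1 << j)
                v = dp[m] + cost[k, j]
                if v < dp[nm]:
                    dp[nm] = v
    return best


def test_exact_subset_matches_at_zero_cost():
    all_times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    all_events = [1, 0, 1, 1, 0, 1]
    sub_idx = [0, 2, 4]
    allc = _cohort(all_times, all_events, prefix="a")
    sub = _cohort([all_times[i] for i in sub_idx],
                  [all_events[i] for i in sub_idx], subgroup="high", prefix="s")
    res = ip.match_subgroup(allc, sub)
    assert res.total_cost == 0.0
    assert res.n_cross_status == 0
    comp = res.complement.data
    expect = sorted((all_times[i], all_events[i]) for i in range(6) if i not in sub_idx)
    got = sorted(zip(comp["time"], comp["event"]))
    assert got == expect
    assert (comp["subgroup"] == "low").all()
    assert res.complement.provenance == "derived-complement"


def test_partition_invariant_and_sizes():
    rng = np.random.default_rng(0)
    n, r = 30, 12
    allc = _cohort(rng.exponential(10, n).round(3),
                   rng.integers(0, 2, n), prefix="a")
    sub = _cohort(rng.exponential(10, r).round(3),
                  rng.integers(0, 2, r), subgroup="high", prefix="s")
    res = ip.match_subgroup(allc, sub)
    assert len(res.pairs) == r
    assert len(res.complement) == n - r
    matched_ids = set(res.pairs["matched_id"])
    comp_ids = set(res.complement.data["patient_id"])
    assert len(matched_ids) == r  # nothing matched twice
    assert matched_ids | comp_ids == set(allc.data["patient_id"])
    assert matched_ids.isdisjoint(comp_ids)


@pytest.mark.parametrize("seed", range(12))
def test_assignment_cost_equals_bruteforce_optimum(seed):
    rng = np.random.default_rng(seed)
    r = int(rng.integers(2, 9))       # subgroup of <= 8 patients
    n = int(rng.integers(r, 13))
    sub = _cohort(rng.exponential(12, r).round(2), rng.integers(0, 2, r),
                  subgroup="high", prefix="s")
    allc = _cohort(rng.exponential(12, n).round(2), rng.integers(0, 2, n), prefix="a")
    penalty = STATUS_PENALTY_SCALE * max(sub.time.max(), allc.time.max(), 1.0)
    res = ip.match_subgroup(allc, sub, penalty=penalty)
    # rebuild the exact cost matrix in the solver's sorted order
    sdf = sub.data.sort_values(["time", "event", "patient_id"]).reset_index(drop=True)
    adf = allc.data.sort_values(["time", "event", "patient_id"]).reset_index(drop=True)
    cost_mat = np.abs(sdf["time"].to_numpy()[:, None] - adf["time"].to_numpy()[None, :])
    cost_mat += penalty * (sdf["event"].to_numpy()[:, None] != adf["event"].to_numpy()[None, :])
    assert res.total_cost == pytest.approx(_bruteforce_assignment_cost(cost_mat), rel=1e-12)


def test_small_jitter_keeps_the_assignment():
    rng = np.random.default_rng(4)
    base = np.sort(rng.exponential(12, 12).round(1)) + np.arange(12) * 0.5  # well separated
    events = np.ones(12, int)
    allc = _cohort(base, events, prefix="a")
    sub_idx = [1, 3, 4, 6, 7, 8, 10, 11]
    exact_sub = _cohort(base[sub_idx], events[sub_idx], subgroup="high", prefix="s")
    jit = rng.uniform(-0.05, 0.05, len(sub_idx))
    jit_sub = _cohort(base[sub_idx] + jit, events[sub_idx], subgroup="high", prefix="s")
    res_exact = ip.match_subgroup(allc, exact_sub)
    res_jit = ip.match_subgroup(allc, jit_sub)
    assert sorted(res_exact.pairs["matched_id"]) == sorted(res_jit.pairs["matched_id"])
    assert sorted(res_exact.complement.data["patient_id"]) == sorted(
        res_jit.complement.data["patient_id"]
    )


def test_no_cross_status_match_when_same_status_matching_exists():
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n_ev, n_cen = 6, 6
        all_t = np.concatenate([rng.exponential(10, n_ev), rng.exponential(10, n_cen)])
        all_e = np.array([1] * n_ev + [0] * n_cen)
        allc = _cohort(all_t.round(2), all_e, prefix="a")
        # subgroup status counts compatible with all-comers: perfect
        # same-status matching exists, so none may cross
        sub = _cohort(rng.exponential(10, 4).round(2), [1, 1, 0, 0],
                      subgroup="high", prefix="s")
        res = ip.match_subgroup(allc, sub)
        assert res.n_cross_status == 0


def test_subgroup_larger_than_cohort_raises():
    allc = _cohort([1.0, 2.0], [1, 1], prefix="a")
    sub = _cohort([1.0, 2.0, 3.0], [1, 1, 1], subgroup="high", prefix="s")
    with pytest.raises(ValueError, match="exceeds"):
        ip.match_subgroup(allc, sub)


def test_lossless_pipeline_complement_equals_true_low(small_scenario):
    truth = ip.simulate_trial(small_scenario)
    high = truth.filter(subgroup="high")
    low = truth.filter(subgroup="low")
    derived = ip.derive_low_subgroup(truth, high)
    assert len(derived) == len(low)
    a = np.sort(derived.data[["time", "event"]].to_numpy(), axis=0)
    b = np.sort(low.data[["time", "event"]].to_numpy(), axis=0)
    assert np.array_equal(a, b)


def test_derived_complement_agrees_with_truth_after_reconstruction():
    """Reconstructed-and-subtracted complements are statistically
    indistinguishable from the true biomarker-low cohort (log-rank)."""
    scn = ip.get_preset("orient16_like")
    ok = 0
    reps = 30
    for seed in range(reps):
        truth = ip.simulate_trial(scn.with_seed(seed))
        rng = np.random.default_rng(seed)
        art_all = ip.render_published(truth, noise_sd=0.002, rng=rng)
        art_high = ip.render_published(truth.filter(subgroup="high"),
                                       noise_sd=0.002, rng=rng)
        all_rec, _ = ip.reconstruct_trial(art_all.curves, art_all.risk_table,
                                          art_all.total_events)
        high_rec, _ = ip.reconstruct_trial(art_high.curves, art_high.risk_table,
                                           art_high.total_events)
        derived = ip.derive_low_subgroup(all_rec, high_rec)
        _, p = ip.logrank_test(derived, truth.filter(subgroup="low"))
        ok += p > 0.9
    assert ok / reps >= 0.9


def test_monte_carlo_error_limits_interface(small_scenario):
    with pytest.raises(ValueError, match="iterations"):
        ip.monte_carlo_error_limits(small_scenario, iterations=10)
    lim = ip.monte_carlo_error_limits(small_scenario, iterations=100,
                                      exact_ipd=True, noise_sd=0.0, seed=1)
    assert lim.iterations == 100
    for arm in ("treatment", "control"):
        assert lim.mean_abs_ln_hr[arm] == np.mean(lim.samples[arm])
    # reproducibility under the same seed
    lim2 = ip.monte_carlo_error_limits(small_scenario, iterations=100,
                                       exact_ipd=True, noise_sd=0.0, seed=1)
    assert lim.mean_abs_ln_hr == lim2.mean_abs_ln_hr
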