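"""Quality assessment of reconstruction and matching.

Reproduces the validation battery applied before any pooled analysis:

* concordance of reconstructed HRs and medians with the published values;
* Bland-Altman agreement of follow-up times between matched pairs;
* two-sample Kolmogorov-Smirnov comparison of the matched follow-up-time
  distributions (the ECDF check);
* overlap of the matched cohort with the known subgroup (Cox HR ~ 1,
  log-rank p ~ 1 when matching worked).

Pass thresholds are package policy (the source workflows report only
qualitative "approximating 0/1" behaviour) and are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .survival_core import CoxFit, IPDCohort, fit_cox, fit_km, logrank_test
from .subgroup_subtraction import MatchResult

__all__ = [
    "QCThresholds",
    "QCReport",
    "concordance_report",
    "bland_altman",
    "ecdf_ks",
    "matched_overlap_check",
    "qc_battery",
    "plot_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    """Default QC pass criteria (package policy, all configurable)."""

    max_abs_ln_hr_delta: float = 0.05   # reported-vs-reconstructed HR
    overlap_hr_low: float = 0.9
    overlap_hr_high: float = 1.1
    overlap_min_logrank_p: float = 0.5


@dataclass
class QCReport:
    """Aggregated QC metrics; ``None`` marks a check not assessed."""

    hr_reported: float | None = None
    hr_reconstructed: float | None = None
    abs_ln_hr_delta: float | None = None
    hr_flagged: bool | None = None
    medians_reported: dict | None = None
    medians_reconstructed: dict | None = None
    median_deltas: dict | None = None
    bland_altman: dict | None = None
    ecdf_ks: dict | None = None
    overlap_hr: float | None = None
    overlap_logrank_p: float | None = None
    overlap_pass: bool | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def concordance_report(
    recon: IPDCohort,
    reported: dict | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Compare the reconstructed cohort's HR and per-arm medians with the
    published values.

    ``reported`` may contain ``hr`` and/or ``medians`` (a per-arm mapping);
    absent entries are marked not-assessed rather than failing.
    """
    report = QCReport()
    fit = fit_cox(recon)
    report.hr_reconstructed = fit.hr
    report.medians_reconstructed = {
        arm: fit_km(recon, arm=arm).median for arm in sorted(recon.data["arm"].unique())
    }
    if reported and "hr" in reported and reported["hr"] is not None:
        report.hr_reported = float(reported["hr"])
        report.abs_ln_hr_delta = abs(math.log(fit.hr / report.hr_reported))
        report.hr_flagged = report.abs_ln_hr_delta > thresholds.max_abs_ln_hr_delta
    if reported and "medians" in reported and reported["medians"]:
        report.medians_reported = dict(reported["medians"])
        report.median_deltas = {
            arm: report.medians_reconstructed.get(arm, math.nan) - float(m)
            for arm, m in report.medians_reported.items()
        }
    return report


def bland_altman(pairs: pd.DataFrame) -> tuple[float, float, float, float]:
    """Bland-Altman agreement of matched follow-up times.

    Differences are subgroup time minus matched time. Returns
    ``(mean_diff, sd, loa_low, loa_high)``; the 95% limits of agreement
    are mean +/- 1.96 sd.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    diff = pairs["subgroup_time"].to_numpy() - pairs["matched_time"].to_numpy()
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return (mean, sd, mean - 1.96 * sd, mean + 1.96 * sd)


def mean_absolute_difference(pairs: pd.DataFrame) -> float:
    diff = pairs["subgroup_time"].to_numpy() - pairs["matched_time"].to_numpy()
    return float(np.abs(diff).mean())


def ecdf_ks(pairs: pd.DataFrame) -> tuple[float, float]:
    """Two-sample KS statistic and p between the subgroup and matched
    follow-up-time distributions."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    a = pairs["subgroup_time"].to_numpy()
    b = pairs["matched_time"].to_numpy()
    if np.array_equal(np.sort(a), np.sort(b)):
        return (0.0, 1.0)
    res = ks_2samp(a, b)
    return (float(res.statistic), float(res.pvalue))


def matched_overlap_check(
    matched_cohort: IPDCohort,
    known_subgroup: IPDCohort,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[CoxFit, float, bool]:
    """Cox HR and log-rank p of matched cohort vs known subgroup.

    Successful matching produces near-identical cohorts, hence HR ~ 1 and
    log-rank p ~ 1; the boolean applies the configured pass band.
    """
    time = np.concatenate([matched_cohort.time, known_subgroup.time])
    event = np.concatenate([matched_cohort.event, known_subgroup.event])
    x = np.concatenate([np.ones(len(matched_cohort)), np.zeros(len(known_subgroup))])
    if event.sum() == 0:
        fit = CoxFit(log_hr=0.0, se=math.inf, ties_method="efron",
                     n=len(time), n_events=0, converged=True)
        p = 1.0
    else:
        from .survival_core import cox_newton

        beta, cov, ll, conv, msg = cox_newton(time, event, x)
        fit = CoxFit(
            log_hr=float(beta[0]),
            se=float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else math.inf,
            ties_method="efron", n=len(time), n_events=int(event.sum()),
            converged=conv, message=msg, loglik=ll,
        )
        _, p = logrank_test(matched_cohort, known_subgroup)
    ok = (
        thresholds.overlap_hr_low <= fit.hr <= thresholds.overlap_hr_high
        and p > thresholds.overlap_min_logrank_p
    )
    return fit, p, ok


def qc_battery(
    recon: IPDCohort,
    match: MatchResult,
    known_subgroup: IPDCohort,
    reported: dict | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Run the full validation battery and aggregate into one report."""
    report = concordance_report(recon, reported, thresholds)
    mean, sd, lo, hi = bland_altman(match.pairs)
    report.bland_altman = {
        "mean_diff": mean, "sd": sd, "loa_low": lo, "loa_high": hi,
        "mean_abs_diff": mean_absolute_difference(match.pairs),
    }
    ks, p_ks = ecdf_ks(match.pairs)
    report.ecdf_ks = {"statistic": ks, "p": p_ks}
    fit, p_lr, ok = matched_overlap_check(match.matched_cohort, known_subgroup, thresholds)
    report.overlap_hr = fit.hr
    report.overlap_logrank_p = p_lr
    report.overlap_pass = ok
    return report


def plot_qc(match: MatchResult, out_prefix: str) -> dict[str, str]:
    """Emit the Bland-Altman and ECDF figures plus tidy CSVs of the
    plotted values (assertions belong on the CSVs, not the images)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = match.pairs
    diff = pairs["subgroup_time"].to_numpy() - pairs["matched_time"].to_numpy()
    avg = (pairs["subgroup_time"].to_numpy() + pairs["matched_time"].to_numpy()) / 2
    written = {}

    ba_csv = f"{out_prefix}_bland_altman.csv"
    pd.DataFrame({"mean_time": avg, "difference": diff}).to_csv(ba_csv, index=False)
    written["bland_altman_csv"] = ba_csv
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(avg, diff, s=8, alpha=0.6)
    m, s = diff.mean(), diff.std(ddof=1) if len(diff) > 1 else 0.0
    for y, style in ((m, "-"), (m - 1.96 * s, "--"), (m + 1.96 * s, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("Mean of matched follow-up times (months)")
    ax.set_ylabel("Difference (subgroup - matched)")
    fig.tight_layout()
    ba_png = f"{out_prefix}_bland_altman.png"
    fig.savefig(ba_png, dpi=120)
    plt.close(fig)
    written["bland_altman_png"] = ba_png

    ecdf_csv = f"{out_prefix}_ecdf.csv"
    rows = []
    for label, col in (("subgroup", "subgroup_time"), ("matched", "matched_time")):
        x = np.sort(pairs[col].to_numpy())
        rows.append(pd.DataFrame({"group": label, "time": x,
                                  "ecdf": np.arange(1, len(x) + 1) / len(x)}))
    pd.concat(rows, ignore_index=True).to_csv(ecdf_csv, index=False)
    written["ecdf_csv"] = ecdf_csv
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, col in (("subgroup", "subgroup_time"), ("matched", "matched_time")):
        x = np.sort(pairs[col].to_numpy())
        ax.step(x, np.arange(1, len(x) + 1) / len(x), where="post", label=label)
    ax.set_xlabel("Follow-up time (months)")
    ax.set_ylabel("ECDF")
    ax.legend()
    fig.tight_layout()
    ecdf_png = f"{out_prefix}_ecdf.png"
    fig.savefig(ecdf_png, dpi=120)
    plt.close(fig)
    written["ecdf_png"] = ecdf_png
    return written
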