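"""Core survival statistics shared by every pipeline stage.

Provides the patient-level data containers (:class:`SurvivalRecord`,
:class:`IPDCohort`), the Kaplan-Meier product-limit estimator with
Brookmeyer-Crowley median confidence intervals, the two-sample log-rank
test, and a Cox proportional-hazards engine.

The Cox engine is implemented here (Newton-Raphson on the partial
likelihood, Efron or Breslow tie handling) rather than delegated, because
the shared-frailty estimator in :mod:`ipdpool.pooled_frailty` requires
log-frailty offsets in the linear predictor and access to the baseline
cumulative hazard, neither of which the usual high-level fitters expose.
Times are in months throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARM_TREATMENT",
    "ARM_CONTROL",
    "SUBGROUP_HIGH",
    "SUBGROUP_LOW",
    "SUBGROUP_UNKNOWN",
    "SurvivalRecord",
    "IPDCohort",
    "KMEstimate",
    "CoxFit",
    "fit_km",
    "median_survival_ci",
    "logrank_test",
    "fit_cox",
    "cox_newton",
    "breslow_cumhaz",
    "PartialLikelihood",
]

# Canonical labels -----------------------------------------------------------

ARM_TREATMENT = "treatment"
ARM_CONTROL = "control"
ARMS = (ARM_TREATMENT, ARM_CONTROL)

SUBGROUP_HIGH = "high"      # e.g. PD-L1 CPS >= 5
SUBGROUP_LOW = "low"        # e.g. PD-L1 CPS < 5
SUBGROUP_UNKNOWN = "unknown"
SUBGROUPS = (SUBGROUP_HIGH, SUBGROUP_LOW, SUBGROUP_UNKNOWN)

ENDPOINTS = ("OS", "PFS")

IPD_COLUMNS = ["patient_id", "time", "event", "arm", "study", "subgroup", "endpoint"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: observed follow-up time (months) and event status."""

    patient_id: str
    time: float
    event: int
    arm: str
    study: str = ""
    subgroup: str = SUBGROUP_UNKNOWN
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.time < 0 or not math.isfinite(self.time):
            raise ValueError(f"invalid time {self.time!r} for {self.patient_id!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event!r}")
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"subgroup must be one of {SUBGROUPS}, got {self.subgroup!r}")


@dataclass
class IPDCohort:
    """An ordered collection of patient records sharing one endpoint.

    Wraps a :class:`pandas.DataFrame` with the canonical IPD columns.
    ``provenance`` records how the cohort arose: ``simulated``,
    ``reconstructed`` or ``derived-complement``.
    """

    data: pd.DataFrame
    study: str = ""
    endpoint: str = "OS"
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in IPD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"IPD frame missing columns {missing}")
        # an empty cohort is a legal container (e.g. an empty matching
        # complement); estimation entry points reject it
        if len(df):
            if (df["time"] < 0).any() or not np.isfinite(df["time"].to_numpy(dtype=float)).all():
                raise ValueError("invalid time")
            if not df["event"].isin([0, 1]).all():
                raise ValueError("event must be 0/1")
            endpoints = df["endpoint"].unique()
            if len(endpoints) > 1:
                raise ValueError(f"cohort mixes endpoints {sorted(endpoints)}")
        self.data = df.reset_index(drop=True)

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[SurvivalRecord], *, provenance: str = "simulated") -> "IPDCohort":
        rows = [
            (r.patient_id, r.time, r.event, r.arm, r.study, r.subgroup, r.endpoint)
            for r in records
        ]
        if not rows:
            raise ValueError("empty cohort")
        df = pd.DataFrame(rows, columns=IPD_COLUMNS)
        return cls(df, study=df["study"].iloc[0], endpoint=df["endpoint"].iloc[0], provenance=provenance)

    @classmethod
    def from_arrays(
        cls,
        time: Sequence[float],
        event: Sequence[int],
        arm: Sequence[str],
        *,
        study: str = "",
        subgroup: Sequence[str] | str = SUBGROUP_UNKNOWN,
        endpoint: str = "OS",
        provenance: str = "simulated",
        patient_id: Sequence[str] | None = None,
    ) -> "IPDCohort":
        n = len(time)
        if patient_id is None:
            patient_id = [f"P{i + 1:05d}" for i in range(n)]
        if isinstance(subgroup, str):
            subgroup = [subgroup] * n
        df = pd.DataFrame(
            {
                "patient_id": list(patient_id),
                "time": np.asarray(time, dtype=float),
                "event": np.asarray(event, dtype=int),
                "arm": list(arm),
                "study": study,
                "subgroup": list(subgroup),
                "endpoint": endpoint,
            }
        )
        return cls(df, study=study, endpoint=endpoint, provenance=provenance)

    # -- accessors -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def filter(self, *, arm: str | None = None, subgroup: str | None = None, study: str | None = None) -> "IPDCohort":
        """Restrict to one arm/subgroup/study; raises if nothing remains."""
        mask = np.ones(len(self.data), dtype=bool)
        if arm is not None:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
            mask &= (self.data["arm"] == arm).to_numpy()
        if subgroup is not None:
            mask &= (self.data["subgroup"] == subgroup).to_numpy()
        if study is not None:
            mask &= (self.data["study"] == study).to_numpy()
        if not mask.any():
            raise ValueError("empty cohort")
        return replace(self, data=self.data.loc[mask].reset_index(drop=True))

    def relabel(self, **fields: str) -> "IPDCohort":
        df = self.data.copy()
        for col, value in fields.items():
            if col not in IPD_COLUMNS:
                raise ValueError(f"unknown field {col!r}")
            df[col] = value
        out = replace(self, data=df)
        if "study" in fields:
            out.study = fields["study"]
        if "endpoint" in fields:
            out.endpoint = fields["endpoint"]
        return out


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMEstimate:
    """Product-limit estimate over the distinct event times.

    ``n_censored`` counts censorings in the half-open interval
    ``[t_k, t_{k+1})`` (the last entry absorbs everything after the final
    event time), so the accounting identity
    ``n_at_risk[k+1] = n_at_risk[k] - n_events[k] - n_censored[k]`` holds
    exactly. ``median`` is the smallest t with S(t) <= 0.5, ``inf`` when
    the curve never reaches 0.5; CI bounds use the same convention.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    n_total: int
    median: float
    median_ci: tuple[float, float]

    def survival_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Step-function value S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, np.concatenate([[1.0], self.survival])[idx + 1])
        return float(s) if s.ndim == 0 else s


def _km_median(times: np.ndarray, surv: np.ndarray) -> float:
    below = surv <= 0.5 + 1e-12
    if not below.any():
        return math.inf
    return float(times[np.argmax(below)])


def fit_km(cohort: IPDCohort, arm: str | None = None, alpha: float = 0.05) -> KMEstimate:
    """Kaplan-Meier estimate for a cohort (optionally one arm).

    Censored observations reduce the risk set but contribute no step; tied
    events at one time are aggregated into a single multiplicity-d step.
    """
    sub = cohort.filter(arm=arm) if arm is not None else cohort
    if len(sub) == 0:
        raise ValueError("empty cohort")
    time, event = sub.time, sub.event
    n = len(time)

    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]

    ev_times = np.unique(t_sorted[e_sorted == 1])
    # at risk at t: everyone with observed time >= t
    n_at_risk = n - np.searchsorted(t_sorted, ev_times, side="left")
    n_events = np.array(
        [int(((t_sorted == t) & (e_sorted == 1)).sum()) for t in ev_times], dtype=int
    )

    if len(ev_times) == 0:
        return KMEstimate(
            event_times=np.empty(0),
            survival=np.empty(0),
            n_at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            n_censored=np.empty(0, dtype=int),
            n_total=n,
            median=math.inf,
            median_ci=(math.inf, math.inf),
        )

    surv = np.cumprod(1.0 - n_events / n_at_risk)

    # censorings per half-open inter-event interval [t_k, t_{k+1})
    nxt = np.append(n_at_risk[1:], 0)
    n_censored = n_at_risk - n_events - nxt
    # events censored exactly at the last event time or later, minus the
    # patients who are simply past follow-up, are all "after last event"
    n_censored[-1] = n_at_risk[-1] - n_events[-1]

    median = _km_median(ev_times, surv)
    ci = median_survival_ci_from_arrays(time, event, alpha=alpha)
    return KMEstimate(
        event_times=ev_times,
        survival=surv,
        n_at_risk=n_at_risk,
        n_events=n_events,
        n_censored=n_censored,
        n_total=n,
        median=median,
        median_ci=ci,
    )


def median_survival_ci_from_arrays(
    time: np.ndarray, event: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Brookmeyer-Crowley median CI via the complementary log-log band."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    if event.sum() == 0:
        return (math.inf, math.inf)
    kmf = KaplanMeierFitter(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(time, event)
        band = median_survival_times(kmf.confidence_interval_)
    lo = float(band.iloc[0, 0])
    hi = float(band.iloc[0, 1])
    return (lo, hi)


def median_survival_ci(
    cohort: IPDCohort, arm: str | None = None, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Median survival and its (1-alpha) CI; open bounds are ``inf``."""
    sub = cohort.filter(arm=arm) if arm is not None else cohort
    km = fit_km(sub, alpha=alpha)
    return (km.median, km.median_ci[0], km.median_ci[1])


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


def logrank_test(a: IPDCohort, b: IPDCohort) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and two-sided p-value."""
    from lifelines.statistics import logrank_test as _ll_logrank

    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty cohort")
    if a.event.sum() == 0 and b.event.sum() == 0:
        return (0.0, 1.0)
    res = _ll_logrank(a.time, b.time, event_observed_A=a.event, event_observed_B=b.event)
    return (float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox model for a single binary covariate (or one coefficient
    of interest from a larger design)."""

    log_hr: float
    se: float
    ties_method: str
    n: int
    n_events: int
    converged: bool = True
    message: str = ""
    loglik: float = math.nan

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.log_hr - 1.959963984540054 * self.se),
                math.exp(self.log_hr + 1.959963984540054 * self.se))

    @property
    def z(self) -> float:
        return self.log_hr / self.se if self.se > 0 else math.inf

    @property
    def p_value(self) -> float:
        from scipy.stats import norm

        if self.se <= 0:
            return math.nan
        return float(2.0 * norm.sf(abs(self.z)))


class PartialLikelihood:
    """Pre-sorted Cox partial-likelihood workspace.

    Prepared once per dataset/ties-method; evaluation methods take ``beta``
    and an optional offset so the frailty EM can re-evaluate cheaply with
    changing log-frailty offsets.
    """

    def __init__(self, time, event, X, ties: str = "efron"):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}")
        self.ties = ties
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order]
        self.X = X[self.order]
        self.n, self.p = self.X.shape

        ev_mask = self.event == 1
        ev_t = self.time[ev_mask]
        self.ev_idx = np.nonzero(ev_mask)[0]
        uniq, grp_start = np.unique(ev_t, return_index=True)
        grp_size = np.diff(np.append(grp_start, len(ev_t)))
        self.uniq_times = uniq
        self.grp_start = grp_start
        self.grp_size = grp_size
        self.risk_start = np.searchsorted(self.time, uniq, side="left")
        self.row_grp = np.repeat(np.arange(len(uniq)), grp_size)
        if ties == "efron":
            within = np.arange(len(ev_t)) - np.repeat(grp_start, grp_size)
            self.row_frac = within / np.repeat(grp_size, grp_size)
        else:
            self.row_frac = np.zeros(len(ev_t))
        self.XX = self.X[:, :, None] * self.X[:, None, :]
        self.x_ev = self.X[self.ev_idx]
        self.XX_ev = self.XX[self.ev_idx]
        self.x_ev_sum = self.x_ev.sum(axis=0)

    def sort_offset(self, offset) -> np.ndarray:
        """Re-order a user-supplied offset to the internal sort order."""
        return np.asarray(offset, dtype=float)[self.order]

    def _risk_quantities(self, beta, offset_sorted):
        eta = self.X @ beta if offset_sorted is None else self.X @ beta + offset_sorted
        eta = np.clip(eta, -500, 500)
        r = np.exp(eta)
        S0 = np.cumsum(r[::-1])[::-1]
        r_ev = r[self.ev_idx]
        D0 = np.add.reduceat(r_ev, self.grp_start)
        phi0 = S0[self.risk_start[self.row_grp]] - self.row_frac * D0[self.row_grp]
        return eta, r, r_ev, phi0

    def loglik_score_info(self, beta, offset_sorted=None):
        """Log partial likelihood, score vector and observed information."""
        eta, r, r_ev, phi0 = self._risk_quantities(beta, offset_sorted)
        S1 = np.cumsum((r[:, None] * self.X)[::-1], axis=0)[::-1]
        S2 = np.cumsum((r[:, None, None] * self.XX)[::-1], axis=0)[::-1]
        D1 = np.add.reduceat(r_ev[:, None] * self.x_ev, self.grp_start, axis=0)
        D2 = np.add.reduceat(r_ev[:, None, None] * self.XX_ev, self.grp_start, axis=0)

        g = self.row_grp
        f = self.row_frac[:, None]
        rs = self.risk_start[g]
        phi1 = S1[rs] - f * D1[g]
        phi2 = S2[rs] - f[:, :, None] * D2[g]

        loglik = float(eta[self.ev_idx].sum() - np.log(phi0).sum())
        ratio1 = phi1 / phi0[:, None]
        score = self.x_ev_sum - ratio1.sum(axis=0)
        info = (phi2 / phi0[:, None, None]).sum(axis=0) - (
            ratio1[:, :, None] * ratio1[:, None, :]
        ).sum(axis=0)
        return loglik, score, info

    def newton(self, beta0=None, offset_sorted=None, max_iter=50, tol=1e-9):
        """Newton-Raphson maximization; returns
        ``(beta, cov, loglik, converged, message)``."""
        beta = np.zeros(self.p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        ll, score, info = self.loglik_score_info(beta, offset_sorted)
        message = ""
        converged = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                return beta, np.full((self.p, self.p), np.nan), ll, False, "singular information matrix"
            for _half in range(30):
                cand = beta + step
                ll_new, score_new, info_new = self.loglik_score_info(cand, offset_sorted)
                if ll_new >= ll - 1e-12:
                    break
                step = step / 2.0
            delta_ll = ll_new - ll
            beta, ll, score, info = cand, ll_new, score_new, info_new
            if np.abs(score).max() < tol or abs(delta_ll) < 1e-13:
                converged = True
                break
        if np.abs(beta).max() > 20:
            converged = False
            message = "monotone likelihood (complete separation): estimates diverge"
        if not converged and not message:
            message = f"Newton-Raphson did not converge in {max_iter} iterations"
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((self.p, self.p), np.nan)
        return beta, cov, ll, converged, message

    def cumhaz(self, beta, offset_sorted=None):
        """Baseline cumulative-hazard jumps at the distinct event times
        (Efron-corrected denominators under Efron ties)."""
        _, _, _, phi0 = self._risk_quantities(np.atleast_1d(beta), offset_sorted)
        jumps = np.zeros(len(self.grp_start))
        np.add.at(jumps, self.row_grp, 1.0 / phi0)
        return self.uniq_times, jumps


def cox_newton(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    *,
    offset: np.ndarray | None = None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
):
    """Maximise the Cox partial likelihood by Newton-Raphson.

    Returns ``(beta, cov, loglik, converged, message)``. ``X`` is (n, p);
    ``offset`` adds a fixed term to the linear predictor (used for the
    frailty EM M-step).
    """
    pl = PartialLikelihood(time, event, X, ties=ties)
    off = None if offset is None else pl.sort_offset(offset)
    return pl.newton(offset_sorted=off, max_iter=max_iter, tol=tol)


def breslow_cumhaz(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    *,
    offset: np.ndarray | None = None,
    ties: str = "efron",
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline cumulative-hazard jumps at the distinct event times.

    Efron ties use the Efron-corrected denominators; Breslow the plain risk
    sums. Returns ``(event_times, jumps)``.
    """
    pl = PartialLikelihood(time, event, X, ties=ties)
    off = None if offset is None else pl.sort_offset(offset)
    return pl.cumhaz(beta, off)


def fit_cox(
    cohort: IPDCohort,
    covariate: str | np.ndarray = "arm",
    *,
    ties: str = "efron",
) -> CoxFit:
    """Cox PH fit for a single binary covariate (default: treatment arm).

    ``covariate`` may be the name ``"arm"`` (treatment=1 vs control=0), a
    column name with exactly two levels, or an explicit 0/1 array aligned
    with the cohort rows.
    """
    if isinstance(covariate, str):
        if covariate == "arm":
            x = (cohort.data["arm"] == ARM_TREATMENT).to_numpy(dtype=float)
        else:
            col = cohort.data[covariate]
            levels = sorted(col.unique())
            if len(levels) != 2:
                raise ValueError(f"covariate {covariate!r} must have 2 levels, has {levels}")
            x = (col == levels[1]).to_numpy(dtype=float)
    else:
        x = np.asarray(covariate, dtype=float)
        if len(x) != len(cohort):
            raise ValueError("covariate length mismatch")

    time, event = cohort.time, cohort.event
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("no events in cohort")
    if len(np.unique(x)) < 2:
        raise ValueError("covariate is constant")

    beta, cov, ll, converged, message = cox_newton(time, event, x, ties=ties)
    se = float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else math.nan
    return CoxFit(
        log_hr=float(beta[0]),
        se=se,
        ties_method=ties,
        n=len(cohort),
        n_events=n_events,
        converged=converged,
        message=message,
        loglik=ll,
    )
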