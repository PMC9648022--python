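"""Prognostic evaluation: censoring rule, Kaplan-Meier/log-rank, maximally
selected marker cutpoints, multivariate Cox regression, and IPCW
time-dependent AUC.

Follow-up is administratively censored at 5 years (60 months).  Markers are
dichotomized at the cutoff maximizing the absolute standardized log-rank
statistic (maximally selected rank statistic); the naive p at the selected
cutoff is selection-inflated and flagged as such, with a permutation null
available.  Cox models use Efron tie handling.  The time-dependent AUC is the
cumulative/dynamic estimator with inverse-probability-of-censoring weights
from the Kaplan-Meier censoring distribution; nested models are compared at
each evaluation time by paired bootstrap with Holm adjustment across times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .io import SurvivalCohort, logger

FIVE_YEARS_MONTHS = 60.0


def apply_censor_rule(cohort: SurvivalCohort, horizon: float = FIVE_YEARS_MONTHS) -> SurvivalCohort:
    """Administrative censoring: times beyond the horizon are truncated to the
    horizon with event = 0; the boundary itself is untouched (inclusive)."""
    df = cohort.data.copy()
    over = df["time_months"] > horizon
    df.loc[over, "time_months"] = horizon
    df.loc[over, "event"] = 0
    if over.any():
        logger.info("censored %d records at %.0f months", int(over.sum()), horizon)
    return SurvivalCohort(data=df, endpoint=cohort.endpoint)


@dataclass
class KMCurve:
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray


def km_estimate(time, event) -> KMCurve:
    """Product-limit survival estimate."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    censor_times = np.sort(np.asarray(time, dtype=float)[np.asarray(event) == 0])
    return KMCurve(
        times=table.index.to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(),
        survival=surv,
        censor_times=censor_times,
    )


def _logrank_zstat(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic z = (O1 - E1)/sqrt(V)."""
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order].astype(bool)
    uniq = np.unique(time[event == 1])
    o = e = v = 0.0
    for t in uniq:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        dead = (time == t) & (event == 1)
        d = dead.sum()
        d1 = (dead & group).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0
    return float((o - e) / np.sqrt(v))


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if len(np.unique(group)) != 2 or min((group == g).sum() for g in np.unique(group)) == 0:
        raise ValueError("need two non-empty groups")
    if event.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    z = _logrank_zstat(time, event, group == np.unique(group)[1])
    chi2 = z * z
    return chi2, float(stats.chi2.sf(chi2, 1))


@dataclass
class CutpointResult:
    cutoff: float
    zstat: float
    chi2: float
    naive_p: float
    selection_inflated: bool
    n_low: int
    n_high: int
    permutation_p: float | None = None


def optimal_cutpoint(
    time,
    event,
    marker,
    minprop: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous marker.

    Every distinct marker value is a candidate cutoff (high group = marker >
    cutoff) provided both sides keep at least ``minprop`` of the cohort; the
    cutoff maximizing |z| wins, smallest value on ties.  The naive p carries a
    ``selection_inflated`` flag; an unbiased permutation p over the maximal
    statistic is computed when ``n_permutations`` > 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    marker = np.asarray(marker, dtype=float)
    n = len(marker)
    min_n = minprop * n

    def scan(m: np.ndarray) -> tuple[float, float] | None:
        best: tuple[float, float] | None = None  # (|z|, cutoff); keeps smallest cutoff on ties
        for c in np.unique(m)[:-1]:
            high = m > c
            if high.sum() < min_n or (~high).sum() < min_n:
                continue
            z = _logrank_zstat(time, event, high)
            if best is None or abs(z) > best[0] + 1e-12:
                best = (abs(z), float(c), z)
        return best

    best = scan(marker)
    if best is None:
        raise ValueError("no cutoff satisfies the minprop constraint")
    absz, cutoff, z = best
    chi2 = z * z
    result = CutpointResult(
        cutoff=cutoff,
        zstat=z,
        chi2=chi2,
        naive_p=float(stats.chi2.sf(chi2, 1)),
        selection_inflated=True,
        n_low=int((marker <= cutoff).sum()),
        n_high=int((marker > cutoff).sum()),
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = scan(rng.permutation(marker))
            if perm is not None and perm[0] >= absz - 1e-12:
                count += 1
        result.permutation_p = (1 + count) / (1 + n_permutations)
    return result


@dataclass
class CoxResult:
    summary: pd.DataFrame  # index covariate; columns beta, hr, ci_low, ci_high, p
    log_likelihood: float
    fitter: CoxPHFitter = field(repr=False, default=None)


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str, covariates: list[str]) -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    Raises on non-convergence and on quasi-separation (|beta| > 15).
    """
    data = df[[duration_col, event_col, *covariates]].copy()
    if data[event_col].sum() < 1:
        raise ValueError("need at least one event")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(
            data,
            duration_col=duration_col,
            event_col=event_col,
            fit_options={"precision": 1e-9},
        )
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    betas = cph.params_
    if (betas.abs() > 15).any():
        bad = list(betas.index[betas.abs() > 15])
        raise RuntimeError(f"separation detected (|beta| > 15) for covariates {bad}")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(summary=summary, log_likelihood=float(cph.log_likelihood_), fitter=cph)


# ---------------------------------------------------------------------------
# IPCW time-dependent AUC
# ---------------------------------------------------------------------------

def _censor_survival(time: np.ndarray, event: np.ndarray):
    """KM estimate of the censoring distribution G; returns step-function
    evaluators G(t) (right-continuous) and G(t-) (left limit).  Censoring at a
    tied time is taken to occur after events (events at t stay in the censor
    risk set at t)."""
    uniq = np.unique(time)
    g = 1.0
    steps_t, steps_g = [0.0], [1.0]
    for t in uniq:
        at_risk = (time >= t).sum()
        c = ((time == t) & (event == 0)).sum()
        if c and at_risk:
            g *= 1 - c / at_risk
            steps_t.append(t)
            steps_g.append(g)
    steps_t = np.asarray(steps_t)
    steps_g = np.asarray(steps_g)

    def right(q):
        idx = np.searchsorted(steps_t, q, side="right") - 1
        return steps_g[np.maximum(idx, 0)]

    def left(q):
        idx = np.searchsorted(steps_t, q, side="left") - 1
        return steps_g[np.maximum(idx, 0)]

    return right, left


def ipcw_auc(time, event, risk, t: float) -> float:
    """Cumulative/dynamic AUC at time t with IPCW weights.

    Cases are subjects with an observed event by t (weight 1/G(T-)); controls
    are subjects event-free through t — observed beyond t, or censored at
    exactly t (so the administrative-horizon time itself is evaluable); tied
    risk scores count 1/2.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    g_right, g_left = _censor_survival(time, event)
    cases = (time <= t) & (event == 1)
    controls = (time > t) | ((time == t) & (event == 0))
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError(f"no cases or no controls at t={t}")
    w_case = 1.0 / g_left(time[cases])
    # the common control weight cancels in the ratio; fall back to the left
    # limit when the censoring KM hits zero at an administrative horizon
    g_t = g_right(np.array([t]))[0] or g_left(np.array([t]))[0] or 1.0
    w_ctrl = np.full(controls.sum(), 1.0 / g_t)
    rc = risk[cases][:, None]
    rt = risk[controls][None, :]
    conc = (rc > rt) + 0.5 * (rc == rt)
    w = w_case[:, None] * w_ctrl[None, :]
    return float((conc * w).sum() / w.sum())


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def time_dependent_auc(
    time,
    event,
    risk,
    times=(12, 24, 36, 48, 60),
) -> pd.DataFrame:
    """IPCW cumulative/dynamic AUC(t) over a grid of evaluation months."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    times = np.asarray(times, dtype=float)
    if times.max() > time.max():
        raise ValueError("evaluation times exceed observed follow-up")
    if not ((time <= times.min()) & (event == 1)).any():
        raise ValueError("no events before the first evaluation time")
    aucs = [ipcw_auc(time, event, risk, t) for t in times]
    return pd.DataFrame({"time_months": times, "auc": aucs})


def compare_time_dependent_auc(
    time,
    event,
    risk_full,
    risk_reduced,
    times=(12, 24, 36, 48, 60),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired-bootstrap comparison of two risk scores' AUC(t) with Holm
    adjustment across evaluation times.

    The p at each time is the normal-approximation two-sided p from the
    bootstrap standard error of the paired AUC difference.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk_full = np.asarray(risk_full, dtype=float)
    risk_reduced = np.asarray(risk_reduced, dtype=float)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(time)

    obs_full = np.array([ipcw_auc(time, event, risk_full, t) for t in times])
    obs_red = np.array([ipcw_auc(time, event, risk_reduced, t) for t in times])
    diffs = np.full((n_boot, len(times)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        for j, t in enumerate(times):
            try:
                diffs[b, j] = ipcw_auc(time[idx], event[idx], risk_full[idx], t) - ipcw_auc(
                    time[idx], event[idx], risk_reduced[idx], t
                )
            except ValueError:
                continue
    se = np.nanstd(diffs, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs_full - obs_red) / se
    p = 2 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "time_months": times,
            "auc_full": obs_full,
            "auc_reduced": obs_red,
            "diff": obs_full - obs_red,
            "p": p,
            "p_holm": holm_adjust(p),
        }
    )
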