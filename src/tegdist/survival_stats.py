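"""Survival-analysis primitives.

Kaplan–Meier estimation and the log-rank test are delegated to
lifelines; on top of those this module provides

* Harrell's concordance index with an asymptotic (Noether/U-statistic)
  standard error, 95% CI and a two-sided p-value against c = 0.5,
* an inverse-probability-of-censoring-weighted (IPCW) Brier score for a
  scalar risk score, obtained by first converting the score into
  per-subject survival probabilities through a single-covariate
  proportional-hazards fit (Efron ties, Breslow baseline) and then
  scoring those probabilities against observed status,
* the Kaplan–Meier-based cumulative-case / dynamic-control
  time-dependent ROC curve (Heagerty–Lumley–Pepe) and its AUC.

Ties between an event and a censoring at the same time follow the
standard convention: events precede censorings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import brier_score as _sksurv_brier
from sksurv.util import Surv


@dataclass
class SurvivalData:
    """Right-censored follow-up: times in days, events True = death."""

    times: np.ndarray
    events: np.ndarray
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape or self.times.ndim != 1:
            raise ValueError("times and events must be 1-D and aligned")
        if len(self.times) < 2:
            raise ValueError("need at least 2 subjects")
        if np.any(self.times <= 0):
            raise ValueError("all times must be positive")
        if self.sample_ids is not None and len(self.sample_ids) != len(self.times):
            raise ValueError("sample_ids misaligned")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class KMCurve:
    """Product-limit survival curve as a right-continuous step function."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    no_events: bool = False

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


@dataclass
class ConcordanceResult:
    c: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_pairs_used: int


@dataclass
class BrierResult:
    eval_times: np.ndarray
    brier_at_t: np.ndarray
    integrated: float


def km_estimate(d: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    kmf = KaplanMeierFitter()
    kmf.fit(d.times, event_observed=d.events)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index and \
        0.0 not in d.times else kmf.event_table
    times = np.asarray(table.index, dtype=float)
    surv = np.asarray(
        kmf.survival_function_.loc[table.index, "KM_estimate"], dtype=float
    )
    at_risk = np.asarray(table["at_risk"], dtype=float)
    return KMCurve(event_times=times, survival_probs=surv, at_risk=at_risk,
                   no_events=not bool(d.events.any()))


def logrank_test(groups: Sequence[SurvivalData]) -> LogrankResult:
    """k-sample log-rank test with hypergeometric variance."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group")
    times = np.concatenate([g.times for g in groups])
    events = np.concatenate([g.events for g in groups])
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    if not events.any():
        return LogrankResult(chi2=0.0, df=len(groups) - 1, p=1.0)
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(chi2=float(res.test_statistic), df=len(groups) - 1,
                         p=float(res.p_value))


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def _pair_tallies(scores: np.ndarray, d: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    """Per-ordered-pair concordance weight and usability indicator.

    Pair (i, j) is usable when subject i's event is observed and either
    t_i < t_j, or t_i == t_j with j censored (events precede
    censorings).  Tied scores contribute 1/2.
    """
    t, e, s = d.times, d.events, scores
    lt = t[:, None] < t[None, :]
    tie_ec = (t[:, None] == t[None, :]) & (~e)[None, :]
    usable = e[:, None] & (lt | tie_ec)
    np.fill_diagonal(usable, False)
    conc = np.where(s[:, None] > s[None, :], 1.0,
                    np.where(s[:, None] == s[None, :], 0.5, 0.0))
    return conc, usable


def concordance_index(scores: Sequence[float], d: SurvivalData) -> ConcordanceResult:
    """Harrell's C for a risk score (higher score = higher risk).

    The standard error is the Noether-type U-statistic estimator of
    Pencina & D'Agostino, computed from per-subject concordant /
    usable-pair averages; the p-value is the two-sided normal test of
    c = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != d.times.shape:
        raise ValueError("scores misaligned with survival data")
    conc, usable = _pair_tallies(scores, d)
    # symmetrize: count each unordered pair once, from its usable direction
    w = usable.astype(float)
    n_pairs = int(w.sum())
    if n_pairs == 0:
        raise ValueError("no usable pairs under censoring")
    c = float((conc * w).sum() / n_pairs)

    n = len(d)
    # per-subject average concordant / discordant probabilities over both
    # pair orientations (pair (i,j) usable one way contributes to both i, j)
    cw = conc * w
    dw = (1.0 - conc) * w
    pc_i = (cw.sum(axis=1) + cw.sum(axis=0)) / (n - 1)
    pd_i = (dw.sum(axis=1) + dw.sum(axis=0)) / (n - 1)
    pc, pdd = pc_i.mean(), pd_i.mean()
    wsum = pc + pdd
    s_cc = np.mean((pc_i - pc) ** 2)
    s_dd = np.mean((pd_i - pdd) ** 2)
    s_cd = np.mean((pc_i - pc) * (pd_i - pdd))
    var = 4.0 * (pdd**2 * s_cc - 2 * pc * pdd * s_cd + pc**2 * s_dd) / (wsum**4) / n
    se = float(np.sqrt(max(var, 0.0)))
    ci_low = max(0.0, c - 1.959963984540054 * se)
    ci_high = min(1.0, c + 1.959963984540054 * se)
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(c - 0.5) / se))
    else:
        p = 1.0 if c == 0.5 else 0.0
    return ConcordanceResult(c=c, se=se, ci_low=ci_low, ci_high=ci_high,
                             p=p, n_pairs_used=n_pairs)


def bootstrap_concordance_ci(
    scores: Sequence[float], d: SurvivalData, n_boot: int = 500, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for Harrell's C (alternative to the
    asymptotic interval)."""
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(d)
    cs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot = SurvivalData(d.times[idx], d.events[idx])
            cs.append(concordance_index(scores[idx], boot).c)
        except ValueError:
            continue
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------

def _validate_eval_times(d: SurvivalData, eval_times: np.ndarray) -> None:
    lo, hi = d.times.min(), d.times.max()
    if np.any(eval_times < lo) or np.any(eval_times >= hi):
        raise ValueError(
            f"eval_times must lie within observed follow-up [{lo}, {hi})"
        )


def ipcw_brier(
    surv_probs: np.ndarray, d: SurvivalData, eval_times: Sequence[float]
) -> BrierResult:
    """IPCW Brier score of given survival probabilities.

    ``surv_probs`` has shape (n_subjects, n_eval_times): predicted
    P(T > t) per subject at each evaluation time.  Censoring weights
    come from the Kaplan–Meier estimate of the censoring distribution
    on the same data.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    _validate_eval_times(d, eval_times)
    surv_probs = np.asarray(surv_probs, dtype=float)
    if surv_probs.shape != (len(d), len(eval_times)):
        raise ValueError("surv_probs must be (n_subjects, n_eval_times)")
    y = Surv.from_arrays(event=d.events, time=d.times)
    times, scores = _sksurv_brier(y, y, surv_probs, eval_times)
    if len(eval_times) > 1:
        integrated = float(np.trapezoid(scores, times) / (times[-1] - times[0]))
    else:
        integrated = float(scores[0])
    return BrierResult(eval_times=times, brier_at_t=np.asarray(scores),
                       integrated=integrated)


def score_to_survival_probs(
    scores: Sequence[float], d: SurvivalData, eval_times: Sequence[float]
) -> np.ndarray:
    """Convert a scalar risk score to survival probabilities via a
    single-covariate proportional-hazards fit (Efron ties, Breslow
    baseline)."""
    scores = np.asarray(scores, dtype=float)
    eval_times = np.asarray(eval_times, dtype=float)
    df = pd.DataFrame({"time": d.times, "event": d.events.astype(int),
                       "score": scores})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            f"proportional-hazards fit did not converge: {err}"
        ) from err
    sf = cph.predict_survival_function(df, times=eval_times)
    return sf.to_numpy().T  # (n_subjects, n_times)


def brier_score(
    scores: Sequence[float], d: SurvivalData, eval_times: Sequence[float]
) -> BrierResult:
    """IPCW Brier score of a scalar risk score (higher = higher risk)."""
    eval_times = np.asarray(eval_times, dtype=float)
    _validate_eval_times(d, eval_times)
    probs = score_to_survival_probs(scores, d, eval_times)
    return ipcw_brier(probs, d, eval_times)


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

def _km_at(times: np.ndarray, events: np.ndarray, t: float) -> float:
    """Product-limit survival at t (events precede censorings at ties)."""
    if len(times) == 0:
        return 1.0
    s = 1.0
    for u in np.unique(times[events & (times <= t)]):
        at_risk = np.sum(times >= u)
        d_u = np.sum((times == u) & events)
        if at_risk > 0:
            s *= 1.0 - d_u / at_risk
    return float(s)


def time_dependent_roc(
    scores: Sequence[float], d: SurvivalData, t: float
) -> tuple[float, list[tuple[float, float, float]]]:
    """Cumulative-case / dynamic-control ROC at horizon ``t``.

    Uses the Kaplan–Meier estimator of Heagerty, Lumley & Pepe: with
    S(t) the overall KM curve and S_c(t) the KM curve among subjects
    with score > c,

        TPR(c) = (1 - S_c(t)) * P(score > c) / (1 - S(t))
        FPR(c) =      S_c(t)  * P(score > c) / S(t)

    Returns the trapezoidal AUC and the ROC points as
    ``(fpr, tpr, cutoff)`` in path order (descending cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != d.times.shape:
        raise ValueError("scores misaligned with survival data")
    s_t = _km_at(d.times, d.events, t)
    if s_t >= 1.0:
        raise ValueError(f"no cases (events) by t = {t}")
    if s_t <= 0.0:
        raise ValueError(f"no controls beyond t = {t}")
    n = len(d)
    points = [(1.0, 1.0, -np.inf)]
    for c in np.unique(scores):
        above = scores > c
        p_c = above.mean()
        if p_c == 0.0:
            s_c = 1.0
        else:
            s_c = _km_at(d.times[above], d.events[above], t)
        tpr = (1.0 - s_c) * p_c / (1.0 - s_t)
        fpr = s_c * p_c / s_t
        points.append((float(np.clip(fpr, 0, 1)), float(np.clip(tpr, 0, 1)),
                       float(c)))
    # natural ROC path order: descending cutoff, (0,0) -> (1,1); sorting by
    # the estimated FPR instead can swap points that tie up to rounding
    points.sort(key=lambda p: -p[2])
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return auc, points
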