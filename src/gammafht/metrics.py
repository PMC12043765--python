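"""Censored-prediction metrics: Kaplan-Meier, IPCW Brier score, IBS, C-index.

Censoring is corrected by inverse-probability-of-censoring weights
(IPCW) built from the Kaplan-Meier estimate of the censoring
distribution (the product-limit estimator on flipped status, with the
convention that at tied times events precede censorings).
"""

from __future__ import annotations

import warnings

import numpy as np

from .distribution import SurvivalDataset

__all__ = [
    "KaplanMeier",
    "kaplan_meier",
    "censoring_km",
    "brier_score",
    "integrated_brier",
    "c_index",
    "predicted_median",
]


class KaplanMeier:
    """Right-continuous product-limit step function."""

    def __init__(self, times, status):
        times = np.asarray(times, dtype=float)
        status = np.asarray(status, dtype=int)
        if times.size == 0:
            raise ValueError("empty input")
        order = np.argsort(times, kind="stable")
        t = times[order]
        d = status[order]
        uniq = np.unique(t)
        at_risk = np.empty(uniq.size)
        events = np.empty(uniq.size)
        n = t.size
        for k, tv in enumerate(uniq):
            at_risk[k] = np.sum(t >= tv)
            events[k] = np.sum((t == tv) & (d == 1))
        factors = 1.0 - events / at_risk
        surv = np.cumprod(factors)
        keep = events > 0
        self.event_times = uniq[keep]
        self.surv = surv[keep]

    def __call__(self, t):
        """S(t), right-continuous; S = 1 before the first event time."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        vals = np.concatenate([[1.0], self.surv])
        out = vals[idx]
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """S(t-): the value just before t."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="left")
        vals = np.concatenate([[1.0], self.surv])
        out = vals[idx]
        return out if out.ndim else float(out)


def kaplan_meier(times, status) -> KaplanMeier:
    """Kaplan-Meier estimator of the event-time survival function."""
    return KaplanMeier(times, status)


def censoring_km(times, status) -> KaplanMeier:
    """Kaplan-Meier estimator of the censoring distribution G.

    Status is flipped (a censoring becomes the 'event'); at tied times the
    survival events are taken to occur first, so censorings at time t see
    an at-risk set reduced by the events at t.  This is realized by
    shifting censoring times infinitesimally to the right of tied events.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    eps = 1e-9 * max(1.0, float(times.max()))
    shifted = np.where(status == 0, times + eps, times)
    return KaplanMeier(shifted, 1 - status)


def _surface_at(time_grid, S, t_eval):
    """Column of the prediction surface at t_eval (step interpolation)."""
    time_grid = np.asarray(time_grid, dtype=float)
    k = np.searchsorted(time_grid, t_eval, side="right") - 1
    if k < 0:
        return np.ones(S.shape[0])
    return S[:, min(k, S.shape[1] - 1)]


def brier_score(t_eval, time_grid, S, test: SurvivalDataset,
                G: KaplanMeier | None = None) -> float:
    """IPCW (Graf) Brier score at horizon t_eval.

    Events before t_eval contribute (0 - S_hat)^2 / G(t_i-); individuals
    still at risk contribute (1 - S_hat)^2 / G(t_eval); observations
    censored before t_eval contribute nothing.
    """
    if G is None:
        G = censoring_km(test.times, test.status)
    s_hat = _surface_at(time_grid, S, t_eval)
    t = test.times
    d = test.status
    contrib = np.zeros(test.n)
    w_used = np.ones(test.n, dtype=bool)

    died = (t <= t_eval) & (d == 1)
    g_died = G.left_limit(t[died])
    at_risk = t > t_eval
    g_risk = G(t_eval)

    bad = np.zeros(test.n, dtype=bool)
    if np.any(g_died <= 0):
        bad_idx = np.nonzero(died)[0][g_died <= 0]
        bad[bad_idx] = True
        warnings.warn("censoring-survival weight 0; dropping affected terms",
                      RuntimeWarning)
    contrib[died] = (0.0 - s_hat[died]) ** 2 / np.maximum(g_died, 1e-300)
    if at_risk.any():
        if g_risk <= 0:
            bad |= at_risk
            warnings.warn("censoring-survival weight 0 at horizon; dropping terms",
                          RuntimeWarning)
        else:
            contrib[at_risk] = (1.0 - s_hat[at_risk]) ** 2 / g_risk
    contrib[bad] = 0.0
    return float(np.sum(contrib) / test.n)


def integrated_brier(time_grid, S, test: SurvivalDataset,
                     t_max: float | None = None,
                     eval_times: np.ndarray | None = None) -> float:
    """Trapezoidal integral of the Brier curve up to t_max, span-normalized.

    The evaluation grid defaults to the unique test event times (<= t_max),
    matching the step locations of the estimators involved.
    """
    if eval_times is None:
        eval_times = np.unique(test.times[test.status == 1])
    eval_times = np.asarray(eval_times, dtype=float)
    if t_max is not None:
        eval_times = eval_times[eval_times <= t_max]
    if eval_times.size < 3:
        raise ValueError("need at least 3 evaluation times before t_max")
    G = censoring_km(test.times, test.status)
    bs = np.array([brier_score(t, time_grid, S, test, G=G) for t in eval_times])
    span = eval_times[-1] - eval_times[0]
    return float(np.trapezoid(bs, eval_times) / span)


def c_index(risk_scores, test: SurvivalDataset, t_max: float | None = None) -> float:
    """IPCW concordance index (Uno-style weights 1/G(t_i-)^2).

    Usable pairs (i, j): i experienced the event, t_i < t_j and
    t_i <= t_max.  A pair is concordant when the earlier failure has the
    higher risk score; risk ties count 1/2.
    """
    risk = np.asarray(risk_scores, dtype=float)
    if risk.shape != (test.n,):
        raise ValueError("one risk score per individual required")
    t = test.times
    d = test.status
    if t_max is None:
        t_max = np.inf
    G = censoring_km(t, d)
    g_left = np.maximum(G.left_limit(t), 1e-300)
    num = 0.0
    den = 0.0
    for i in range(test.n):
        if d[i] != 1 or t[i] > t_max:
            continue
        usable = t > t[i]
        if not usable.any():
            continue
        w = 1.0 / (g_left[i] ** 2)
        conc = (risk[usable] < risk[i]).sum() + 0.5 * (risk[usable] == risk[i]).sum()
        num += w * conc
        den += w * usable.sum()
    if den == 0:
        raise ValueError("no usable pairs for the concordance index")
    return float(num / den)


def predicted_median(time_grid, S):
    """Per-row median survival time from a prediction surface.

    Linear interpolation between grid points around S = 0.5; rows whose
    curve stays above 0.5 get the last grid time (a right-censored
    median).  The negated median is the default risk score.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    n, m = S.shape
    med = np.empty(n)
    for i in range(n):
        row = S[i]
        below = np.nonzero(row <= 0.5)[0]
        if below.size == 0:
            med[i] = time_grid[-1]
            continue
        k = below[0]
        if k == 0:
            med[i] = time_grid[0]
        else:
            s0, s1 = row[k - 1], row[k]
            t0, t1 = time_grid[k - 1], time_grid[k]
            med[i] = t0 + (s0 - 0.5) / max(s0 - s1, 1e-300) * (t1 - t0)
    return med
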