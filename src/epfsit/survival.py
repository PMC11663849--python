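"""Right-censored survival analysis of conidia donors and receivers.

Kaplan–Meier product-limit estimation with Greenwood standard errors,
the G-group Mantel-Cox log-rank test (pooled hypergeometric treatment
of ties), and the unpaired t-test used to compare donor and receiver
median lethal times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "TTestResult",
    "km_estimate",
    "logrank_test",
    "t_test_unpaired",
]


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    group: str
    time: float
    event: int  # 1 = death, 0 = right-censored

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier step estimate over the distinct event times."""

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): survival just after time t (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    pooled: bool


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator for one group.

    With no events (all censored) the curve is flat at 1 and carries no
    event times. The Greenwood variance is
    S(t)² · Σ_{tᵢ≤t} dᵢ / (nᵢ (nᵢ − dᵢ)).
    """
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records], float)
    events = np.array([r.event for r in records], int)
    event_times = np.unique(times[events == 1])
    n = times.size
    surv = []
    se_terms = []
    at_risk = []
    n_ev = []
    s = 1.0
    cum = 0.0
    for t in event_times:
        n_t = int(np.sum(times >= t))
        d_t = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_t / n_t
        if n_t > d_t:
            cum += d_t / (n_t * (n_t - d_t))
            se = s * math.sqrt(cum)
        else:
            se = 0.0  # S = 0: Greenwood variance degenerates
        at_risk.append(n_t)
        n_ev.append(d_t)
        surv.append(s)
        se_terms.append(se)
    return KMCurve(
        times=event_times,
        n_at_risk=np.array(at_risk, int),
        n_events=np.array(n_ev, int),
        survival=np.array(surv, float),
        greenwood_se=np.array(se_terms, float),
    )


def logrank_test(records: Sequence[SurvivalRecord]) -> LogRankResult:
    """Mantel-Cox log-rank chi-squared test across >=2 groups.

    Observed-minus-expected event counts over the pooled distinct event
    times with the hypergeometric (co)variance; ties at an event time
    share the same risk set. chi² = (O−E)' V⁻¹ (O−E) over the first
    G−1 groups, df = G−1.
    """
    groups = sorted({r.group for r in records})
    g = len(groups)
    if g < 2:
        raise ValueError("logrank_test requires at least 2 groups")
    for grp in groups:
        if not any(r.group == grp for r in records):
            raise ValueError(f"group {grp!r} is empty")
    times = np.array([r.time for r in records], float)
    events = np.array([r.event for r in records], int)
    gidx = np.array([groups.index(r.group) for r in records], int)
    if events.sum() == 0:
        raise ValueError("no events: log-rank test undefined")

    event_times = np.unique(times[events == 1])
    o_minus_e = np.zeros(g)
    V = np.zeros((g, g))
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        n_gt = np.bincount(gidx[at_risk], minlength=g).astype(float)
        d_gt = np.bincount(gidx[(times == t) & (events == 1)], minlength=g).astype(float)
        e_gt = d_t * n_gt / n_t
        o_minus_e += d_gt - e_gt
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1) / n_t
            V += c * (np.diag(n_gt) - np.outer(n_gt, n_gt) / n_t)
    u = o_minus_e[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(Vsub) @ u)
    chi2 = max(chi2, 0.0)
    df = g - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2=chi2, df=df, p=p)


def t_test_unpaired(
    group_a: Sequence[float], group_b: Sequence[float], pooled: bool = True
) -> TTestResult:
    """Two-sided unpaired t-test; pooled-variance Student by default,
    Welch with ``pooled=False``."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), pooled=pooled)
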