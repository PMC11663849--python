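"""Virulence bioassay analysis.

Covers the quality gate on conidial viability (germination percentage),
cumulative mortality summaries, Abbott's correction for control
mortality, the time–mortality GLM yielding LT50 ± SE by the delta
method, and the classification of a strain's LT50 against the
SIT-compatibility window: a candidate fungus must kill slowly enough
that released sterile males stay alive and competitive long enough to
mate (LT50 >= 10 days) but not so slowly that it contributes nothing
(LT50 <= 20 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stats_core import glm_fit

__all__ = [
    "GerminationCount",
    "GerminationSummary",
    "MortalityRecord",
    "MortalityPct",
    "AbbottResult",
    "LT50Estimate",
    "SITCompatibility",
    "percent_germination",
    "cumulative_mortality_pct",
    "abbott_correct",
    "fit_time_mortality",
    "classify_sit_compatible",
]

GERMINATION_GATE_PCT = 80.0
SIT_WINDOW_DAYS = (10.0, 20.0)


@dataclass(frozen=True)
class GerminationCount:
    """Germinated conidia among ``n_scored`` scored on one coverslip."""

    plate_id: str
    coverslip_index: int
    n_germinated: int
    n_scored: int = 100
    temperature: float | None = None

    def __post_init__(self):
        if not 0 <= self.n_germinated <= self.n_scored:
            raise ValueError("n_germinated must lie in [0, n_scored]")


@dataclass(frozen=True)
class MortalityRecord:
    """Cumulative deaths by ``day`` for one treatment replicate."""

    treatment_id: str
    replicate: str
    day: int
    n_initial: int
    n_dead_cum: int

    def __post_init__(self):
        if self.day < 1:
            raise ValueError("day must be >= 1")
        if not 0 <= self.n_dead_cum <= self.n_initial:
            raise ValueError("n_dead_cum must lie in [0, n_initial]")


@dataclass(frozen=True)
class GerminationSummary:
    mean_pct: float
    se_pct: float
    n_coverslips: int
    passes_gate: bool


@dataclass(frozen=True)
class MortalityPct:
    treatment_id: str
    day: int
    mean_pct: float
    se_pct: float
    n_replicates: int


@dataclass(frozen=True)
class AbbottResult:
    treated_pct: float
    control_pct: float
    corrected_pct: float


@dataclass(frozen=True)
class LT50Estimate:
    lt50: float
    se: float
    slope: float
    slope_se: float
    intercept: float
    link: str
    n_obs: int
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class SITCompatibility:
    strain: str
    lt50: float
    window: tuple[float, float]
    category: str  # too_fast | compatible | too_slow


def percent_germination(
    counts: Sequence[GerminationCount], gate_pct: float = GERMINATION_GATE_PCT
) -> GerminationSummary:
    """Mean germination % over coverslips, its SE, and the viability gate.

    The gate passes strictly above ``gate_pct`` (a strain at exactly 80%
    is excluded from bioassays).
    """
    if not counts:
        raise ValueError("percent_germination requires at least one coverslip")
    pcts = np.array([100.0 * c.n_germinated / c.n_scored for c in counts])
    mean = float(pcts.mean())
    se = float(pcts.std(ddof=1) / math.sqrt(pcts.size)) if pcts.size > 1 else 0.0
    return GerminationSummary(
        mean_pct=mean, se_pct=se, n_coverslips=pcts.size, passes_gate=mean > gate_pct
    )


def cumulative_mortality_pct(
    records: Sequence[MortalityRecord], day: int
) -> list[MortalityPct]:
    """Per-treatment mean ± SE of cumulative mortality % at ``day``.

    Each replicate contributes 100·n_dead_cum/n_initial; the SE is the
    sample SD across replicates divided by √(number of replicates).
    Every replicate of a treatment must have a record for ``day``.
    """
    by_treatment: dict[str, dict[str, float]] = {}
    replicates_seen: dict[str, set] = {}
    for r in records:
        replicates_seen.setdefault(r.treatment_id, set()).add(r.replicate)
        if r.day == day:
            by_treatment.setdefault(r.treatment_id, {})[r.replicate] = (
                100.0 * r.n_dead_cum / r.n_initial
            )
    out = []
    for treatment, reps in sorted(by_treatment.items()):
        missing = replicates_seen[treatment] - reps.keys()
        if missing:
            raise ValueError(
                f"treatment {treatment!r}: no day-{day} record for replicate(s) {sorted(missing)}"
            )
        pcts = np.array(list(reps.values()))
        se = float(pcts.std(ddof=1) / math.sqrt(pcts.size)) if pcts.size > 1 else 0.0
        out.append(
            MortalityPct(
                treatment_id=treatment,
                day=day,
                mean_pct=float(pcts.mean()),
                se_pct=se,
                n_replicates=pcts.size,
            )
        )
    return out


def abbott_correct(treated_pct: float, control_pct: float) -> AbbottResult:
    """Abbott's control-mortality correction, floored at zero.

    corrected = 100 · (treated − control) / (100 − control).
    """
    if not 0.0 <= treated_pct <= 100.0:
        raise ValueError("treated_pct must lie in [0, 100]")
    if not 0.0 <= control_pct < 100.0:
        raise ValueError("control_pct must lie in [0, 100); 100% control mortality is undefined")
    corrected = 100.0 * (treated_pct - control_pct) / (100.0 - control_pct)
    return AbbottResult(
        treated_pct=treated_pct,
        control_pct=control_pct,
        corrected_pct=max(0.0, corrected),
    )


def _cumulative_count_covariance(
    X: np.ndarray,
    trials: np.ndarray,
    mu: np.ndarray,
    dmu: np.ndarray,
    cohort: np.ndarray,
) -> np.ndarray:
    """Coefficient covariance honouring the serial dependence of
    cumulative death counts.

    Rows of the design are repeated observations of the same fly cohort,
    so Cov(y_t, y_s) = m·[F(min(t,s)) − F(t)·F(s)] within a cohort (the
    same fly's death indicator appears in every later count) and 0
    across cohorts. The returned matrix is the model-based sandwich
    A⁻¹ B A⁻¹ with A the weighted information and B the exact variance
    of the quasi-score under the fitted model.
    """
    v = np.clip(mu * (1.0 - mu), 1e-12, None)
    g = dmu / v  # score weight: Σ g_t·x_t·(y_t − m·μ_t)
    same = cohort[:, None] == cohort[None, :]
    m_eff = np.minimum.outer(trials, trials)
    fmin = np.minimum.outer(mu, mu)
    cov_y = np.where(same, m_eff * (fmin - np.outer(mu, mu)), 0.0)
    B = X.T @ (np.outer(g, g) * cov_y) @ X
    A = X.T @ (X * (trials * dmu**2 / v)[:, None])
    a_inv = np.linalg.inv(A)
    return a_inv @ B @ a_inv


def fit_time_mortality(
    records: Sequence[MortalityRecord],
    link: str = "logit",
    log_day: bool = False,
    pool_replicates: bool = True,
    se_method: str = "cumulative",
) -> LT50Estimate:
    """Binomial GLM of cumulative proportion dead on day; LT50 ± SE.

    Replicates are pooled by default (summed deaths over summed initial
    counts per day), matching the single LT50 ± SE reported per strain.
    LT50 = −intercept/slope on the (possibly log-transformed) day scale;
    its SE comes from the delta method on the coefficient covariance:

        Var(LT50) = (1/b₁²)·[Var(b₀) + LT50²·Var(b₁) + 2·LT50·Cov(b₀,b₁)]

    Because the response is a *cumulative* count, observations on
    successive days re-count the same flies; the default coefficient
    covariance (``se_method="cumulative"``) therefore uses the exact
    model-based covariance of cumulative counts in a sandwich around the
    IRLS information, which restores nominal interval coverage. The
    naive independent-binomial covariance (what a plain GLM reports) is
    available with ``se_method="glm"``.

    A non-positive fitted slope (mortality not increasing with time) or
    suspected separation is reported through converged=False plus a
    message; the point estimates are still returned.
    """
    if link not in ("logit", "probit"):
        raise ValueError("link must be 'logit' or 'probit'")
    if se_method not in ("cumulative", "glm"):
        raise ValueError("se_method must be 'cumulative' or 'glm'")
    if not records:
        raise ValueError("no mortality records supplied")
    if pool_replicates:
        pooled: dict[int, list[int]] = {}
        for r in records:
            agg = pooled.setdefault(r.day, [0, 0])
            agg[0] += r.n_dead_cum
            agg[1] += r.n_initial
        days = np.array(sorted(pooled), float)
        deaths = np.array([pooled[int(d)][0] for d in days], float)
        trials = np.array([pooled[int(d)][1] for d in days], float)
        cohort = np.zeros(days.size)
    else:
        days = np.array([r.day for r in records], float)
        deaths = np.array([r.n_dead_cum for r in records], float)
        trials = np.array([r.n_initial for r in records], float)
        rep_ids = sorted({r.replicate for r in records})
        cohort = np.array([rep_ids.index(r.replicate) for r in records], float)
    if len(np.unique(days)) < 2:
        raise ValueError("need >=2 distinct observation days")
    partial = np.any((deaths > 0) & (deaths < trials))

    x = np.log(days) if log_day else days
    X = np.column_stack([np.ones_like(x), x])
    fit = glm_fit(deaths, X, family=f"binomial-{link}", trials=trials)
    b0, b1 = fit.coefficients
    covariance = fit.covariance
    if se_method == "cumulative" and np.all(np.isfinite(covariance)):
        eta = X @ fit.coefficients
        if link == "logit":
            mu = 1.0 / (1.0 + np.exp(-eta))
            dmu = mu * (1.0 - mu)
        else:
            from scipy import stats as _st

            mu = _st.norm.cdf(eta)
            dmu = _st.norm.pdf(eta)
        covariance = _cumulative_count_covariance(X, trials, mu, dmu, cohort)
    lt50_x = -b0 / b1 if b1 != 0 else math.inf
    if b1 > 0 and np.all(np.isfinite(covariance)):
        v00, v11 = covariance[0, 0], covariance[1, 1]
        v01 = covariance[0, 1]
        var = (v00 + lt50_x**2 * v11 + 2.0 * lt50_x * v01) / b1**2
        se_x = math.sqrt(max(var, 0.0))
    else:
        se_x = math.nan
    if log_day:
        lt50 = math.exp(lt50_x)
        se = lt50 * se_x if math.isfinite(se_x) else math.nan  # delta method again
    else:
        lt50, se = lt50_x, se_x

    converged = fit.converged
    message = fit.message
    if not partial:
        converged = False
        message = (message + "; " if message else "") + (
            "no day with partial mortality: separation, LT50 not identifiable"
        )
    if b1 <= 0:
        converged = False
        message = (message + "; " if message else "") + (
            "non-positive slope: mortality does not increase with time"
        )
    return LT50Estimate(
        lt50=float(lt50),
        se=float(se),
        slope=float(b1),
        slope_se=float(math.sqrt(covariance[1, 1])) if np.all(np.isfinite(covariance)) else math.nan,
        intercept=float(b0),
        link=link,
        n_obs=int(days.size),
        converged=converged,
        message=message,
    )


def classify_sit_compatible(
    lt50: float,
    strain: str = "",
    window: tuple[float, float] = SIT_WINDOW_DAYS,
) -> SITCompatibility:
    """Classify an LT50 against the SIT-compatibility window (inclusive).

    Below the window the fungus kills sterile males before they can
    mate (``too_fast``); above it the kill is too slow to contribute
    (``too_slow``).
    """
    if not (math.isfinite(lt50) and lt50 > 0):
        raise ValueError("lt50 must be finite and positive")
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    if lt50 < lo:
        category = "too_fast"
    elif lt50 > hi:
        category = "too_slow"
    else:
        category = "compatible"
    return SITCompatibility(strain=strain, lt50=lt50, window=(lo, hi), category=category)
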