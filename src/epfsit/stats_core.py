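"""Shared statistical machinery.

One-way ANOVA, Tukey HSD with compact-letter displays, and generalized
linear model fitting (binomial logit/probit, Poisson log) by iteratively
reweighted least squares (IRLS).

The GLM fitter is written in-package because downstream stages need its
exact surface (coefficient covariance for delta-method standard errors,
a deviance trace that is non-increasing by construction, and explicit
separation diagnostics). ANOVA, the t machinery and studentized-range
tail probabilities are delegated to scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "GlmFit",
    "oneway_anova",
    "tukey_hsd",
    "compact_letters",
    "glm_fit",
]

FAMILIES = ("binomial-logit", "binomial-probit", "poisson-log")


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise Tukey-HSD comparisons.

    ``pairs`` holds (group_a, group_b, mean_diff, q_stat, p_adj) with
    mean_diff = mean(a) - mean(b).
    """

    pairs: tuple[tuple[str, str, float, float, float], ...]
    alpha: float = 0.05

    def p_lookup(self) -> dict[frozenset, float]:
        return {frozenset((a, b)): p for a, b, _, _, p in self.pairs}


@dataclass
class GlmFit:
    family: str
    coefficients: np.ndarray
    covariance: np.ndarray
    deviance: float
    deviance_trace: tuple[float, ...]
    n_iter: int
    converged: bool
    message: str = ""

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coefficients

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        eta = self.predict_linear(X)
        return _INVLINK[self.family](eta)


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over ``groups`` of raw values."""
    if len(groups) < 2:
        raise ValueError("oneway_anova requires at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group must contain at least 2 values")
    n_total = sum(a.size for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("zero variance overall: ANOVA undefined")
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w, p=float(p))


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """Tukey's honestly-significant-difference test over labelled groups.

    Uses the Tukey–Kramer statistic for (possibly) unbalanced designs;
    adjusted p-values come from the studentized-range distribution with
    the pooled within-group degrees of freedom.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    names = list(groups)
    if len(names) < 2:
        raise ValueError("tukey_hsd requires at least 2 groups")
    arrays = {k: np.asarray(groups[k], float) for k in names}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group must contain at least 2 values")
    k = len(names)
    n_total = sum(a.size for a in arrays.values())
    df_w = n_total - k
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    msw = ssw / df_w
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[names[i]], arrays[names[j]]
            diff = float(a.mean() - b.mean())
            if msw <= 0:
                q = 0.0 if diff == 0 else math.inf
            else:
                se = math.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se if se > 0 else math.inf
            p_adj = float(stats.studentized_range.sf(q, k, df_w)) if math.isfinite(q) else 0.0
            if q == 0.0:
                p_adj = 1.0
            pairs.append((names[i], names[j], diff, q, min(1.0, p_adj)))
    return TukeyResult(pairs=tuple(pairs), alpha=alpha)


def compact_letters(tukey: TukeyResult, alpha: float | None = None) -> dict[str, str]:
    """Compact-letter display by the insert-and-absorb algorithm.

    Two groups share at least one letter if and only if their adjusted
    pairwise p-value is >= alpha. Letters are assigned in input group
    order, so output is deterministic.
    """
    if alpha is None:
        alpha = tukey.alpha
    names: list[str] = []
    for a, b, *_ in tukey.pairs:
        if a not in names:
            names.append(a)
        if b not in names:
            names.append(b)
    sig = [(a, b) for a, b, _, _, p in tukey.pairs if p < alpha]
    columns: list[set[str]] = [set(names)]
    for a, b in sig:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = []
        for col in new_columns:
            if not any(col < other or (col == other and other in columns) for other in new_columns if other is not col):
                if col and col not in columns:
                    columns.append(col)
    # deterministic column order: by first member's position in input order
    columns.sort(key=lambda col: min(names.index(g) for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for idx, col in enumerate(columns):
        ch = alphabet[idx % 26] * (1 + idx // 26)
        for g in names:
            if g in col:
                letters[g] += ch
    return letters


# --- IRLS GLM -------------------------------------------------------------

_INVLINK = {
    "binomial-logit": lambda eta: 1.0 / (1.0 + np.exp(-eta)),
    "binomial-probit": lambda eta: stats.norm.cdf(eta),
    "poisson-log": np.exp,
}


def _mu_eta(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "binomial-logit":
        mu = _INVLINK[family](eta)
        return mu * (1.0 - mu)
    if family == "binomial-probit":
        return stats.norm.pdf(eta)
    return np.exp(eta)  # poisson-log


def _variance(family: str, mu: np.ndarray) -> np.ndarray:
    if family.startswith("binomial"):
        return mu * (1.0 - mu)
    return mu


def _deviance(family: str, y: np.ndarray, mu: np.ndarray, trials: np.ndarray) -> float:
    def xlogy(x, v):
        return np.where(x > 0, x * np.log(np.where(x > 0, v, 1.0)), 0.0)

    if family.startswith("binomial"):
        yy = y
        mm = np.clip(mu * trials, 1e-12, None)
        dev = xlogy(yy, yy / mm) + xlogy(trials - yy, (trials - yy) / np.clip(trials - mm, 1e-12, None))
        return float(2.0 * dev.sum())
    dev = xlogy(y, y / np.clip(mu, 1e-300, None)) - (y - mu)
    return float(2.0 * dev.sum())


def glm_fit(
    y: Sequence[float],
    X: Sequence[Sequence[float]],
    family: str = "binomial-logit",
    trials: Sequence[float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Fit a GLM by iteratively reweighted least squares.

    Parameters
    ----------
    y
        Response: success counts for the binomial families, event counts
        for Poisson.
    X
        Design matrix (n x p), full column rank; include the intercept
        column explicitly.
    family
        One of ``binomial-logit``, ``binomial-probit``, ``poisson-log``.
    trials
        Binomial denominators (required for binomial families).

    The working-response update includes step-halving so the deviance
    trace is non-increasing. Coefficient covariance is the inverse of
    the final weighted information matrix.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match design matrix rows")
    if np.linalg.matrix_rank(X) < p:
        return GlmFit(family, np.full(p, np.nan), np.full((p, p), np.nan),
                      math.nan, (), 0, False, "design matrix is rank-deficient")
    if family.startswith("binomial"):
        if trials is None:
            raise ValueError("binomial families require `trials`")
        m = np.asarray(trials, float)
        if np.any(y < 0) or np.any(y > m):
            raise ValueError("binomial successes must satisfy 0 <= y <= trials")
        ybar = (y + 0.5) / (m + 1.0)  # shrunken start keeps link finite
        mu = ybar.copy()
    else:
        m = np.ones(n)
        if np.any(y < 0):
            raise ValueError("poisson counts must be nonnegative")
        mu = np.clip(y, 0.5, None)

    if family == "binomial-logit":
        eta = np.log(mu / (1 - mu))
    elif family == "binomial-probit":
        eta = stats.norm.ppf(np.clip(mu, 1e-10, 1 - 1e-10))
    else:
        eta = np.log(mu)

    beta = np.zeros(p)
    # initialise beta from one weighted LS solve on the starting eta
    dev = math.inf
    trace: list[float] = []
    converged = False
    message = "reached max_iter without meeting tolerance"
    for it in range(1, max_iter + 1):
        mu = _INVLINK[family](eta)
        if family.startswith("binomial"):
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
        else:
            mu = np.clip(mu, 1e-300, None)
        d = np.clip(_mu_eta(family, eta), 1e-12, None)
        v = np.clip(_variance(family, mu), 1e-12, None)
        w = m * d * d / v
        z = eta + (y / m - mu) / d
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)

        # step-halving keeps the deviance trace monotone
        step = 1.0
        for _ in range(30):
            cand = beta + step * (beta_new - beta) if trace else beta_new
            eta_c = X @ cand
            mu_c = _INVLINK[family](eta_c)
            if family.startswith("binomial"):
                mu_c = np.clip(mu_c, 1e-12, 1 - 1e-12)
            dev_c = _deviance(family, y, mu_c, m)
            if dev_c <= dev or not trace:
                break
            step /= 2.0
        if trace and dev_c > dev:
            # no step along the IRLS direction improves the deviance:
            # accept the current iterate as the solution
            converged = True
            message = ""
            break
        beta, eta = cand, eta_c
        trace.append(dev_c)
        if dev != math.inf and abs(dev - dev_c) <= tol * (abs(dev_c) + tol):
            dev = dev_c
            converged = True
            message = ""
            break
        dev = dev_c

    mu = _INVLINK[family](np.clip(eta, -500, 500))
    if family.startswith("binomial"):
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
    d = np.clip(_mu_eta(family, eta), 1e-12, None)
    v = np.clip(_variance(family, mu), 1e-12, None)
    w = m * d * d / v
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
        message = "singular information matrix at solution"
    saturated = math.isfinite(dev) and dev < 1e-6 and float(np.abs(eta).max()) > 20
    if converged and (np.abs(beta).max() > 1e4 or saturated):
        converged = False
        message = "extreme coefficients: complete or quasi-complete separation suspected"
    return GlmFit(
        family=family,
        coefficients=beta,
        covariance=cov,
        deviance=dev if math.isfinite(dev) else trace[-1] if trace else math.nan,
        deviance_trace=tuple(trace),
        n_iter=len(trace),
        converged=converged,
        message=message,
    )
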