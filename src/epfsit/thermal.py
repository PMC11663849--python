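"""Temperature-dependent growth modelling of fungal colonies.

Daily colony-radius series (four quadrant radii per plate per day) are
reduced to absolute radial growth rates (mm/day, OLS slope of mean
radius against day). The rate-versus-temperature response is then fitted
with three models:

* ``linear``      — y = a + b·T
* ``lactin1``     — y = a·(T − Tmin)²·(Tmax − T) on [Tmin, Tmax], else 0
* ``ctmi``        — cardinal temperature model with inflection, a
  four-parameter unimodal response equal to μopt at Topt and zero at the
  cardinal extremes Tmin and Tmax

plus an optional ``lactin1_classical`` (the exponential Lactin form).
Model comparison uses the Gaussian-RSS AIC, adjusted pseudo-R², and the
Vuong non-nested likelihood-ratio test. All rate evaluations are floored
at zero: negative growth rates are not biologically meaningful here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RadialGrowthSeries",
    "GrowthRate",
    "TPCFit",
    "VuongResult",
    "CardinalSummary",
    "ModelSelection",
    "absolute_growth_rate",
    "eval_tpc",
    "fit_tpc",
    "aic_gaussian",
    "r2_measures",
    "vuong_test",
    "select_model",
    "cardinal_summary",
]

MODELS = ("linear", "lactin1", "ctmi", "lactin1_classical")
_N_PARAMS = {"linear": 2, "lactin1": 3, "ctmi": 4, "lactin1_classical": 3}


@dataclass(frozen=True)
class RadialGrowthSeries:
    """One day's four quadrant-radius readings for one plate."""

    plate_id: str
    strain: str
    temperature: float
    day: int
    quadrant_radii: tuple[float, float, float, float]

    def __post_init__(self):
        if len(self.quadrant_radii) != 4:
            raise ValueError("quadrant_radii must hold exactly 4 values")
        if any(r < 0 for r in self.quadrant_radii):
            raise ValueError("quadrant_radii must be nonnegative")

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.quadrant_radii))


@dataclass(frozen=True)
class GrowthRate:
    """Absolute radial growth rate: OLS slope of radius on day."""

    strain: str
    temperature: float
    plate_id: str
    beta: float  # mm/day
    intercept: float  # mm
    fit_r2: float


@dataclass(frozen=True)
class TPCFit:
    model: str
    params: dict
    rss: float
    n: int
    k: int
    aic: float
    pseudo_r2: float
    adj_r2: float
    converged: bool
    strain: str = ""


@dataclass(frozen=True)
class VuongResult:
    z: float
    p: float
    n: int
    verdict: str  # A_preferred | B_preferred | indistinguishable


@dataclass(frozen=True)
class ModelSelection:
    ranked: tuple[TPCFit, ...]
    best: TPCFit
    tie_broken_by_adj_r2: bool
    needs_vuong: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class CardinalSummary:
    per_strain: dict
    overall_tmin: float
    overall_tmax: float
    topt_range: tuple[float, float]


def absolute_growth_rate(
    series: Sequence[RadialGrowthSeries],
) -> list[GrowthRate]:
    """OLS of mean-of-four-quadrants radius against day, per plate.

    Returns one GrowthRate per (strain, temperature, plate). Requires at
    least two distinct days per plate.
    """
    by_plate: dict[tuple, list[RadialGrowthSeries]] = {}
    for s in series:
        by_plate.setdefault((s.strain, s.temperature, s.plate_id), []).append(s)
    out: list[GrowthRate] = []
    for (strain, temp, plate), obs in by_plate.items():
        days = np.array([o.day for o in obs], float)
        radii = np.array([o.mean_radius for o in obs], float)
        if len(np.unique(days)) < 2:
            raise ValueError(
                f"plate {plate!r} at {temp}°C: need >=2 distinct days for a slope"
            )
        res = stats.linregress(days, radii)
        r2 = float(res.rvalue**2) if np.std(radii) > 0 else 1.0
        out.append(
            GrowthRate(
                strain=strain,
                temperature=float(temp),
                plate_id=str(plate),
                beta=float(res.slope),
                intercept=float(res.intercept),
                fit_r2=r2,
            )
        )
    return out


# --- model evaluation -------------------------------------------------------


def _ctmi_check(params: Mapping[str, float]) -> tuple[float, float, float, float]:
    mu, tmin, topt, tmax = (
        params["mu_opt"],
        params["Tmin"],
        params["Topt"],
        params["Tmax"],
    )
    if not (tmin < topt < tmax):
        raise ValueError("ctmi requires Tmin < Topt < Tmax")
    if mu <= 0:
        raise ValueError("ctmi requires mu_opt > 0")
    return mu, tmin, topt, tmax


def _ctmi_raw(T, mu, tmin, topt, tmax):
    """CTMI without validation; 0 outside [Tmin, Tmax]; no degeneracy check."""
    T = np.asarray(T, float)
    num = mu * (T - tmax) * (T - tmin) ** 2
    den = (topt - tmin) * (
        (topt - tmin) * (T - topt) - (topt - tmax) * (topt + tmin - 2.0 * T)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(np.abs(den) > 0, num / np.where(den == 0, 1.0, den), 0.0)
    val = np.where((T < tmin) | (T > tmax), 0.0, val)
    return np.maximum(val, 0.0)


def _lactin1_raw(T, a, tmin, tmax):
    T = np.asarray(T, float)
    val = a * (T - tmin) ** 2 * (tmax - T)
    val = np.where((T < tmin) | (T > tmax), 0.0, val)
    return np.maximum(val, 0.0)


def _lactin1_classical_raw(T, rho, tmax, delta):
    T = np.asarray(T, float)
    val = np.exp(rho * T) - np.exp(rho * tmax - (tmax - T) / delta)
    return np.maximum(val, 0.0)


def eval_tpc(model: str, params: Mapping[str, float], T) -> np.ndarray | float:
    """Evaluate a thermal-performance model at temperature(s) ``T`` (°C).

    Rates are in mm/day and are never negative. For ``lactin1`` and
    ``ctmi`` the response is identically zero outside [Tmin, Tmax].
    Raises on inadmissible parameters and on a degenerate CTMI
    denominator (|den| < 1e-12) at a requested in-range temperature.
    """
    scalar = np.isscalar(T)
    T_arr = np.atleast_1d(np.asarray(T, float))
    if model == "linear":
        val = np.maximum(params["a"] + params["b"] * T_arr, 0.0)
    elif model == "lactin1":
        if not params["Tmin"] < params["Tmax"]:
            raise ValueError("lactin1 requires Tmin < Tmax")
        val = _lactin1_raw(T_arr, params["a"], params["Tmin"], params["Tmax"])
    elif model == "lactin1_classical":
        val = _lactin1_classical_raw(T_arr, params["rho"], params["Tmax"], params["delta"])
    elif model == "ctmi":
        mu, tmin, topt, tmax = _ctmi_check(params)
        den = (topt - tmin) * (
            (topt - tmin) * (T_arr - topt)
            - (topt - tmax) * (topt + tmin - 2.0 * T_arr)
        )
        in_range = (T_arr >= tmin) & (T_arr <= tmax)
        if np.any(in_range & (np.abs(den) < 1e-12)):
            bad = T_arr[in_range & (np.abs(den) < 1e-12)]
            raise ValueError(f"ctmi denominator degenerate at T={bad.tolist()}")
        val = _ctmi_raw(T_arr, mu, tmin, topt, tmax)
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return float(val[0]) if scalar else val


# --- fitting ----------------------------------------------------------------


def _extract_xy(rates: Sequence[GrowthRate]):
    T = np.array([r.temperature for r in rates], float)
    y = np.array([r.beta for r in rates], float)
    return T, y


def _fit_linear(T, y, w):
    W = np.diag(w)
    X = np.column_stack([np.ones_like(T), T])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    params = {"a": float(beta[0]), "b": float(beta[1])}
    resid = y - eval_tpc("linear", params, T)
    return params, resid


def fit_tpc(
    rates: Sequence[GrowthRate],
    model: str,
    weights: Sequence[float] | None = None,
) -> TPCFit:
    """Least-squares fit of a thermal-performance model to growth rates.

    Nonlinear models are fitted by deterministic multi-start trust-region
    least squares; ordering constraints (ctmi: Tmin < Topt < Tmax;
    lactin1: Tmin < Tmax) are enforced through a log-gap
    reparameterisation so every iterate is admissible. The start grid is
    fixed (Tmin offsets {-15,-5,0} from the coldest observed temperature,
    Tmax offsets {0,5,15} above the warmest, Topt over the observed
    temperatures, amplitude from the largest observed rate), making the
    fit fully deterministic.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    T, y = _extract_xy(rates)
    k = _N_PARAMS[model]
    if len(np.unique(T)) < k + 1:
        raise ValueError(
            f"fit_tpc({model}) needs at least {k + 1} distinct temperatures"
        )
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    if w.shape != y.shape or np.any(w < 0):
        raise ValueError("weights must be nonnegative and match the data")
    sw = np.sqrt(w)
    strain = rates[0].strain if rates else ""
    n = y.size

    if model == "linear":
        params, resid = _fit_linear(T, y, w)
        converged = True
    else:
        tmin_starts = [T.min() - 15.0, T.min() - 5.0, T.min()]
        tmax_starts = [T.max(), T.max() + 5.0, T.max() + 15.0]
        topt_starts = sorted(np.unique(T).tolist())
        amp = max(float(y.max()), 1e-6)

        def pack_ctmi(theta):
            ln_mu, tmin, g1, g2 = theta
            topt = tmin + math.exp(g1)
            return {
                "mu_opt": math.exp(ln_mu),
                "Tmin": tmin,
                "Topt": topt,
                "Tmax": topt + math.exp(g2),
            }

        def pack_lactin(theta):
            ln_a, tmin, g = theta
            return {"a": math.exp(ln_a), "Tmin": tmin, "Tmax": tmin + math.exp(g)}

        def pack_lactin_classical(theta):
            rho, tmax, ln_d = theta
            return {"rho": rho, "Tmax": tmax, "delta": math.exp(ln_d)}

        if model == "ctmi":
            pack = pack_ctmi

            def raw(theta, TT):
                p = pack_ctmi(theta)
                return _ctmi_raw(TT, p["mu_opt"], p["Tmin"], p["Topt"], p["Tmax"])

            starts = [
                np.array([math.log(amp), tmin0, math.log(max(topt0 - tmin0, 1.0)),
                          math.log(max(tmax0 - topt0, 1.0))])
                for tmin0 in tmin_starts
                for topt0 in topt_starts
                for tmax0 in tmax_starts
                if tmin0 < topt0 < tmax0
            ]
        elif model == "lactin1":
            pack = pack_lactin

            def raw(theta, TT):
                p = pack_lactin(theta)
                return _lactin1_raw(TT, p["a"], p["Tmin"], p["Tmax"])

            starts = []
            for tmin0 in tmin_starts:
                for tmax0 in tmax_starts:
                    if tmin0 >= tmax0:
                        continue
                    topt0 = tmin0 + 2.0 * (tmax0 - tmin0) / 3.0
                    a0 = amp / max((topt0 - tmin0) ** 2 * (tmax0 - topt0), 1e-9)
                    starts.append(
                        np.array([math.log(a0), tmin0, math.log(tmax0 - tmin0)])
                    )
        else:  # lactin1_classical
            pack = pack_lactin_classical

            def raw(theta, TT):
                p = pack_lactin_classical(theta)
                return _lactin1_classical_raw(TT, p["rho"], p["Tmax"], p["delta"])

            starts = [
                np.array([rho0, tmax0, math.log(d0)])
                for rho0 in (0.01, 0.05, 0.1)
                for tmax0 in tmax_starts
                for d0 in (1.0, 5.0)
            ]

        def residuals(theta):
            return sw * (raw(theta, T) - y)

        best = None
        converged = False
        for theta0 in starts:
            try:
                sol = optimize.least_squares(
                    residuals, theta0, method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except (ValueError, OverflowError):
                continue
            rss_cand = float(np.sum(sol.fun**2))
            if best is None or rss_cand < best[0] - 1e-15:
                best = (rss_cand, sol.x, sol.success)
        if best is None:
            return TPCFit(model=model, params={}, rss=math.inf, n=n, k=k,
                          aic=math.inf, pseudo_r2=math.nan, adj_r2=math.nan,
                          converged=False, strain=strain)
        params = pack(best[1])
        converged = bool(best[2])
        resid = raw(best[1], T) - y

    rss = float(np.sum(w * resid**2))
    aic = aic_gaussian_raw(n=n, rss=rss, k=k)
    fit = TPCFit(model=model, params=params, rss=rss, n=n, k=k, aic=aic,
                 pseudo_r2=math.nan, adj_r2=math.nan, converged=converged,
                 strain=strain)
    pr2, ar2 = r2_measures(fit, rates)
    return TPCFit(model=model, params=params, rss=rss, n=n, k=k, aic=aic,
                  pseudo_r2=pr2, adj_r2=ar2, converged=converged, strain=strain)


def aic_gaussian_raw(n: int, rss: float, k: int) -> float:
    """Gaussian-likelihood AIC: n·ln(rss/n) + 2·(k+1).

    The +1 counts the error variance as an estimated parameter. For a
    numerically perfect fit (rss == 0) the criterion is -inf.
    """
    if n <= k + 1:
        raise ValueError("AIC requires n > k + 1")
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if rss == 0:
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (k + 1)


def aic_gaussian(fit: TPCFit) -> float:
    return aic_gaussian_raw(n=fit.n, rss=fit.rss, k=fit.k)


def r2_measures(fit: TPCFit, rates: Sequence[GrowthRate]) -> tuple[float, float]:
    """(pseudo-R², adjusted R²) of a TPC fit against the observed rates.

    pseudo-R² = 1 − RSS/TSS with TSS about the observed mean;
    adj-R² = 1 − (1 − pseudo-R²)(n − 1)/(n − k − 1).
    """
    _, y = _extract_xy(rates)
    if y.size < 2 or np.ptp(y) == 0:
        raise ValueError("r2_measures needs >=2 observations with variation")
    tss = float(np.sum((y - y.mean()) ** 2))
    pseudo = 1.0 - fit.rss / tss
    n, k = y.size, fit.k
    adj = 1.0 - (1.0 - pseudo) * (n - 1) / (n - k - 1)
    return pseudo, adj


def vuong_test(
    fitA: TPCFit,
    fitB: TPCFit,
    rates: Sequence[GrowthRate],
    alpha: float = 0.05,
) -> VuongResult:
    """Vuong's non-nested likelihood-ratio test between two fitted models.

    Each model's per-observation Gaussian log-likelihood uses its own
    ML variance rss/n. z = Σmᵢ / (√n · ω̂) with ω̂ the ML (ddof=0)
    standard deviation of the log-likelihood differences mᵢ; two-sided
    normal p. Positive z favours model A.
    """
    if fitA.n != fitB.n or fitA.n != len(rates):
        raise ValueError("both fits must be on the same observations")
    T, y = _extract_xy(rates)
    n = y.size

    def loglik_i(fit):
        mu = np.atleast_1d(eval_tpc(fit.model, fit.params, T))
        s2 = max(fit.rss / n, 1e-300)
        return -0.5 * (math.log(2 * math.pi * s2) + (y - mu) ** 2 / s2)

    m = loglik_i(fitA) - loglik_i(fitB)
    sd = float(np.std(m))  # ML (ddof=0) estimate, Vuong's omega-hat
    if sd < 1e-12:
        return VuongResult(z=0.0, p=1.0, n=n, verdict="indistinguishable")
    z = float(np.sum(m) / (math.sqrt(n) * sd))
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p < alpha:
        verdict = "A_preferred" if z > 0 else "B_preferred"
    else:
        verdict = "indistinguishable"
    return VuongResult(z=z, p=p, n=n, verdict=verdict)


def select_model(fits: Sequence[TPCFit], aic_tie: float = 2.0) -> ModelSelection:
    """Rank fits by AIC (ascending); near-ties (|ΔAIC| < aic_tie) are
    broken by adjusted R², and any remaining exact ties are flagged for
    a Vuong test."""
    if not fits:
        raise ValueError("select_model needs at least one fit")
    ranked = sorted(fits, key=lambda f: (f.aic, -f.adj_r2 if math.isfinite(f.adj_r2) else 0.0))
    best = ranked[0]
    tie_broken = False
    needs_vuong: list[tuple[str, str]] = []
    if len(ranked) > 1:
        contenders = [f for f in ranked[1:] if abs(f.aic - ranked[0].aic) < aic_tie]
        if contenders:
            pool = [ranked[0], *contenders]
            by_r2 = sorted(pool, key=lambda f: -f.adj_r2)
            if by_r2[0] is not best:
                tie_broken = True
            best = by_r2[0]
            for f in pool:
                if f is not best and f.adj_r2 == best.adj_r2:
                    needs_vuong.append((best.model, f.model))
        ranked = [best] + [f for f in ranked if f is not best]
    return ModelSelection(
        ranked=tuple(ranked),
        best=best,
        tie_broken_by_adj_r2=tie_broken,
        needs_vuong=tuple(needs_vuong),
    )


def cardinal_summary(per_strain: Mapping[str, object]) -> CardinalSummary:
    """Collect cardinal temperatures across strains.

    ``per_strain`` maps strain → TPCFit (a model with Tmin/Topt/Tmax in
    its parameters) or a (Tmin, Topt, Tmax, mu_opt) tuple. Reports the
    literal overall [min Tmin, max Tmax] and the [min, max] range of
    Topt; any exclusion of outlying strains is the caller's decision.
    """
    if not per_strain:
        raise ValueError("cardinal_summary needs at least one strain")
    table: dict[str, tuple[float, float, float, float]] = {}
    for strain, obj in per_strain.items():
        if isinstance(obj, TPCFit):
            p = obj.params
            if not {"Tmin", "Topt", "Tmax"} <= p.keys():
                raise ValueError(
                    f"fit for {strain!r} ({obj.model}) has no cardinal temperatures"
                )
            table[strain] = (
                float(p["Tmin"]), float(p["Topt"]), float(p["Tmax"]),
                float(p.get("mu_opt", math.nan)),
            )
        else:
            tmin, topt, tmax, mu = obj  # type: ignore[misc]
            table[strain] = (float(tmin), float(topt), float(tmax), float(mu))
    tmins = [v[0] for v in table.values()]
    topts = [v[1] for v in table.values()]
    tmaxs = [v[2] for v in table.values()]
    return CardinalSummary(
        per_strain=table,
        overall_tmin=min(tmins),
        overall_tmax=max(tmaxs),
        topt_range=(min(topts), max(topts)),
    )
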