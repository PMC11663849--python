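"""Synthetic-data generators mirroring the study designs.

The original bioassays (30 tenerals × 3 replicates observed daily for
15 days; 6 temperatures × 4 plates × 14 days of quadrant radii; 100
conidia × 4 coverslips; 3 receiver flies per day per replicate sampled
on days 1/3/5) published no raw data, so every downstream stage is
exercised on generated inputs whose designs and effect structures match
those protocols. All generators are bit-reproducible for a fixed seed.

Generative models
-----------------
* Mortality: each fly's fungus-induced death time is a continuous
  logistic variable with midpoint ``lt50_true`` and steepness
  ``slope_true``, observed at the daily inspection (ceil, clamped to
  day >= 1), so the cumulative death probability by day t is exactly the
  logistic the analysis-stage GLM fits. A geometric background process
  (``control_daily_hazard``) competes; the earliest death wins. Control
  mortality levels are rarely reported in this assay family; 0.5%/day is
  this package's default for a healthy colony.
* Radial growth: radius = plug + rate(T)·day + Gaussian noise, truncated
  to the physical plate ([plug_radius, plate_radius_max]); per-series
  monotonicity is deliberately NOT enforced (measurement noise).
* Germination: Binomial(n_conidia, p(T)) per coverslip.
* Survival: geometric death day per subject, administratively censored
  at the end of the observation window.
* Conidia loads: lognormal multiplicative noise around exponential decay
  initial_load · retention^day (loads are positive and right-skewed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .bioassay import GerminationCount, MortalityRecord
from .survival import SurvivalRecord
from .thermal import RadialGrowthSeries, eval_tpc
from .transmission import ConidiaLoad

__all__ = [
    "BioassaySimConfig",
    "TPCSimConfig",
    "TransmissionSimConfig",
    "SurvivalSimConfig",
    "gen_mortality",
    "gen_radial_growth",
    "gen_germination",
    "gen_survival",
    "gen_transmission",
]

STUDY_TEMPERATURES = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)


@dataclass(frozen=True)
class BioassaySimConfig:
    """Time–mortality bioassay design: 30 flies × 3 replicates, 15 days."""

    n_flies_per_replicate: int = 30
    n_replicates: int = 3
    lt50_true: float = 15.0
    slope_true: float = 0.5
    control_daily_hazard: float = 0.005
    horizon: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_flies_per_replicate < 1:
            raise ValueError("n_flies_per_replicate must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.lt50_true <= 0:
            raise ValueError("lt50_true must be > 0")
        if self.slope_true <= 0:
            raise ValueError("slope_true must be > 0")
        if not 0 <= self.control_daily_hazard < 1:
            raise ValueError("control_daily_hazard must lie in [0, 1)")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass(frozen=True)
class TPCSimConfig:
    """Radial-growth design: 6 temperatures × 4 plates × 14 daily readings."""

    true_model: str = "ctmi"
    true_params: Mapping[str, float] = field(
        default_factory=lambda: {"mu_opt": 2.0, "Tmin": 10.0, "Topt": 27.0, "Tmax": 40.0}
    )
    temperatures: tuple[float, ...] = STUDY_TEMPERATURES
    n_plates: int = 4
    n_days: int = 14
    plug_radius: float = 4.0  # mm, 8 mm cork-borer plug
    plate_radius_max: float = 45.0  # mm, half of a 9 cm Petri dish
    noise_sd: float = 0.1  # mm; 5% of the default mu_opt
    seed: int = 0

    def __post_init__(self):
        if self.true_model not in ("linear", "lactin1", "ctmi"):
            raise ValueError("true_model must be one of linear, lactin1, ctmi")
        if not self.temperatures:
            raise ValueError("temperatures must be nonempty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.plug_radius < self.plate_radius_max:
            raise ValueError("plug_radius must be < plate_radius_max")
        if self.n_plates < 1 or self.n_days < 2:
            raise ValueError("need n_plates >= 1 and n_days >= 2")


@dataclass(frozen=True)
class TransmissionSimConfig:
    """Receiver sampling design: 3 flies/day/replicate on days 1, 3, 5."""

    initial_load: float = 4.5e6  # conidia/mL
    daily_retention: float = 0.8
    sampling_days: tuple[int, ...] = (1, 3, 5)
    n_flies_per_day: int = 3
    n_replicates: int = 3
    lognormal_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.initial_load < 0:
            raise ValueError("initial_load must be >= 0")
        if not 0 < self.daily_retention <= 1:
            raise ValueError("daily_retention must lie in (0, 1]")
        if list(self.sampling_days) != sorted(set(self.sampling_days)):
            raise ValueError("sampling_days must be strictly increasing")
        if self.lognormal_sd < 0:
            raise ValueError("lognormal_sd must be >= 0")
        if self.n_flies_per_day < 1 or self.n_replicates < 1:
            raise ValueError("n_flies_per_day and n_replicates must be >= 1")


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Daily-observation survival design with administrative censoring."""

    group_hazards: Mapping[str, float] = field(
        default_factory=lambda: {"donor": 0.08, "receiver": 0.08}
    )
    n_per_group: int = 30
    censor_day: int = 15
    seed: int = 0

    def __post_init__(self):
        if not self.group_hazards:
            raise ValueError("group_hazards must be nonempty")
        for g, h in self.group_hazards.items():
            if not 0 <= h < 1:
                raise ValueError(f"group_hazards[{g!r}] must lie in [0, 1)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.censor_day < 1:
            raise ValueError("censor_day must be >= 1")


def gen_mortality(
    cfg: BioassaySimConfig, treatment_id: str = "treated"
) -> list[MortalityRecord]:
    """Simulate cumulative mortality counts for one treatment.

    Death day = min(ceil(X), G) where X ~ Logistic(lt50_true,
    1/slope_true) (fungal process, clamped to day >= 1) and G is
    geometric with the control hazard; flies whose death day exceeds the
    horizon survive the observation window.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[MortalityRecord] = []
    n = cfg.n_flies_per_replicate
    for rep in range(1, cfg.n_replicates + 1):
        u = rng.uniform(size=n)
        x = cfg.lt50_true + np.log(u / (1.0 - u)) / cfg.slope_true
        fungal_day = np.maximum(np.ceil(x), 1.0)
        if cfg.control_daily_hazard > 0:
            background_day = rng.geometric(cfg.control_daily_hazard, size=n).astype(float)
        else:
            background_day = np.full(n, np.inf)
        death_day = np.minimum(fungal_day, background_day)
        for day in range(1, cfg.horizon + 1):
            records.append(
                MortalityRecord(
                    treatment_id=treatment_id,
                    replicate=f"R{rep}",
                    day=day,
                    n_initial=n,
                    n_dead_cum=int(np.sum(death_day <= day)),
                )
            )
    return records


def gen_radial_growth(cfg: TPCSimConfig) -> list[RadialGrowthSeries]:
    """Simulate quadrant radii: plug + rate(T)·day + noise, truncated to
    the plate."""
    rng = np.random.default_rng(cfg.seed)
    out: list[RadialGrowthSeries] = []
    for temp in cfg.temperatures:
        rate = float(eval_tpc(cfg.true_model, dict(cfg.true_params), temp))
        for plate in range(1, cfg.n_plates + 1):
            plate_id = f"T{temp:g}_P{plate}"
            noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_days, 4)) if cfg.noise_sd > 0 else np.zeros((cfg.n_days, 4))
            for day in range(1, cfg.n_days + 1):
                radii = cfg.plug_radius + rate * day + noise[day - 1]
                radii = np.clip(radii, cfg.plug_radius, cfg.plate_radius_max)
                out.append(
                    RadialGrowthSeries(
                        plate_id=plate_id,
                        strain="sim",
                        temperature=float(temp),
                        day=day,
                        quadrant_radii=tuple(float(r) for r in radii),
                    )
                )
    return out


def gen_germination(
    prob_model: Callable[[float], float],
    temperatures: Sequence[float] = STUDY_TEMPERATURES,
    n_plates: int = 4,
    seed: int = 0,
    n_coverslips: int = 4,
    n_conidia: int = 100,
) -> list[GerminationCount]:
    """Binomial germination counts per coverslip with probability p(T),
    clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    out: list[GerminationCount] = []
    for temp in temperatures:
        p = float(np.clip(prob_model(temp), 0.0, 1.0))
        for plate in range(1, n_plates + 1):
            counts = rng.binomial(n_conidia, p, size=n_coverslips)
            for cs in range(1, n_coverslips + 1):
                out.append(
                    GerminationCount(
                        plate_id=f"T{temp:g}_P{plate}",
                        coverslip_index=cs,
                        n_germinated=int(counts[cs - 1]),
                        n_scored=n_conidia,
                        temperature=float(temp),
                    )
                )
    return out


def gen_survival(cfg: SurvivalSimConfig) -> list[SurvivalRecord]:
    """Geometric death days per group, censored at ``censor_day``."""
    rng = np.random.default_rng(cfg.seed)
    out: list[SurvivalRecord] = []
    for group in cfg.group_hazards:  # insertion order: deterministic
        h = cfg.group_hazards[group]
        if h > 0:
            days = rng.geometric(h, size=cfg.n_per_group)
        else:
            days = np.full(cfg.n_per_group, np.iinfo(np.int64).max)
        for i, d in enumerate(days, start=1):
            censored = d > cfg.censor_day
            out.append(
                SurvivalRecord(
                    subject_id=f"{group}_{i}",
                    group=group,
                    time=float(cfg.censor_day if censored else d),
                    event=0 if censored else 1,
                )
            )
    return out


def gen_transmission(
    cfg: TransmissionSimConfig,
    sex: str = "F",
    role: str = "receiver",
    irradiated: bool = False,
) -> list[ConidiaLoad]:
    """Lognormal loads decaying as initial_load · retention^day."""
    rng = np.random.default_rng(cfg.seed)
    out: list[ConidiaLoad] = []
    for rep in range(1, cfg.n_replicates + 1):
        for day in cfg.sampling_days:
            mean_load = cfg.initial_load * cfg.daily_retention**day
            eps = (
                rng.normal(0.0, cfg.lognormal_sd, size=cfg.n_flies_per_day)
                if cfg.lognormal_sd > 0
                else np.zeros(cfg.n_flies_per_day)
            )
            for i in range(cfg.n_flies_per_day):
                out.append(
                    ConidiaLoad(
                        fly_id=f"{role}_{sex}_R{rep}_D{day}_F{i + 1}",
                        sex=sex,
                        role=role,
                        irradiated=irradiated,
                        day_post_exposure=int(day),
                        conidia_per_ml=float(mean_load * math.exp(eps[i])),
                    )
                )
    return out
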