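"""Conidia acquisition and retention quantification.

Hemocytometer square counts are converted to conidia/mL with the
standard improved-Neubauer factor (1e4 per large 1 mm² × 0.1 mm square,
exposed as a parameter since chamber geometry varies), and per-fly loads
are summarised by role, sex and day post-exposure, with a log-linear
decay slope quantifying retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HemocytometerCount",
    "ConidiaLoad",
    "GroupLoadSummary",
    "RetentionSummary",
    "conidia_concentration",
    "retention_summary",
]

NEUBAUER_VOLUME_FACTOR = 1e4  # large square: 1 mm² × 0.1 mm depth → ×1e4 per mL


@dataclass(frozen=True)
class HemocytometerCount:
    fly_id: str
    square_counts: tuple[int, ...]
    dilution: float = 1.0
    volume_factor: float = NEUBAUER_VOLUME_FACTOR

    def __post_init__(self):
        if not self.square_counts:
            raise ValueError("at least one square count is required")
        if any(c < 0 for c in self.square_counts):
            raise ValueError("square counts must be nonnegative")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class ConidiaLoad:
    fly_id: str
    sex: str  # M | F
    role: str  # donor | receiver
    irradiated: bool
    day_post_exposure: int
    conidia_per_ml: float

    def __post_init__(self):
        if self.conidia_per_ml < 0:
            raise ValueError("conidia_per_ml must be nonnegative")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.role not in ("donor", "receiver"):
            raise ValueError("role must be 'donor' or 'receiver'")


@dataclass(frozen=True)
class GroupLoadSummary:
    role: str
    sex: str
    day: int
    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class RetentionSummary:
    groups: tuple[GroupLoadSummary, ...]
    # (role, sex) → OLS slope of ln(load) on day; NaN when undefined
    decay_slopes: dict
    n_zero_excluded: int


def conidia_concentration(hc: HemocytometerCount) -> float:
    """conidia/mL = mean count per large square × volume factor × dilution."""
    return float(np.mean(hc.square_counts)) * hc.volume_factor * hc.dilution


def retention_summary(loads: Sequence[ConidiaLoad]) -> RetentionSummary:
    """Group means/SEs per (role, sex, day) and log-linear decay slopes.

    The decay slope per (role, sex) is the OLS slope of ln(load) on day
    post-exposure; zero loads are excluded from that regression (their
    count is reported) since ln(0) is undefined. An empty input yields
    an empty summary rather than an error.
    """
    groups: dict[tuple[str, str, int], list[float]] = {}
    series: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for ld in loads:
        groups.setdefault((ld.role, ld.sex, ld.day_post_exposure), []).append(
            ld.conidia_per_ml
        )
        series.setdefault((ld.role, ld.sex), []).append(
            (ld.day_post_exposure, ld.conidia_per_ml)
        )
    summaries = []
    for (role, sex, day), vals in sorted(groups.items()):
        arr = np.asarray(vals)
        se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        summaries.append(
            GroupLoadSummary(role=role, sex=sex, day=day, mean=float(arr.mean()),
                             se=se, n=arr.size)
        )
    slopes: dict[tuple[str, str], float] = {}
    n_zero = 0
    for key, pts in sorted(series.items()):
        days = np.array([d for d, v in pts], float)
        vals = np.array([v for d, v in pts], float)
        pos = vals > 0
        n_zero += int((~pos).sum())
        days, vals = days[pos], vals[pos]
        if len(np.unique(days)) < 2:
            slopes[key] = math.nan
            continue
        res = stats.linregress(days, np.log(vals))
        slopes[key] = float(res.slope)
    return RetentionSummary(
        groups=tuple(summaries), decay_slopes=slopes, n_zero_excluded=n_zero
    )
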