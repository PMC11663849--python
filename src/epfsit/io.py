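"""CSV schemas, validated table IO, and the pipeline runner.

All tabular IO is UTF-8 CSV with a header row and '.' decimals. Days are
integers (day 1 = first day post-exposure), temperatures are °C and
concentrations conidia/mL. Each pipeline run writes a ``manifest.json``
carrying the seed and a hash of the configuration so every output is
attributable to (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import bioassay, survival, synthetic_data, thermal, transmission

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "read_table",
    "write_table",
    "run_pipeline",
    "DEFAULT_CONFIG",
]

logger = logging.getLogger("epfsit")

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict  # column → dtype ('int', 'float', 'str', 'bool')
    prefix_columns: tuple = ()  # e.g. ('square_',): one or more numbered columns
    validators: tuple = ()  # callables df → list[str] of error messages


def _validate_mortality(df: pd.DataFrame) -> list[str]:
    errors = []
    for (treatment, rep), sub in df.groupby(["treatment_id", "replicate"], sort=False):
        sub = sub.sort_values("day")
        if (np.diff(sub["n_dead_cum"].to_numpy()) < 0).any():
            row = sub.index[1:][np.diff(sub["n_dead_cum"].to_numpy()) < 0][0]
            errors.append(
                f"row {row + 2}: n_dead_cum decreases within treatment "
                f"{treatment!r} replicate {rep!r}"
            )
        bad = sub[(sub.n_dead_cum < 0) | (sub.n_dead_cum > sub.n_initial)]
        for row in bad.index:
            errors.append(f"row {row + 2}: n_dead_cum outside [0, n_initial]")
    return errors


def _validate_germination(df: pd.DataFrame) -> list[str]:
    bad = df[(df.n_germinated < 0) | (df.n_germinated > df.n_scored)]
    return [f"row {i + 2}: n_germinated outside [0, n_scored]" for i in bad.index]


def _validate_survival(df: pd.DataFrame) -> list[str]:
    errors = [f"row {i + 2}: time must be > 0" for i in df.index[df.time <= 0]]
    errors += [
        f"row {i + 2}: event must be 0 or 1" for i in df.index[~df.event.isin((0, 1))]
    ]
    return errors


SCHEMAS = {
    "mortality": TableSchema(
        name="mortality",
        columns={"treatment_id": "str", "replicate": "str", "day": "int",
                 "n_initial": "int", "n_dead_cum": "int"},
        validators=(_validate_mortality,),
    ),
    "germination": TableSchema(
        name="germination",
        columns={"plate_id": "str", "coverslip": "int", "n_germinated": "int",
                 "n_scored": "int"},
        validators=(_validate_germination,),
    ),
    "radial_growth": TableSchema(
        name="radial_growth",
        columns={"plate_id": "str", "strain": "str", "temperature": "float",
                 "day": "int", "q1": "float", "q2": "float", "q3": "float",
                 "q4": "float"},
    ),
    "growth_rates": TableSchema(
        name="growth_rates",
        columns={"strain": "str", "temperature": "float", "plate_id": "str",
                 "beta": "float", "intercept": "float", "fit_r2": "float"},
    ),
    "survival": TableSchema(
        name="survival",
        columns={"subject_id": "str", "group": "str", "time": "float",
                 "event": "int"},
        validators=(_validate_survival,),
    ),
    "hemocytometer": TableSchema(
        name="hemocytometer",
        columns={"fly_id": "str", "sex": "str", "role": "str",
                 "irradiated": "bool", "day": "int", "dilution": "float"},
        prefix_columns=("square_",),
    ),
}

_CASTERS = {
    "int": lambda s: pd.to_numeric(s, errors="raise").astype(int),
    "float": lambda s: pd.to_numeric(s, errors="raise").astype(float),
    "str": lambda s: s.astype(str),
    "bool": lambda s: s.astype(str).str.lower().isin(("true", "1", "yes")),
}


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Missing columns, non-numeric cells and violated row invariants fail
    with messages naming the offending column or 1-based file line
    (header = line 1). Unknown columns raise a warning but are kept.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    known = set(schema.columns)
    prefixed = [
        c for c in df.columns if any(c.startswith(p) for p in schema.prefix_columns)
    ]
    if schema.prefix_columns and not prefixed:
        raise ValueError(
            f"{path.name}: expected at least one column starting with "
            f"{schema.prefix_columns}"
        )
    unknown = [c for c in df.columns if c not in known and c not in prefixed]
    if unknown:
        warnings.warn(
            f"{path.name}: unknown column(s) {unknown} kept as-is", stacklevel=2
        )
    for col, kind in schema.columns.items():
        try:
            df[col] = _CASTERS[kind](df[col])
        except (ValueError, TypeError) as exc:
            bad_rows = []
            for i, v in df[col].items():
                try:
                    _CASTERS[kind](pd.Series([v]))
                except (ValueError, TypeError):
                    bad_rows.append(i + 2)
            raise ValueError(
                f"{path.name}: column {col!r} has non-{kind} value(s) at "
                f"line(s) {bad_rows[:10]}"
            ) from exc
    for col in prefixed:
        df[col] = pd.to_numeric(df[col], errors="raise")
    errors: list[str] = []
    for validate in schema.validators:
        errors.extend(validate(df))
    if errors:
        raise ValueError(f"{path.name}: " + "; ".join(errors[:20]))
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# --- record <-> frame adapters ---------------------------------------------


def mortality_records(df: pd.DataFrame) -> list[bioassay.MortalityRecord]:
    return [
        bioassay.MortalityRecord(
            treatment_id=r.treatment_id, replicate=r.replicate, day=int(r.day),
            n_initial=int(r.n_initial), n_dead_cum=int(r.n_dead_cum),
        )
        for r in df.itertuples()
    ]


def radial_series(df: pd.DataFrame) -> list[thermal.RadialGrowthSeries]:
    return [
        thermal.RadialGrowthSeries(
            plate_id=r.plate_id, strain=r.strain, temperature=float(r.temperature),
            day=int(r.day), quadrant_radii=(r.q1, r.q2, r.q3, r.q4),
        )
        for r in df.itertuples()
    ]


def survival_records(df: pd.DataFrame) -> list[survival.SurvivalRecord]:
    return [
        survival.SurvivalRecord(
            subject_id=r.subject_id, group=r.group, time=float(r.time),
            event=int(r.event),
        )
        for r in df.itertuples()
    ]


def frame_from_mortality(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.treatment_id, r.replicate, r.day, r.n_initial, r.n_dead_cum) for r in records],
        columns=["treatment_id", "replicate", "day", "n_initial", "n_dead_cum"],
    )


def frame_from_radial(series) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.plate_id, s.strain, s.temperature, s.day, *s.quadrant_radii) for s in series],
        columns=["plate_id", "strain", "temperature", "day", "q1", "q2", "q3", "q4"],
    )


def frame_from_survival(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.subject_id, r.group, r.time, r.event) for r in records],
        columns=["subject_id", "group", "time", "event"],
    )


# --- pipeline ---------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "link": "logit",
    "window": [10.0, 20.0],
    "models": ["linear", "lactin1", "ctmi"],
    "alpha": 0.05,
    "simulate": {
        "treatments": {
            "treated": {"lt50_true": 15.0, "slope_true": 0.5},
            "control": {"lt50_true": 1000.0, "slope_true": 0.5},
        },
        "control_daily_hazard": 0.005,
        "tpc": {},
        "survival": {},
        "transmission": {},
    },
}

ALL_STAGES = ("simulate", "bioassay", "thermal", "survival", "transmission", "report")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "epfsit_out",
    stages: Sequence[str] = ALL_STAGES,
    seed: int | None = None,
) -> dict:
    """Run the requested stages in order on synthetic or provided CSVs.

    ``simulate`` writes the input CSVs; each analysis stage reads its
    input CSV from ``out_dir`` and writes its result tables there. The
    manifest records the seed and config hash, making the whole bundle
    reproducible byte-for-byte from (config, seed).
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    produced: dict[str, Path] = {}

    if "simulate" in stages:
        logger.info("simulate: seed=%d", seed)
        sim = cfg["simulate"]
        recs = []
        for i, (tid, spec) in enumerate(sorted(sim["treatments"].items())):
            bcfg = synthetic_data.BioassaySimConfig(
                lt50_true=spec["lt50_true"], slope_true=spec["slope_true"],
                control_daily_hazard=sim["control_daily_hazard"],
                seed=seed + 1000 * (i + 1),
            )
            recs.extend(synthetic_data.gen_mortality(bcfg, treatment_id=tid))
        produced["mortality"] = write_table(frame_from_mortality(recs), out / "mortality.csv")

        tcfg = synthetic_data.TPCSimConfig(seed=seed + 11, **sim.get("tpc", {}))
        series = synthetic_data.gen_radial_growth(tcfg)
        produced["radial_growth"] = write_table(frame_from_radial(series), out / "radial_growth.csv")

        scfg = synthetic_data.SurvivalSimConfig(seed=seed + 12, **sim.get("survival", {}))
        produced["survival"] = write_table(
            frame_from_survival(synthetic_data.gen_survival(scfg)), out / "survival.csv"
        )

        xcfg = synthetic_data.TransmissionSimConfig(seed=seed + 13, **sim.get("transmission", {}))
        loads = synthetic_data.gen_transmission(xcfg)
        produced["conidia_loads_input"] = write_table(
            pd.DataFrame(
                [(l.fly_id, l.sex, l.role, l.irradiated, l.day_post_exposure, l.conidia_per_ml) for l in loads],
                columns=["fly_id", "sex", "role", "irradiated", "day", "conidia_per_ml"],
            ),
            out / "conidia_loads.csv",
        )

    if "bioassay" in stages:
        logger.info("bioassay: link=%s window=%s", cfg["link"], cfg["window"])
        df = read_table(out / "mortality.csv", "mortality")
        rows, compat = [], []
        control = df[df.treatment_id == "control"]
        control_pct = None
        if len(control):
            final = control[control.day == control.day.max()]
            control_pct = float(100.0 * final.n_dead_cum.sum() / final.n_initial.sum())
        for tid, sub in df.groupby("treatment_id"):
            if tid == "control":
                continue
            est = bioassay.fit_time_mortality(mortality_records(sub), link=cfg["link"])
            final = sub[sub.day == sub.day.max()]
            raw_pct = float(100.0 * final.n_dead_cum.sum() / final.n_initial.sum())
            corrected = (
                bioassay.abbott_correct(raw_pct, control_pct).corrected_pct
                if control_pct is not None else raw_pct
            )
            rows.append((tid, est.lt50, est.se, est.slope, est.slope_se, est.link,
                         est.converged, raw_pct, corrected))
            if est.converged and est.lt50 > 0:
                c = bioassay.classify_sit_compatible(
                    est.lt50, strain=tid, window=tuple(cfg["window"])
                )
                compat.append((tid, c.lt50, c.category))
        produced["lt50"] = write_table(
            pd.DataFrame(rows, columns=["treatment_id", "lt50", "se", "slope",
                                        "slope_se", "link", "converged",
                                        "mortality_pct", "abbott_corrected_pct"]),
            out / "lt50.csv",
        )
        produced["compatibility"] = write_table(
            pd.DataFrame(compat, columns=["treatment_id", "lt50", "category"]),
            out / "compatibility.csv",
        )

    if "thermal" in stages:
        logger.info("thermal: models=%s", cfg["models"])
        df = read_table(out / "radial_growth.csv", "radial_growth")
        rates = thermal.absolute_growth_rate(radial_series(df))
        fit_rows, best_fits = [], {}
        for strain in sorted({r.strain for r in rates}):
            sub = [r for r in rates if r.strain == strain]
            fits = [thermal.fit_tpc(sub, m) for m in cfg["models"]]
            for f in fits:
                fit_rows.append((strain, f.model, json.dumps(f.params), f.rss,
                                 f.n, f.k, f.aic, f.pseudo_r2, f.adj_r2, f.converged))
            best = thermal.select_model(fits).best
            if {"Tmin", "Topt", "Tmax"} <= best.params.keys():
                best_fits[strain] = best
        produced["tpc_fits"] = write_table(
            pd.DataFrame(fit_rows, columns=["strain", "model", "params", "rss", "n",
                                            "k", "aic", "pseudo_r2", "adj_r2",
                                            "converged"]),
            out / "tpc_fits.csv",
        )
        if best_fits:
            summary = thermal.cardinal_summary(best_fits)
            srows = [
                (s, *vals) for s, vals in sorted(summary.per_strain.items())
            ]
            sdf = pd.DataFrame(srows, columns=["strain", "Tmin", "Topt", "Tmax", "mu_opt"])
            sdf["overall_tmin"] = summary.overall_tmin
            sdf["overall_tmax"] = summary.overall_tmax
            sdf["topt_low"], sdf["topt_high"] = summary.topt_range
            produced["cardinal_summary"] = write_table(sdf, out / "cardinal_summary.csv")

    if "survival" in stages:
        logger.info("survival")
        df = read_table(out / "survival.csv", "survival")
        recs = survival_records(df)
        rows = []
        for grp in sorted({r.group for r in recs}):
            curve = survival.km_estimate([r for r in recs if r.group == grp])
            for t, nr, ne, s, se in zip(curve.times, curve.n_at_risk,
                                        curve.n_events, curve.survival,
                                        curve.greenwood_se):
                rows.append((grp, t, nr, ne, s, se))
        produced["km_curves"] = write_table(
            pd.DataFrame(rows, columns=["group", "time", "n_at_risk", "n_events",
                                        "survival", "greenwood_se"]),
            out / "km_curves.csv",
        )
        lr = survival.logrank_test(recs)
        produced["logrank"] = write_table(
            pd.DataFrame([(lr.chi2, lr.df, lr.p)], columns=["chi2", "df", "p"]),
            out / "logrank.csv",
        )

    if "transmission" in stages:
        logger.info("transmission")
        path = out / "hemocytometer.csv"
        if path.exists():
            df = read_table(path, "hemocytometer")
            sq_cols = [c for c in df.columns if c.startswith("square_")]
            loads = [
                transmission.ConidiaLoad(
                    fly_id=r.fly_id, sex=r.sex, role=r.role,
                    irradiated=bool(r.irradiated), day_post_exposure=int(r.day),
                    conidia_per_ml=transmission.conidia_concentration(
                        transmission.HemocytometerCount(
                            fly_id=r.fly_id,
                            square_counts=tuple(int(getattr(r, c)) for c in sq_cols),
                            dilution=float(r.dilution),
                        )
                    ),
                )
                for r in df.itertuples()
            ]
        else:
            df = pd.read_csv(out / "conidia_loads.csv")
            loads = [
                transmission.ConidiaLoad(
                    fly_id=r.fly_id, sex=r.sex, role=r.role,
                    irradiated=bool(r.irradiated), day_post_exposure=int(r.day),
                    conidia_per_ml=float(r.conidia_per_ml),
                )
                for r in df.itertuples()
            ]
        summ = transmission.retention_summary(loads)
        produced["retention_summary"] = write_table(
            pd.DataFrame(
                [(g.role, g.sex, g.day, g.mean, g.se, g.n) for g in summ.groups],
                columns=["role", "sex", "day", "mean_conidia_per_ml", "se", "n"],
            ),
            out / "retention_summary.csv",
        )
        produced["decay_slopes"] = write_table(
            pd.DataFrame(
                [(role, sex, slope) for (role, sex), slope in sorted(summ.decay_slopes.items())],
                columns=["role", "sex", "log_decay_slope_per_day"],
            ),
            out / "decay_slopes.csv",
        )

    if "report" in stages:
        manifest = {
            "schema_version": SCHEMA_VERSION,
            "seed": seed,
            "config_hash": _config_hash(cfg),
            "stages": list(stages),
            "outputs": {k: Path(v).name for k, v in produced.items()},
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        produced["manifest"] = mpath
    return produced
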