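"""CSV and YAML interfaces.

Schemas (plain CSV, header row, UTF-8, '.' decimal):

- ``vital_rates.csv``: subpop, sex, age_class, variant, mean, se
- ``recruitment.csv``: subpop, age, lpr_mean, lpr_se, litter_size_mean,
  litter_size_se
- ``harvest.csv``: subpop, season_start, season_end, kill, prop_female
- ``status_points.csv``: subpop, lambda_h0, p_decline, sampling,
  tek_call, pva_call

Validation failures are reported with row context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .engine import HarvestInterval, HarvestSchedule, SimulationConfig
from .rates import AGE_CLASSES, Rate, SEXES, VitalRates
from .stats import StatusPoint

__all__ = [
    "SchemaError",
    "ScenarioConfig",
    "read_vital_rates",
    "write_vital_rates",
    "read_harvest",
    "write_harvest",
    "read_status_points",
    "write_status_points",
    "rates_from_frames",
    "harvest_from_frame",
    "load_scenario_config",
]


class SchemaError(ValueError):
    """A table violated its schema or a domain invariant."""


def _require_columns(df: pd.DataFrame, cols, name: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


# -- vital rates ------------------------------------------------------------


def rates_from_frames(
    survival_df: pd.DataFrame,
    recruitment_df: pd.DataFrame,
    subpop: str,
    variant: str = "natural",
    cub_sex_ratio: float = 0.5,
    max_age: int = 30,
) -> VitalRates:
    """Assemble a :class:`VitalRates` from schema DataFrames."""
    _require_columns(
        survival_df, ["subpop", "sex", "age_class", "variant", "mean", "se"], "vital_rates"
    )
    _require_columns(
        recruitment_df,
        ["subpop", "age", "lpr_mean", "lpr_se", "litter_size_mean", "litter_size_se"],
        "recruitment",
    )
    surv = survival_df[
        (survival_df.subpop == subpop) & (survival_df.variant == variant)
    ]
    if surv.empty:
        raise SchemaError(f"no survival rows for subpop {subpop!r} variant {variant!r}")
    survival = {}
    for idx, row in surv.iterrows():
        if row.sex not in SEXES or row.age_class not in AGE_CLASSES:
            raise SchemaError(
                f"vital_rates row {idx}: unknown sex/age_class "
                f"({row.sex!r}, {row.age_class!r})"
            )
        if not (0.0 <= row["mean"] <= 1.0):
            raise SchemaError(
                f"vital_rates row {idx}: survival mean {row['mean']} outside [0,1]"
            )
        survival[(row.sex, row.age_class)] = Rate(float(row["mean"]), float(row.se))
    rec = recruitment_df[recruitment_df.subpop == subpop]
    if rec.empty:
        raise SchemaError(f"no recruitment rows for subpop {subpop!r}")
    lpr = {}
    for idx, row in rec.iterrows():
        if not (0.0 <= row.lpr_mean <= 1.0):
            raise SchemaError(
                f"recruitment row {idx}: litter production {row.lpr_mean} outside [0,1]"
            )
        lpr[int(row.age)] = Rate(float(row.lpr_mean), float(row.lpr_se))
    ls = rec.iloc[0]
    try:
        return VitalRates(
            subpop,
            survival,
            rate_variant=variant,
            litter_production=lpr,
            litter_size=Rate(float(ls.litter_size_mean), float(ls.litter_size_se)),
            cub_sex_ratio=cub_sex_ratio,
            max_age=max_age,
        )
    except ValueError as e:
        raise SchemaError(f"subpop {subpop!r}: {e}") from e


def read_vital_rates(
    survival_path, recruitment_path, subpop: str, variant: str = "natural", **kw
) -> VitalRates:
    return rates_from_frames(
        pd.read_csv(survival_path), pd.read_csv(recruitment_path), subpop, variant, **kw
    )


def write_vital_rates(rates: VitalRates, survival_path, recruitment_path):
    rows = [
        {
            "subpop": rates.subpop_id,
            "sex": sex,
            "age_class": cls,
            "variant": rates.rate_variant,
            "mean": rate.mean,
            "se": rate.se,
        }
        for (sex, cls), rate in sorted(rates.survival.items())
    ]
    pd.DataFrame(rows).to_csv(survival_path, index=False)
    rec_rows = [
        {
            "subpop": rates.subpop_id,
            "age": age,
            "lpr_mean": r.mean,
            "lpr_se": r.se,
            "litter_size_mean": rates.litter_size.mean,
            "litter_size_se": rates.litter_size.se,
        }
        for age, r in sorted(rates.litter_production.items())
    ]
    pd.DataFrame(rec_rows).to_csv(recruitment_path, index=False)


# -- harvest ----------------------------------------------------------------


def harvest_from_frame(df: pd.DataFrame, subpop: str) -> HarvestSchedule:
    _require_columns(
        df, ["subpop", "season_start", "season_end", "kill", "prop_female"], "harvest"
    )
    sub = df[df.subpop == subpop]
    intervals = []
    for idx, row in sub.iterrows():
        try:
            intervals.append(
                HarvestInterval(
                    int(row.season_start),
                    int(row.season_end),
                    float(row.kill),
                    float(row.prop_female),
                )
            )
        except ValueError as e:
            raise SchemaError(f"harvest row {idx}: {e}") from e
    try:
        return HarvestSchedule(intervals)
    except ValueError as e:
        raise SchemaError(f"harvest for {subpop!r}: {e}") from e


def read_harvest(path, subpop: str) -> HarvestSchedule:
    return harvest_from_frame(pd.read_csv(path), subpop)


def write_harvest(schedule: HarvestSchedule, subpop: str, path):
    rows = [
        {
            "subpop": subpop,
            "season_start": iv.start,
            "season_end": iv.end,
            "kill": iv.removals,
            "prop_female": iv.prop_female,
        }
        for iv in schedule.intervals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- status points ----------------------------------------------------------


def read_status_points(path) -> list:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["subpop", "lambda_h0", "p_decline", "sampling", "tek_call", "pva_call"],
        "status_points",
    )
    points = []
    for idx, row in df.iterrows():
        try:
            points.append(
                StatusPoint(
                    str(row.subpop),
                    float(row.lambda_h0),
                    float(row.p_decline),
                    str(row.sampling),
                    str(row.tek_call),
                    str(row.pva_call),
                )
            )
        except ValueError as e:
            raise SchemaError(f"status_points row {idx}: {e}") from e
    return points


def write_status_points(points, path):
    pd.DataFrame(
        [
            {
                "subpop": p.subpop_id,
                "lambda_h0": p.lambda_unharvested,
                "p_decline": p.p_decline,
                "sampling": p.sampling,
                "tek_call": p.tek_call,
                "pva_call": p.pva_call,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


# -- scenario configuration -------------------------------------------------


@dataclass
class ScenarioConfig:
    """Validated scenario: resolved file paths plus simulation settings."""

    subpops: list
    vital_rates_path: Path
    recruitment_path: Path
    harvest_path: Path | None
    status_points_path: Path | None
    simulation: SimulationConfig
    output_dir: Path = Path("results")
    tables: dict = field(default_factory=dict)


def load_scenario_config(path) -> ScenarioConfig:
    """Load a YAML scenario file and validate every referenced table."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(key, required):
        p = raw.get(key)
        if p is None:
            if required:
                raise SchemaError(f"scenario config: missing {key!r}")
            return None
        p = base / p
        if not p.exists():
            raise SchemaError(f"scenario config: {key} file not found: {p}")
        return p

    vr = resolve("vital_rates", True)
    rec = resolve("recruitment", True)
    harv = resolve("harvest", False)
    stat = resolve("status_points", False)
    sim_raw = raw.get("simulation", {})
    try:
        sim = SimulationConfig(**sim_raw)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"scenario config: bad simulation block: {e}") from e

    subpops = raw.get("subpops")
    surv_df = pd.read_csv(vr)
    rec_df = pd.read_csv(rec)
    _require_columns(
        surv_df, ["subpop", "sex", "age_class", "variant", "mean", "se"], "vital_rates"
    )
    if subpops is None:
        subpops = sorted(surv_df.subpop.unique())
    tables = {"vital_rates": surv_df, "recruitment": rec_df}
    harv_df = None
    if harv is not None:
        harv_df = pd.read_csv(harv)
        tables["harvest"] = harv_df
    for sp in subpops:
        for variant in surv_df[surv_df.subpop == sp].variant.unique():
            rates_from_frames(surv_df, rec_df, sp, variant)  # validates
        if harv_df is not None and (harv_df.subpop == sp).any():
            harvest_from_frame(harv_df, sp)
    if stat is not None:
        tables["status_points"] = read_status_points(stat)
    return ScenarioConfig(
        list(subpops),
        vr,
        rec,
        harv,
        stat,
        sim,
        Path(raw.get("output_dir", "results")),
        tables,
    )
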