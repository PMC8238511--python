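"""Reading and writing model inputs, traces, reports and run manifests.

Inputs travel either as individual CSV tables (documented headers below) or
as one YAML/JSON bundle holding every section inline.  All monetary outputs
carry a ``currency: GBP`` field; reports embed the manifest of the run that
produced them.

CSV headers
-----------
participation : age_lower, age_upper, sex, outcome, value
lifetable     : age, sex, rate
effects       : severity, outcome, measure, point, ci_low, ci_high,
                age_lower, age_upper   (age bounds blank for generic effects)
trace         : cycle, age, state, occupancy, arm, sex
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fiscal import FiscalSchedule, HealthcareCostTable
from .markov import CohortTrace
from .model import ModelInputs
from .parameters import (
    AgeBand,
    BaselineParticipation,
    ConfigurationError,
    LifeTable,
    ModelConfig,
    MortalityAdjustment,
    OUTCOMES,
    RelativeEffect,
    RelativeEffectSet,
    SEXES,
)

logger = logging.getLogger("oafiscal")


class ValidationError(ConfigurationError):
    """Input file failed schema validation; message carries the location."""


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------


def participation_to_frame(tables: dict[str, BaselineParticipation]) -> pd.DataFrame:
    rows = []
    for sex, bp in tables.items():
        for r in bp.table.itertuples():
            for outcome in OUTCOMES:
                rows.append(
                    {
                        "age_lower": int(r.age_lower),
                        "age_upper": int(r.age_upper),
                        "sex": sex,
                        "outcome": outcome,
                        "value": getattr(r, outcome),
                    }
                )
    return pd.DataFrame(rows)


def participation_from_frame(df: pd.DataFrame) -> dict[str, BaselineParticipation]:
    required = {"age_lower", "age_upper", "sex", "outcome", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"participation table missing columns {sorted(missing)}")
    for i, outcome in enumerate(df["outcome"]):
        if outcome not in OUTCOMES:
            raise ValidationError(
                f"participation row {i + 2}: unknown outcome {outcome!r}"
            )
    out = {}
    for sex, g in df.groupby("sex"):
        wide = g.pivot_table(
            index=["age_lower", "age_upper"], columns="outcome", values="value"
        ).reset_index()
        out[str(sex)] = BaselineParticipation(wide)
    return out


def lifetable_from_frame(df: pd.DataFrame) -> LifeTable:
    return LifeTable(df)


def effects_to_frame(effects: dict[str, RelativeEffectSet]) -> pd.DataFrame:
    rows = []
    for severity, es in effects.items():
        for e in es.effects:
            rows.append(
                {
                    "severity": severity,
                    "outcome": e.outcome,
                    "measure": e.measure,
                    "point": e.point,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "age_lower": e.age_band.lower if e.age_band else None,
                    "age_upper": e.age_band.upper if e.age_band else None,
                }
            )
    return pd.DataFrame(rows)


def effects_from_records(records: list[dict]) -> dict[str, RelativeEffectSet]:
    by_sev: dict[str, list[RelativeEffect]] = {}
    for i, rec in enumerate(records):
        try:
            band = None
            if rec.get("age_lower") is not None and not pd.isna(rec.get("age_lower")):
                band = AgeBand(int(rec["age_lower"]), int(rec["age_upper"]))
            effect = RelativeEffect(
                outcome=rec["outcome"],
                measure=rec["measure"],
                point=float(rec["point"]),
                ci_low=float(rec["ci_low"]),
                ci_high=float(rec["ci_high"]),
                age_band=band,
            )
        except (KeyError, TypeError, ValueError, ConfigurationError) as exc:
            raise ValidationError(f"effects row {i + 1}: {exc}") from exc
        by_sev.setdefault(rec["severity"], []).append(effect)
    return {sev: RelativeEffectSet(sev, effs) for sev, effs in by_sev.items()}


# ---------------------------------------------------------------------------
# YAML / JSON bundle
# ---------------------------------------------------------------------------


def bundle_to_dict(inputs: ModelInputs) -> dict:
    sched = asdict(inputs.schedule)
    sched["median_labour_tax_by_age"] = [
        {"age_lower": b.lower, "age_upper": b.upper, "amount": a}
        for b, a in inputs.schedule.median_labour_tax_by_age
    ]
    return {
        "config": asdict(inputs.config),
        "schedule": sched,
        "healthcare": asdict(inputs.healthcare),
        "mortality": asdict(inputs.mortality),
        "participation": {
            sex: bp.table.to_dict(orient="records")
            for sex, bp in inputs.participation.items()
        },
        "lifetable": inputs.lifetable.table.to_dict(orient="records"),
        "effects": {
            sev: effects_to_frame({sev: es}).drop(columns="severity").to_dict(
                orient="records"
            )
            for sev, es in inputs.effects.items()
        },
    }


def bundle_from_dict(data: dict) -> ModelInputs:
    def section(name: str) -> dict | list:
        if name not in data:
            raise ValidationError(f"bundle missing section {name!r}")
        return data[name]

    try:
        config = ModelConfig(**section("config"))
    except (TypeError, ConfigurationError) as exc:
        raise ValidationError(f"config section: {exc}") from exc

    sched_data = dict(section("schedule"))
    bands = sched_data.pop("median_labour_tax_by_age", None)
    if bands is not None:
        sched_data["median_labour_tax_by_age"] = tuple(
            (AgeBand(int(b["age_lower"]), int(b["age_upper"])), float(b["amount"]))
            for b in bands
        )
    try:
        schedule = FiscalSchedule(**sched_data)
    except (TypeError, ConfigurationError) as exc:
        raise ValidationError(f"schedule section: {exc}") from exc

    hc_data = {
        k: tuple(v) if isinstance(v, (list, tuple)) else v
        for k, v in dict(section("healthcare")).items()
    }
    try:
        healthcare = HealthcareCostTable(**hc_data)
    except (TypeError, ConfigurationError) as exc:
        raise ValidationError(f"healthcare section: {exc}") from exc

    mort = dict(section("mortality"))
    for key in ("oa_excess_ci", "womac_hr_ci"):
        if key in mort:
            mort[key] = tuple(mort[key])
    try:
        mortality = MortalityAdjustment(**mort)
    except (TypeError, ConfigurationError) as exc:
        raise ValidationError(f"mortality section: {exc}") from exc

    participation = {}
    for sex, rows in section("participation").items():
        try:
            participation[sex] = BaselineParticipation(pd.DataFrame(rows))
        except ConfigurationError as exc:
            raise ValidationError(f"participation[{sex}]: {exc}") from exc

    try:
        lifetable = LifeTable(pd.DataFrame(section("lifetable")))
    except ConfigurationError as exc:
        raise ValidationError(f"lifetable section: {exc}") from exc

    effects = {}
    for sev, recs in section("effects").items():
        effects.update(
            effects_from_records([{**r, "severity": sev} for r in recs])
        )

    try:
        return ModelInputs(
            participation=participation,
            lifetable=lifetable,
            effects=effects,
            schedule=schedule,
            healthcare=healthcare,
            mortality=mortality,
            config=config,
        )
    except ConfigurationError as exc:
        raise ValidationError(str(exc)) from exc


def save_bundle(inputs: ModelInputs, path: str | Path) -> None:
    path = Path(path)
    data = bundle_to_dict(inputs)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def load_bundle(path: str | Path) -> ModelInputs:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ValidationError(f"{path}: invalid YAML{line}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: bundle must be a mapping")
    return bundle_from_dict(data)


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------


def build_manifest(
    inputs: ModelInputs, seed: int, warnings: list[str] | None = None
) -> dict:
    canonical = json.dumps(bundle_to_dict(inputs), sort_keys=True, default=float)
    return {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "package": "oafiscal",
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "warnings": warnings or [],
    }


def write_traces(traces: dict[str, dict[str, CohortTrace]], path: str | Path) -> None:
    frames = [
        trace.to_frame() for by_sex in traces.values() for trace in by_sex.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def report_to_dict(report: pd.DataFrame, manifest: dict) -> dict:
    # only the deterministic manifest keys are embedded, so identical
    # config + seed reproduce byte-identical report files; the full manifest
    # (with timestamp and warnings) lives in manifest.json
    ref = {k: manifest[k] for k in ("config_hash", "package", "version", "seed")}
    return {
        "currency": "GBP",
        "rows": {
            row: {col: round(float(report.loc[row, col]), 2) for col in report.columns}
            for row in report.index
        },
        "manifest": ref,
    }


def write_report(
    report: pd.DataFrame, manifest: dict, out_dir: str | Path, stem: str = "report"
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rounded = report.round(2)
    rounded.to_csv(out_dir / f"{stem}.csv")
    (out_dir / f"{stem}.json").write_text(
        json.dumps(report_to_dict(report, manifest), indent=2, sort_keys=True)
    )


class WarningCollector(logging.Handler):
    """Collects warning-level log records for inclusion in the manifest."""

    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())

    def __enter__(self) -> "WarningCollector":
        logger.addHandler(self)
        return self

    def __exit__(self, *exc) -> None:
        logger.removeHandler(self)
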