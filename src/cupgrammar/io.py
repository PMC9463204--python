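"""File readers/writers and the end-to-end pipeline.

The trial table is a UTF-8 comma-separated file with a mandatory header
``participant_id,species,age_months,trial_id,n_cups,sequence[,date]``;
the same records serialize to JSON as a list of objects. Summaries are
written one row per trial / per group, and every pipeline run emits a
JSON manifest (package version, seed, config hash) so outputs are
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .classifier import StrategyLabel, classify_trial
from .errors import ConfigError, CupGrammarError, SchemaError, ValidationError
from .metrics import (
    AGE_CLASSES,
    GroupSummary,
    TrialRecord,
    TrialSummary,
    age_class_of,
    select_last_trial,
    summarize_group,
    summarize_trial,
)
from .notation import parse_sequence, render_sequence
from .synthetic import (
    AgentConfig,
    CohortSchedule,
    GroupSpec,
    default_cohort_schedule,
    generate_cohort,
)

logger = logging.getLogger("cupgrammar")

_REQUIRED_COLUMNS = (
    "participant_id",
    "species",
    "age_months",
    "trial_id",
    "n_cups",
    "sequence",
)


def _record_from_row(row: dict) -> TrialRecord:
    age = row.get("age_months")
    if age in (None, "") or (isinstance(age, float) and pd.isna(age)):
        age = None
    else:
        age = int(float(age))
    n_cups = int(float(row["n_cups"]))
    date = row.get("date")
    if date in (None, "") or (isinstance(date, float) and pd.isna(date)):
        date = None
    return TrialRecord(
        participant_id=str(row["participant_id"]),
        species=str(row["species"]),
        trial_id=str(row["trial_id"]),
        n_cups=n_cups,
        events=tuple(parse_sequence(str(row.get("sequence") or ""), n_cups)),
        age_months=age,
        date=date,
    )


def read_trials(
    path, fmt: Optional[str] = None, *, fail_fast: bool = True
) -> list[TrialRecord]:
    """Read and validate a trial table (CSV or JSON).

    With ``fail_fast=False``, rows that fail to parse are skipped and
    logged with their line numbers instead of aborting the read.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str)
        rows = df.to_dict(orient="records")
    elif fmt == "json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: expected a JSON list of trial objects")
    else:
        raise SchemaError(f"unknown trial format {fmt!r}")
    if rows and fmt == "csv":
        missing = [c for c in _REQUIRED_COLUMNS if c not in rows[0]]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
    elif fmt == "csv":
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
    records: list[TrialRecord] = []
    errors: list[str] = []
    for i, row in enumerate(rows):
        if fmt == "json":
            missing = [c for c in _REQUIRED_COLUMNS if c not in row]
            if missing:
                raise SchemaError(f"{path}: row {i} missing key(s) {missing}")
        try:
            records.append(_record_from_row(row))
        except (CupGrammarError, ValueError, TypeError) as exc:
            msg = f"{path}: row {i + 1}: {exc}"
            if fail_fast:
                raise ValidationError(msg) from exc
            errors.append(msg)
            logger.warning("skipping %s", msg)
    if errors:
        logger.info("skipped %d invalid row(s)", len(errors))
    return records


def write_trials(records: Sequence[TrialRecord], path, fmt: Optional[str] = None):
    """Write trial records as CSV or JSON; inverse of :func:`read_trials`."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    rows = [
        {
            "participant_id": r.participant_id,
            "species": r.species,
            "age_months": r.age_months,
            "trial_id": r.trial_id,
            "n_cups": r.n_cups,
            "sequence": render_sequence(r.events, r.n_cups),
            "date": r.date,
        }
        for r in records
    ]
    if fmt == "csv":
        df = pd.DataFrame(rows)
        df["age_months"] = df["age_months"].astype("Int64")
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        raise SchemaError(f"unknown trial format {fmt!r}")


def labeled_events_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """One row per classified event across all trials."""
    rows = []
    for r in records:
        for i, le in enumerate(classify_trial(r)):
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "trial_id": r.trial_id,
                    "event_index": i,
                    "code": render_sequence([le.event]),
                    "label": le.label.value,
                    "pre_state": le.pre_state_digest,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_id",
            "event_index",
            "code",
            "label",
            "pre_state",
        ],
    )


def trial_summary_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "trial_id": s.trial_id,
            "species": s.species,
            "age_months": s.age_months,
            "n_cups": s.n_cups,
            "total_manipulations": s.total_manipulations,
            "success": s.success,
            "max_nesting": s.max_nesting,
            "hierarchical_level_final": s.hierarchical_level_final,
            "undefined_pcts": s.undefined_pcts,
        }
        for lab in StrategyLabel:
            row[f"n_{lab.value}"] = s.per_category_counts[lab]
            row[f"pct_{lab.value}"] = s.per_category_pct[lab]
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary_frame(groups: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = []
    for g in groups:
        row = {
            "group": g.group_label,
            "n_trials": g.n_trials,
            "min_cups_provided": g.cups_provided_range[0],
            "max_cups_provided": g.cups_provided_range[1],
            "min_max_nesting": g.max_in_nesting_range[0],
            "max_max_nesting": g.max_in_nesting_range[1],
            "success_rate": g.success_rate,
            "min_manipulations": g.min_manipulations,
            "max_manipulations": g.max_manipulations,
            "mean_manipulations": g.mean_manipulations,
            "sd_manipulations": g.sd_manipulations,
        }
        for lab in StrategyLabel:
            row[f"mean_pct_{lab.value}"] = g.mean_pct[lab]
            row[f"pooled_pct_{lab.value}"] = g.pooled_pct[lab]
        rows.append(row)
    return pd.DataFrame(rows)


def group_trials(records: Sequence[TrialRecord]) -> dict:
    """Partition last-trials into the analysis groups.

    Humans: one last-trial per participant (most cups, then most
    recent), binned into the six age classes. Other species: pooled by
    species, all trials.
    """
    groups: dict[str, list[TrialRecord]] = {}
    humans: dict[str, list[TrialRecord]] = {}
    for r in records:
        if r.species == "human":
            humans.setdefault(r.participant_id, []).append(r)
        else:
            groups.setdefault(r.species, []).append(r)
    for pid, trials in humans.items():
        last = select_last_trial(trials)
        if last.age_months is None:
            logger.warning("human participant %s has no age; skipped", pid)
            continue
        ac = age_class_of(last.age_months)
        if ac is None:
            logger.warning(
                "participant %s age %sm outside the age classes; skipped",
                pid,
                last.age_months,
            )
            continue
        groups.setdefault(ac.label, []).append(last)
    order = [ac.label for ac in AGE_CLASSES] + sorted(
        k for k in groups if k not in {ac.label for ac in AGE_CLASSES}
    )
    return {k: groups[k] for k in order if k in groups}


def schedule_from_config(cfg: dict) -> CohortSchedule:
    """Build a cohort schedule from a parsed YAML/JSON config mapping."""
    try:
        groups = []
        for g in cfg["groups"]:
            agent = g["agent"]
            config = AgentConfig(
                propensities={
                    StrategyLabel(k): float(v)
                    for k, v in agent["propensities"].items()
                },
                size_judgment_error=float(agent.get("size_judgment_error", 0.0)),
                action_budget=int(agent.get("action_budget", 100)),
                stop_on_success=bool(agent.get("stop_on_success", True)),
            )
            groups.append(
                GroupSpec(
                    label=str(g["label"]),
                    species=str(g["species"]),
                    config=config,
                    n_participants=int(g["n_participants"]),
                    trials_per_participant=int(g.get("trials_per_participant", 1)),
                    n_cups_range=tuple(g.get("n_cups_range", (9, 10))),
                    age_months_range=(
                        tuple(g["age_months_range"])
                        if g.get("age_months_range")
                        else None
                    ),
                )
            )
        return CohortSchedule(tuple(groups))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid cohort config: {exc}") from exc


def load_config(path) -> dict:
    path = Path(path)
    try:
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    except (OSError, yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def run_pipeline(
    out_dir,
    *,
    trials_path=None,
    config_path=None,
    seed: int = 0,
) -> dict:
    """simulate/read -> classify -> summarize, writing all outputs.

    Emits ``trials.csv`` (when simulating), ``labeled_events.csv``,
    ``trial_summaries.csv``, ``group_summaries.csv`` and
    ``manifest.json`` under ``out_dir``; returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_text = None
    if trials_path is not None:
        logger.info("reading trials from %s", trials_path)
        records = read_trials(trials_path)
    else:
        if config_path is not None:
            config_text = Path(config_path).read_text()
            schedule = schedule_from_config(load_config(config_path))
        else:
            schedule = default_cohort_schedule()
        logger.info(
            "simulating cohort (%d groups, seed %d)", len(schedule.groups), seed
        )
        records = [rec for rec, _ in generate_cohort(schedule, seed)]
        write_trials(records, out_dir / "trials.csv")
    logger.info("classifying %d trials", len(records))
    labeled_events_frame(records).to_csv(out_dir / "labeled_events.csv", index=False)
    summaries = [summarize_trial(r) for r in records]
    trial_summary_frame(summaries).to_csv(
        out_dir / "trial_summaries.csv", index=False
    )
    grouped = group_trials(records)
    logger.info("summarizing %d group(s)", len(grouped))
    group_summaries = [
        summarize_group(trials, label) for label, trials in grouped.items()
    ]
    group_summary_frame(group_summaries).to_csv(
        out_dir / "group_summaries.csv", index=False
    )
    manifest = {
        "package": "cupgrammar",
        "version": __version__,
        "seed": seed,
        "n_trials": len(records),
        "groups": {label: len(trials) for label, trials in grouped.items()},
        "config_sha256": (
            hashlib.sha256(config_text.encode()).hexdigest()
            if config_text
            else None
        ),
        "outputs": [
            "labeled_events.csv",
            "trial_summaries.csv",
            "group_summaries.csv",
        ],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
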