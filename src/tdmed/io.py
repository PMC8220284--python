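"""Serialization: cohort CSVs, mediation reports, YAML run configuration."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import pandas as pd
import yaml

from .mediation import MediationResult
from .synthetic import SyntheticCohort, SyntheticConfig
from .task import TaskConfig

PARTICIPANT_COLUMNS = [
    "participant_id", "age", "sex", "is_student", "monthly_income",
    "monthly_benefits", "education_level", "macarthur_ladder",
    "grisk1", "grisk2", "grisk3", "trust_q1", "trust_q2", "trust_q3",
]
TRIAL_COLUMNS = [
    "participant_id", "block_index", "trial_index", "sooner_amount",
    "sooner_delay_days", "later_amount", "later_delay_days", "sooner_on_top",
    "is_catch", "choice", "rt_ms",
]
SCREEN_COLUMNS = ["participant_id", "screen_kind", "rt_ms"]


def _check_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s) {missing}")


def read_participants(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, PARTICIPANT_COLUMNS, f"participant table {path}")
    return frame


def read_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, TRIAL_COLUMNS, f"trial log {path}")
    return frame


def read_screens(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, SCREEN_COLUMNS, f"screen log {path}")
    return frame


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """participants.csv, trials.csv, screens.csv and truth.json in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": outdir / "participants.csv",
        "trials": outdir / "trials.csv",
        "screens": outdir / "screens.csv",
        "truth": outdir / "truth.json",
    }
    cohort.participants.to_csv(paths["participants"], index=False)
    cohort.trials.to_csv(paths["trials"], index=False)
    cohort.screens.to_csv(paths["screens"], index=False)
    truth = cohort.truth.to_dict()
    truth["seed"] = cohort.config.seed
    truth["n"] = cohort.config.n
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths


def render_mediation_table(result: MediationResult) -> str:
    """Plain-text effect table (statistic, estimate, CI bounds, stars)."""
    rows = [
        ("ACME", result.acme),
        ("ADE", result.ade),
        ("total effect", result.total_effect),
        ("prop. mediated", result.prop_mediated),
    ]
    width = 16
    pct = f"{result.ci_level * 100:g}%"
    lines = [
        f"mediation: {result.treatment} -> {result.mediator} -> {result.outcome}",
        f"contrast: control={result.control_value:.4g} treat={result.treat_value:.4g}"
        f"  method={result.method}  draws={result.n_draws}  n={result.n_obs}",
        f"{'statistic':<{width}}{'estimate':>10}{f'{pct} CI low':>12}"
        f"{f'{pct} CI high':>13}{'p':>9}",
    ]
    for name, eff in rows:
        if not result.prop_mediated_defined and name == "prop. mediated":
            lines.append(f"{name:<{width}}{'undefined (total effect = 0)':>10}")
            continue
        est = f"{eff.estimate:.3f}{eff.stars}"
        lines.append(
            f"{name:<{width}}{est:>10}{eff.ci_low:>12.3f}{eff.ci_high:>13.3f}"
            f"{eff.p_value:>9.3f}"
        )
    lines.append("signif.: * p<0.05, ** p<0.01, *** p<0.001")
    return "\n".join(lines)


def write_mediation(result: MediationResult, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"json": outdir / "mediation.json", "text": outdir / "mediation.txt"}
    paths["json"].write_text(json.dumps(result.to_dict(), indent=2,
                                        default=_json_default) + "\n")
    paths["text"].write_text(render_mediation_table(result) + "\n")
    return paths


def _json_default(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_run_config(path) -> dict:
    """YAML run configuration with ``task`` and ``synthetic`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    task_cfg = TaskConfig.from_dict(raw.get("task", {}))
    out["task"] = task_cfg
    synth = dict(raw.get("synthetic", {}))
    synth["task"] = task_cfg
    out["synthetic"] = SyntheticConfig(**synth)
    out["mediation"] = dict(raw.get("mediation", {}))
    out["qc"] = dict(raw.get("qc", {}))
    return out


def dump_default_config(path) -> None:
    cfg = SyntheticConfig()
    synth = dataclasses.asdict(cfg)
    task = synth.pop("task")
    task["catch_trials"] = [list(c) for c in task["catch_trials"]]
    task["block_delays"] = list(task["block_delays"])
    doc = {"task": task, "synthetic": synth,
           "mediation": {"treatment": "objective_ses", "mediator": "auc",
                         "outcome": "trust_index", "n_draws": 1000,
                         "method": "quasi_bayesian"},
           "qc": {}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
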