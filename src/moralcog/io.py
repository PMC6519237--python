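"""Readers and writers for the task CSV schemas and fit-output JSON.

All files are UTF-8 comma-delimited CSV with ``.`` decimals; parameters
and configs travel as JSON.  Readers validate row by row and report the
offending row number on failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ChoiceRecord,
    DecisionTrial,
    JudgmentTrial,
    PredictionRecord,
    Target,
)

logger = logging.getLogger("moralcog.io")

DECISION_COLUMNS = ["subject_id", "trial_index", "dm", "ds", "target", "chose_harm"]
JUDGMENT_COLUMNS = ["subject_id", "trial_index", "dm", "ds", "agent_label", "causation", "blame"]
INFERENCE_COLUMNS = [
    "subject_id", "agent_id", "trial_index", "dm", "ds", "agent_choice",
    "prediction", "feedback_correct", "probe_character", "probe_uncertainty",
]


class SchemaError(ValueError):
    """A task file violates its schema; the message names the row."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_binary(df: pd.DataFrame, col: str, path) -> None:
    bad = df.index[~df[col].isin([0, 1])]
    if len(bad):
        raise SchemaError(f"{path}: {col} must be 0/1; bad value at row {bad[0] + 2}")


def read_decision_csv(path: str | Path) -> dict[str, list[ChoiceRecord]]:
    """Read a decision-task file into per-subject choice records."""
    df = pd.read_csv(path)
    _require_columns(df, DECISION_COLUMNS, path)
    _check_binary(df, "chose_harm", path)
    out: dict[str, list[ChoiceRecord]] = {}
    for i, row in df.iterrows():
        try:
            trial = DecisionTrial(dm=row["dm"], ds=row["ds"], target=Target(row["target"]))
            rec = ChoiceRecord(trial=trial, chose_harm=bool(row["chose_harm"]))
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{path}: invalid decision row {i + 2}: {e}") from e
        out.setdefault(str(row["subject_id"]), []).append(rec)
    return out


def read_judgment_csv(path: str | Path) -> dict[str, list[JudgmentTrial]]:
    """Read a judgment-task file into per-subject blame trials."""
    df = pd.read_csv(path)
    _require_columns(df, JUDGMENT_COLUMNS, path)
    out: dict[str, list[JudgmentTrial]] = {}
    for i, row in df.iterrows():
        kwargs = dict(dm=row["dm"], ds=row["ds"], blame=row["blame"])
        if isinstance(row.get("agent_label"), str) and row["agent_label"]:
            kwargs["agent_label"] = row["agent_label"]
        if isinstance(row.get("causation"), str) and row["causation"]:
            kwargs["causation"] = row["causation"]
        try:
            jt = JudgmentTrial(**kwargs)
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{path}: invalid judgment row {i + 2}: {e}") from e
        out.setdefault(str(row["subject_id"]), []).append(jt)
    return out


def read_inference_csv(
    path: str | Path,
) -> dict[str, dict[str, list[PredictionRecord]]]:
    """Read an inference-task file into subject -> agent -> session records.

    Validates the feedback-consistency invariant: feedback_correct must
    equal (agent_choice == prediction) on every row.
    """
    df = pd.read_csv(path)
    _require_columns(df, INFERENCE_COLUMNS, path)
    for col in ("agent_choice", "prediction", "feedback_correct"):
        _check_binary(df, col, path)
    out: dict[str, dict[str, list[PredictionRecord]]] = {}
    for i, row in df.iterrows():
        try:
            rec = PredictionRecord(
                trial=DecisionTrial(dm=row["dm"], ds=row["ds"], target=Target.OTHER),
                agent_choice=bool(row["agent_choice"]),
                participant_prediction=bool(row["prediction"]),
                feedback_correct=bool(row["feedback_correct"]),
            )
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{path}: invalid inference row {i + 2}: {e}") from e
        out.setdefault(str(row["subject_id"]), {}).setdefault(
            str(row["agent_id"]), []
        ).append(rec)
    return out


def write_decision_csv(path: str | Path, records: dict[str, Sequence[ChoiceRecord]]) -> None:
    rows = [
        {
            "subject_id": sid,
            "trial_index": ti,
            "dm": r.trial.dm,
            "ds": r.trial.ds,
            "target": r.trial.target.value,
            "chose_harm": int(r.chose_harm),
        }
        for sid, recs in records.items()
        for ti, r in enumerate(recs)
    ]
    pd.DataFrame(rows, columns=DECISION_COLUMNS).to_csv(path, index=False)


def write_fit_json(path: str | Path, fits: dict, *, seed: int | None = None, config: dict | None = None) -> None:
    """Write per-subject fit output with the run's seed and config hash."""
    payload = {"seed": seed, "config_hash": config_hash(config or {}), "fits": fits}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def read_fit_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=_json_default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "model_dump"):
        return obj.model_dump()
    raise TypeError(f"not JSON serializable: {type(obj)}")
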