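"""Plain-text cohort serialization.

A cohort on disk is one directory containing a JSON manifest
(``cohort.json``) plus one CSV file per trial.  Trial CSVs have one row
per sample and one column per axis, headed ``<placement>_<x|y|z>``
(two-axis finger units use ``x`` and ``y``); numbers are written with 12
significant digits in the C locale, so round-trips are lossless to well
beyond 9 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    PLACEMENTS,
    TWO_AXIS_PLACEMENTS,
    SensorChannel,
    SensorTrial,
    SubjectSession,
    ValidationError,
)

__all__ = ["read_cohort", "write_cohort", "MANIFEST_NAME"]

MANIFEST_NAME = "cohort.json"
_AXES = ("x", "y", "z")
_FLOAT_FMT = "%.12g"


def _trial_filename(subject_id: str, trial: SensorTrial) -> str:
    return f"{subject_id}_{trial.task_id}_rep{trial.repetition}.csv"


def _trial_frame(trial: SensorTrial) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for placement in PLACEMENTS:  # stable column order
        if placement not in trial.channels:
            continue
        ch = trial.channels[placement]
        for ax in range(ch.n_axes):
            cols[f"{placement}_{_AXES[ax]}"] = ch.samples[:, ax]
    return pd.DataFrame(cols)


def write_cohort(sessions: list[SubjectSession], path: str | Path) -> Path:
    """Write a validated cohort to ``path``; returns the manifest path.

    The layout is deterministic: subjects in input order, trials in input
    order, columns in canonical placement order.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "armscore-cohort", "version": 1, "subjects": []}
    for session in sessions:
        session.validate()
        entry = {
            "subject_id": session.subject_id,
            "diagnosis": session.diagnosis,
            "visit": session.visit,
            "fma_true": int(session.fma_true),
            "fas_true_per_task": {
                k: float(v) for k, v in session.fas_true_per_task.items()
            },
            "demographics": session.demographics,
            "trials": [],
        }
        for trial in session.trials:
            fname = _trial_filename(session.subject_id, trial)
            _trial_frame(trial).to_csv(
                path / fname, index=False, float_format=_FLOAT_FMT
            )
            entry["trials"].append(
                {
                    "file": fname,
                    "task_id": trial.task_id,
                    "repetition": int(trial.repetition),
                    "fs": float(trial.fs),
                    "start_marker": int(trial.start_marker),
                    "end_marker": int(trial.end_marker),
                }
            )
        manifest["subjects"].append(entry)
    manifest_path = path / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=False))
    return manifest_path


def _read_trial(path: Path, meta: dict, subject_id: str) -> SensorTrial:
    csv_path = path / meta["file"]
    if not csv_path.exists():
        raise FileNotFoundError(
            f"trial file {meta['file']} for subject {subject_id} is missing"
        )
    frame = pd.read_csv(csv_path)
    channels: dict[str, SensorChannel] = {}
    for placement in PLACEMENTS:
        axis_cols = [
            f"{placement}_{ax}"
            for ax in _AXES
            if f"{placement}_{ax}" in frame.columns
        ]
        if not axis_cols:
            continue
        expected = 2 if placement in TWO_AXIS_PLACEMENTS else 3
        if len(axis_cols) != expected:
            raise ValidationError(
                f"subject {subject_id} trial {meta['file']}: placement "
                f"{placement!r} has {len(axis_cols)} axis columns, "
                f"expected {expected}"
            )
        channels[placement] = SensorChannel(
            placement=placement,
            samples=frame[axis_cols].to_numpy(dtype=float),
            fs=float(meta["fs"]),
        )
    trial = SensorTrial(
        task_id=meta["task_id"],
        repetition=int(meta["repetition"]),
        channels=channels,
        start_marker=int(meta["start_marker"]),
        end_marker=int(meta["end_marker"]),
    )
    return trial


def read_cohort(path: str | Path) -> list[SubjectSession]:
    """Read and validate a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    sessions: list[SubjectSession] = []
    for entry in manifest["subjects"]:
        subject_id = entry["subject_id"]
        trials = [_read_trial(path, m, subject_id) for m in entry["trials"]]
        session = SubjectSession(
            subject_id=subject_id,
            diagnosis=entry["diagnosis"],
            visit=entry["visit"],
            fma_true=int(entry["fma_true"]),
            fas_true_per_task={
                k: float(v) for k, v in entry["fas_true_per_task"].items()
            },
            trials=trials,
            demographics=entry.get("demographics"),
        )
        session.validate()
        sessions.append(session)
    return sessions
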