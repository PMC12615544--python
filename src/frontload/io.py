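"""Plain-text I/O: trial logs (CSV), experiment configs (JSON), and a
best-effort reader for externally deposited trial tables."""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .synthetic import ExperimentConfig, TrialRecord, config_from_dict, config_to_dict

__all__ = [
    "trials_to_csv",
    "trials_from_csv",
    "trials_to_frame",
    "write_config",
    "read_config",
    "read_external_trials",
]

_COLUMNS = ["subject_id", "trial_index", "missing_target", "preview_time"] + [
    f"t{j}" for j in range(1, 7)
]


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """One row per trial; missing_target empty for full-preview trials."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "trial_index": r.trial_index,
            "missing_target": r.missing_target,
            "preview_time": r.preview_time,
        }
        for j, t in enumerate(r.response_times, start=1):
            row[f"t{j}"] = t
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def trials_to_csv(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write the trial log; times carry six decimal places so identical
    record lists produce byte-identical files."""
    df = trials_to_frame(records)
    df.to_csv(path, index=False, float_format="%.6f")


def _cell(v) -> float | None:
    if v is None:
        return None
    v = float(v)
    return None if math.isnan(v) else v


def trials_from_csv(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV is missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        m = _cell(row.missing_target)
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                trial_index=int(row.trial_index),
                missing_target=int(m) if m is not None else None,
                preview_time=float(row.preview_time),
                response_times=tuple(float(getattr(row, f"t{j}")) for j in range(1, 7)),
            )
        )
    return records


def write_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2, sort_keys=True))


def read_config(path: str | Path) -> ExperimentConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


def read_external_trials(
    path: str | Path, column_map: Mapping[str, str]
) -> list[TrialRecord]:
    """Best-effort import of an externally deposited trial table.

    ``column_map`` maps this package's canonical column names (see the
    trial-log CSV layout) to the columns of the external file. No analysis
    result depends on this reader; it exists so the pipeline can be pointed
    at real data whose layout the caller knows.
    """
    df = pd.read_csv(path)
    absent = [src for src in column_map.values() if src not in df.columns]
    if absent:
        raise ValueError(f"external file lacks mapped columns: {absent}")
    renamed = df.rename(columns={v: k for k, v in column_map.items()})
    for col in _COLUMNS:
        if col not in renamed.columns:
            raise ValueError(f"column_map does not cover required column {col!r}")
    records = []
    for row in renamed[_COLUMNS].itertuples(index=False):
        m = _cell(row.missing_target)
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                trial_index=int(row.trial_index),
                missing_target=int(m) if m is not None else None,
                preview_time=float(row.preview_time),
                response_times=tuple(float(getattr(row, f"t{j}")) for j in range(1, 7)),
            )
        )
    return records
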