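"""Tabular I/O: BIDS-style events, confounds, and result tables.

Events are exchanged as tab-separated ``events.tsv`` files with columns
``onset, duration, trial_type, ssd, response, response_time, outcome``
(durations are written as 0: events are modelled as impulses).  Plain BIDS
dialects that only carry ``onset, duration, trial_type`` plus optional
``response_time`` / ``response`` / ``ssd`` columns are accepted on read;
missing cells are written as ``n/a`` per the BIDS convention.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .race import FS, GO_CORRECT, GO_ERROR, GO_OMISSION, SS, TrialRecord

__all__ = ["write_events", "read_events", "write_confounds", "read_confounds"]

_NA = "n/a"


def _fmt(value, ndigits: int | None = None) -> str:
    if value is None:
        return _NA
    if ndigits is not None:
        return f"{value:.{ndigits}f}"
    return str(value)


def write_events(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write a trial sequence as a BIDS-style events.tsv (impulse events)."""
    rows = []
    for t in trials:
        rows.append({
            "onset": f"{t.onset_s:.3f}",
            "duration": "0",
            "trial_type": t.trial_type,
            "direction": t.direction,
            "ssd": _fmt(t.ssd_ms, 1) if t.ssd_ms is not None else _NA,
            "staircase": _fmt(t.staircase_id),
            "response": t.response if t.response is not None else _NA,
            "response_time": _fmt(t.rt_ms / 1000.0, 4) if t.rt_ms is not None else _NA,
            "outcome": t.outcome if t.outcome is not None else _NA,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _infer_outcome(trial_type: str, response, rt_ms, direction) -> str:
    if trial_type == "stop":
        return FS if response is not None or rt_ms is not None else SS
    if response is None and rt_ms is None:
        return GO_OMISSION
    if direction is not None and response is not None and response != direction:
        return GO_ERROR
    return GO_CORRECT


def read_events(path: str | Path) -> list[TrialRecord]:
    """Read an events.tsv into trial records, validating as it goes.

    Required columns: ``onset``, ``duration``, ``trial_type``.  Stop trials
    must carry an SSD.  Blank / ``n/a`` response times are treated as
    omissions (go) or successful stops (stop).  Outcomes are taken from the
    file when present, otherwise inferred.  Malformed rows raise with their
    line number (1-based, header = line 1).
    """
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=True,
                     dtype={"trial_type": str})
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")

    def cell(row, col):
        if col not in df.columns:
            return None
        val = row[col]
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        return val

    trials: list[TrialRecord] = []
    for i, row in df.iterrows():
        line = i + 2
        trial_type = row["trial_type"]
        if trial_type not in ("go", "stop"):
            raise ValueError(f"{path}:{line}: bad trial_type {trial_type!r}")
        try:
            onset = float(row["onset"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{line}: non-numeric onset") from None
        ssd = cell(row, "ssd")
        if trial_type == "stop" and ssd is None:
            raise ValueError(f"{path}:{line}: stop trial lacks an SSD")
        if trial_type == "go" and ssd is not None:
            raise ValueError(f"{path}:{line}: go trial carries an SSD")
        rt = cell(row, "response_time")
        rt_ms = float(rt) * 1000.0 if rt is not None else None
        response = cell(row, "response")
        direction = cell(row, "direction")
        outcome = cell(row, "outcome")
        if outcome is None:
            outcome = _infer_outcome(trial_type, response, rt_ms, direction)
        stair = cell(row, "staircase")
        trials.append(TrialRecord(
            index=int(i),
            trial_type=trial_type,
            direction=direction if direction is not None else "left",
            onset_s=onset,
            ssd_ms=float(ssd) if ssd is not None else None,
            staircase_id=int(stair) if stair is not None else None,
            response=response,
            rt_ms=rt_ms,
            outcome=outcome,
        ))
    return trials


def write_confounds(confounds: pd.DataFrame, path: str | Path) -> None:
    confounds.to_csv(path, sep="\t", index=False)


def read_confounds(path: str | Path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing confound columns {missing}")
        df = df[list(columns)]
    return df


def format_mean_se(mean: float, se: float) -> str:
    """Render a cell in report style, e.g. ``423 ± 18``."""
    return f"{mean:.0f} ± {se:.0f}"
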