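"""Delimited-text readers and writers for event tables and sweeps.

Event tables are UTF-8 comma-delimited files with one row per event and
columns ``session_id, cell_id, label, duration_s, event_time_s`` plus an
optional ``amplitude_pA``. A cell with zero events is declared by a single
row with an empty ``event_time_s`` field. Sweeps are two-column files
(``time_s, voltage_mV``) with a YAML sidecar holding the step metadata.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import EventTrain, Label, PairedSession, Sweep, ValidationError, as_sessions

log = logging.getLogger("epscorr")

_REQUIRED_COLUMNS = ("session_id", "cell_id", "label", "duration_s", "event_time_s")
#: event times are written with microsecond resolution or better
_TIME_FORMAT = "%.9f"


class FormatError(ValueError):
    """Raised when an input file does not have the expected columns."""


def _train_from_rows(cell_id: str, rows: pd.DataFrame) -> EventTrain:
    durations = rows["duration_s"].unique()
    if len(durations) != 1:
        raise ValidationError(f"cell {cell_id}: inconsistent duration_s values {durations}")
    label = rows["label"].iloc[0]
    try:
        label = Label(str(label).strip().lower())
    except ValueError:
        raise FormatError(f"cell {cell_id}: label must be 'labeled' or 'unlabeled', got {label!r}")
    present = rows[rows["event_time_s"].notna()]
    times = np.sort(present["event_time_s"].to_numpy(dtype=float))
    order = np.argsort(present["event_time_s"].to_numpy(dtype=float), kind="stable")
    amps = None
    if "amplitude_pA" in rows.columns and present["amplitude_pA"].notna().all() and len(present):
        amps = present["amplitude_pA"].to_numpy(dtype=float)[order]
    return EventTrain(
        cell_id=str(cell_id),
        label=label,
        duration=float(durations[0]),
        event_times=times,
        amplitudes=amps,
    )


def read_event_table(path: Union[str, Path]) -> List[PairedSession]:
    """Read a delimited event table into validated paired sessions.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If a session does not have exactly two cells, or an event lies
        outside the recording duration (the offending cell is named).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    sessions = []
    for session_id, srows in df.groupby("session_id", sort=True):
        trains = [
            _train_from_rows(cell_id, crows)
            for cell_id, crows in srows.groupby("cell_id", sort=True)
        ]
        sessions.append(as_sessions(trains, str(session_id)))
    log.info("read_event_table: %d sessions, %d events from %s",
             len(sessions), int(df["event_time_s"].notna().sum()), path)
    return sessions


def write_event_table(sessions: Sequence[PairedSession], path: Union[str, Path]) -> None:
    """Write sessions to the delimited event-table format (lossless round trip)."""
    records = []
    has_amp = any(
        t.amplitudes is not None for s in sessions for t in (s.train_a, s.train_b)
    )
    for s in sessions:
        for train in (s.train_a, s.train_b):
            base = {
                "session_id": s.session_id,
                "cell_id": train.cell_id,
                "label": train.label.value,
                "duration_s": train.duration,
            }
            if train.n_events == 0:
                records.append({**base, "event_time_s": np.nan})
                continue
            for i, t in enumerate(train.event_times):
                rec = {**base, "event_time_s": t}
                if has_amp:
                    rec["amplitude_pA"] = (
                        train.amplitudes[i] if train.amplitudes is not None else np.nan
                    )
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False, float_format=_TIME_FORMAT)
    log.info("write_event_table: %d sessions -> %s", len(sessions), path)


def read_sweep(path: Union[str, Path]) -> Sweep:
    """Read a two-column sweep file; metadata comes from ``<path>.meta.yaml``."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "voltage_mV" not in df.columns:
        raise FormatError(f"{path}: expected columns time_s, voltage_mV")
    meta = yaml.safe_load(Path(str(path) + ".meta.yaml").read_text())
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValidationError(f"{path}: time base is not uniform")
    return Sweep(
        voltage=df["voltage_mV"].to_numpy(dtype=float),
        sampling_rate=float(meta["sampling_rate_hz"]),
        current=float(meta["current_pA"]),
        pulse_onset=float(meta["pulse_onset_s"]),
        pulse_offset=float(meta["pulse_offset_s"]),
    )


def write_sweep(sweep: Sweep, path: Union[str, Path]) -> None:
    pd.DataFrame({"time_s": sweep.time, "voltage_mV": sweep.voltage}).to_csv(
        path, index=False, float_format="%.6f"
    )
    meta = {
        "sampling_rate_hz": sweep.sampling_rate,
        "current_pA": sweep.current,
        "pulse_onset_s": sweep.pulse_onset,
        "pulse_offset_s": sweep.pulse_offset,
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))
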