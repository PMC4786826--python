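"""Readers and writers for recordings, cohort manifests and reports.

Recordings are stored as CSV: ``#``-prefixed header lines carry the metadata
(subject, trial, sample rate, pulse boundaries, provenance), followed by one
column per channel (``force_T12``, ``accel_L1`` ... ``accel_L5``) and one
sample per row.  Round trips are lossless to full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .spine_sim import PulseTrainRecording, SENSOR_LABELS

FORCE_COLUMN = "force_T12"
FORMAT_TAG = "spineshm-recording v1"


def write_recording(
    rec: PulseTrainRecording,
    path: str | Path,
    provenance: dict | None = None,
) -> Path:
    """Write a recording as headed CSV; ``provenance`` (e.g. config hash and
    seed) is embedded in the header."""
    path = Path(path)
    lines = [
        f"# {FORMAT_TAG}",
        f"# subject_id={rec.subject_id}",
        f"# trial_index={rec.trial_index}",
        f"# sample_rate={rec.sample_rate!r}",
        f"# pulse_boundaries={','.join(map(str, rec.pulse_boundaries.tolist()))}",
    ]
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}={val}")
    columns = [FORCE_COLUMN] + [f"accel_{s}" for s in rec.sensors]
    lines.append(",".join(columns))
    data = np.column_stack([rec.force] + [rec.accel[s] for s in rec.sensors])
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.17g")
    return path


def read_recording(path: str | Path, require_spine_sensors: bool = True) -> PulseTrainRecording:
    """Read a recording written by :func:`write_recording`.

    With ``require_spine_sensors`` the file must carry all five lumbar
    accelerometer channels; a missing channel is a format error naming it.
    """
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            entry = line[1:].strip()
            if "=" in entry:
                key, val = entry.split("=", 1)
                header[key.strip()] = val.strip()
    if n_header == 0:
        raise FormatError(f"{path}: missing '#' metadata header")
    for key in ("subject_id", "trial_index", "sample_rate", "pulse_boundaries"):
        if key not in header:
            raise FormatError(f"{path}: header lacks required field {key!r}")
    table = pd.read_csv(path, skiprows=n_header)
    if FORCE_COLUMN not in table.columns:
        raise FormatError(f"{path}: missing channel column {FORCE_COLUMN!r}")
    accel_cols = [c for c in table.columns if c.startswith("accel_")]
    if require_spine_sensors:
        missing = [s for s in SENSOR_LABELS if f"accel_{s}" not in accel_cols]
        if missing:
            raise FormatError(f"{path}: missing accelerometer channel(s) {missing}")
    try:
        boundaries = np.array([int(v) for v in header["pulse_boundaries"].split(",")])
        sample_rate = float(header["sample_rate"])
        trial_index = int(header["trial_index"])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header field ({exc})") from exc
    return PulseTrainRecording(
        subject_id=header["subject_id"],
        trial_index=trial_index,
        sample_rate=sample_rate,
        force=table[FORCE_COLUMN].to_numpy(),
        accel={c.removeprefix("accel_"): table[c].to_numpy() for c in accel_cols},
        pulse_boundaries=boundaries,
    )


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a cohort manifest (one row per recording file)."""
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty manifest") from exc
    required = {"path", "subject_id", "pair_id", "twin_index", "group"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: manifest lacks columns {sorted(missing)}")
    return table
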