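"""Session recordings and cohort tables: in-memory containers and plain-text I/O.

A *session* is one six-minute walk test (6MWT) instrumented with a chest-worn
device: a 5-min seated rest, a 6-min walk, and a 5-min standing recovery.  The
ECG channel is represented by its R-peak timestamps (seconds from recording
start); the accelerometer channel by triaxial samples in g at a nominal 32 Hz.

On disk a session is a directory with three files::

    meta.json     ids, phase boundaries, anthropometrics, measured 6MWD
    r_peaks.tsv   one column: R-peak time [s]
    accel.tsv     four columns: t [s], x, y, z [g]

All numeric serialization uses ``%.17g`` so that read(write(x)) round-trips
bit-exactly.  A missing measured walking distance is encoded by absence of the
key, never by a sentinel value.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import MissingStreamError, SchemaError, ValidationError

__all__ = [
    "PhaseTimes",
    "Anthropometrics",
    "SessionRecording",
    "write_session",
    "read_session",
    "write_cohort_features",
    "read_cohort_features",
    "validate_cohort_table",
]

ACCEL_COLUMNS = ("t", "x", "y", "z")


@dataclass(frozen=True)
class PhaseTimes:
    """Half-open phase boundaries in seconds from recording start.

    rest = [rest_start, walk_start), walk = [walk_start, walk_end),
    recovery = [walk_end, record_end).
    """

    rest_start: float = 0.0
    walk_start: float = 300.0
    walk_end: float = 660.0
    record_end: float = 960.0

    def __post_init__(self) -> None:
        if not (self.rest_start < self.walk_start < self.walk_end < self.record_end):
            raise ValidationError(
                "phase boundaries must satisfy rest_start < walk_start "
                f"< walk_end < record_end, got {self}"
            )

    @property
    def walk_duration(self) -> float:
        return self.walk_end - self.walk_start

    @property
    def total_duration(self) -> float:
        return self.record_end - self.rest_start


@dataclass(frozen=True)
class Anthropometrics:
    age: float
    height_m: float
    weight_kg: float
    sex: str  # "M" or "F"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class SessionRecording:
    """One patient-session of wearable 6MWT data.

    ``six_mwd_measured`` is the distance walked in meters; ``None`` for
    prediction-only sessions where the outcome was not recorded.
    """

    patient_id: str
    session_index: int
    phases: PhaseTimes
    r_peaks: np.ndarray
    accel: pd.DataFrame  # columns t, x, y, z
    anthropometrics: Anthropometrics
    six_mwd_measured: float | None = None

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.session_index < 1:
            raise ValidationError(
                f"session_index must be >= 1, got {self.session_index}"
            )
        if self.r_peaks.ndim != 1:
            raise ValidationError("r_peaks must be a 1-D array of timestamps")
        if len(self.r_peaks) >= 2 and not np.all(np.diff(self.r_peaks) > 0):
            raise ValidationError(
                f"r_peaks must be strictly increasing "
                f"(patient {self.patient_id}, session {self.session_index})"
            )
        if list(self.accel.columns) != list(ACCEL_COLUMNS):
            raise ValidationError(
                f"accel columns must be {ACCEL_COLUMNS}, got {tuple(self.accel.columns)}"
            )
        t = self.accel["t"].to_numpy()
        if len(t) >= 2 and np.any(np.diff(t) < 0):
            raise ValidationError("accel timestamps must be non-decreasing")
        if self.six_mwd_measured is not None and not math.isfinite(self.six_mwd_measured):
            raise ValidationError("six_mwd_measured must be finite or None")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_session(recording: SessionRecording, directory: str | Path) -> dict[str, Path]:
    """Write one session to ``directory`` (created if needed); returns file paths."""
    recording.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meta = {
        "patient_id": recording.patient_id,
        "session_index": recording.session_index,
        "phase_times": {
            "rest_start": recording.phases.rest_start,
            "walk_start": recording.phases.walk_start,
            "walk_end": recording.phases.walk_end,
            "record_end": recording.phases.record_end,
        },
        "anthropometrics": {
            "age": recording.anthropometrics.age,
            "height_m": recording.anthropometrics.height_m,
            "weight_kg": recording.anthropometrics.weight_kg,
            "sex": recording.anthropometrics.sex,
        },
    }
    if recording.six_mwd_measured is not None:
        meta["six_mwd_measured"] = recording.six_mwd_measured

    paths = {
        "meta": directory / "meta.json",
        "r_peaks": directory / "r_peaks.tsv",
        "accel": directory / "accel.tsv",
    }
    paths["meta"].write_text(json.dumps(meta, indent=2) + "\n")

    with paths["r_peaks"].open("w") as fh:
        fh.write("t\n")
        for t in recording.r_peaks:
            fh.write(_fmt(t) + "\n")

    arr = recording.accel[list(ACCEL_COLUMNS)].to_numpy(dtype=float)
    with paths["accel"].open("w") as fh:
        fh.write("\t".join(ACCEL_COLUMNS) + "\n")
        np.savetxt(fh, arr, fmt="%.17g", delimiter="\t")
    return paths


def _load_table(path: Path, n_cols: int) -> np.ndarray:
    if not path.exists():
        raise MissingStreamError(f"required data stream missing: {path}")
    try:
        arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise SchemaError(f"malformed table {path}: {exc}") from exc
    if arr.size == 0:
        arr = arr.reshape(0, n_cols)
    if arr.shape[1] != n_cols:
        raise SchemaError(
            f"malformed table {path}: expected {n_cols} columns, got {arr.shape[1]}"
        )
    return arr


def read_session(directory: str | Path) -> SessionRecording:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`SchemaError` on malformed files, :class:`MissingStreamError`
    on absent streams and :class:`ValidationError` on invariant violations.
    """
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise MissingStreamError(f"required data stream missing: {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed metadata {meta_path}: {exc}") from exc
    try:
        phases = PhaseTimes(**meta["phase_times"])
        anthro = Anthropometrics(**meta["anthropometrics"])
        patient_id = str(meta["patient_id"])
        session_index = int(meta["session_index"])
    except KeyError as exc:
        raise SchemaError(f"metadata {meta_path} missing key {exc}") from exc

    r_peaks = _load_table(directory / "r_peaks.tsv", 1)[:, 0]
    accel_arr = _load_table(directory / "accel.tsv", 4)
    accel = pd.DataFrame(accel_arr, columns=list(ACCEL_COLUMNS))

    return SessionRecording(
        patient_id=patient_id,
        session_index=session_index,
        phases=phases,
        r_peaks=r_peaks,
        accel=accel,
        anthropometrics=anthro,
        six_mwd_measured=meta.get("six_mwd_measured"),
    )


# --- cohort feature tables ------------------------------------------------

KEY_COLUMNS = ("patient_id", "session_index")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (patient_id, session_index) uniqueness invariant."""
    for col in KEY_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"cohort table missing key column {col!r}")
    dup = table.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        keys = table.loc[dup, list(KEY_COLUMNS)].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (patient_id, session_index) keys: {keys[:5]}")
    return table


def write_cohort_features(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort feature table as CSV with full float precision."""
    validate_cohort_table(table)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_cohort_features(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingStreamError(f"cohort feature table missing: {path}")
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise SchemaError(f"malformed cohort table {path}: {exc}") from exc
    if "session_index" in table.columns:
        table["session_index"] = table["session_index"].astype(int)
    return validate_cohort_table(table)
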