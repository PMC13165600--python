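"""Signal data model and file I/O.

Recordings are continuous triaxial acceleration streams in gravitational
units (1 g = 9.807 m/s^2), nominally sampled at 100 Hz from a body-worn
sensor with a +/-16 g range. Activity labels are stored as half-open
sample-index segments ``[start, end)`` over a recording. Feature matrices
round-trip as CSV with a fixed column order; evaluation reports serialize
to JSON.

Conventions
-----------
* Sample indices are 0-based; segments are half-open ``[start, end)``.
* Axis order is (x, y, z) as exported by the device, with y the primary
  vertical axis.
* Out-of-range samples (> 16 g in magnitude) are rejected by default and
  clipped with a warning when ``clip_out_of_range=True``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ACTIVITIES: tuple[str, ...] = ("walking", "running", "jumping")
PLACEMENTS: tuple[str, ...] = ("ankle", "lower_back", "hip")

#: Hard dynamic range of the sensor, in g.
ACCELERATION_RANGE_G: float = 16.0

#: Metadata columns carried alongside the feature columns in a feature matrix.
METADATA_COLUMNS: tuple[str, ...] = ("participant_id", "placement", "label", "window_index")


class SchemaError(ValueError):
    """A file's columns do not match the expected schema."""


@dataclass(frozen=True)
class TriaxialRecording:
    """A participant's continuous triaxial acceleration stream.

    Parameters
    ----------
    recording_id : str
        Unique identifier for the recording.
    participant_id : str
        Identifier of the participant who wore the sensor.
    placement : str
        Sensor location, one of ``ankle``, ``lower_back``, ``hip``.
    fs : float
        Sampling frequency in Hz (default 100).
    samples : ndarray of shape (n, 3)
        Acceleration triplets (ax, ay, az) in g.
    """

    recording_id: str
    participant_id: str
    placement: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError(f"samples must have shape (n, 3), got {samples.shape}")
        if samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("recording contains non-finite acceleration values")
        if np.any(np.abs(samples) > ACCELERATION_RANGE_G):
            raise ValueError(
                f"acceleration values exceed the +/-{ACCELERATION_RANGE_G} g sensor range"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return len(self) / self.fs


@dataclass(frozen=True)
class ActivitySegment:
    """A labeled, half-open slice ``[start, end)`` of a recording."""

    recording_id: str
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in ACTIVITIES:
            raise ValueError(f"label must be one of {ACTIVITIES}, got {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed-duration signal slice used as the unit of classification."""

    participant_id: str
    placement: str
    label: str
    window_samples: np.ndarray
    window_index: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.window_samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("window_samples must have shape (n, 3)")
        object.__setattr__(self, "window_samples", samples)

    def __len__(self) -> int:
        return self.window_samples.shape[0]


def read_recording(
    path: str | Path,
    *,
    fs: float = 100.0,
    skip_rows: int = 0,
    columns: Sequence[int] = (0, 1, 2),
    clip_out_of_range: bool = False,
    recording_id: str | None = None,
    participant_id: str = "",
    placement: str = "hip",
) -> TriaxialRecording:
    """Read a raw triaxial acceleration CSV into a :class:`TriaxialRecording`.

    The dialect tolerates ActiGraph-style raw exports: an optional metadata
    header block of ``skip_rows`` lines, then one row per sample with the
    three acceleration columns (in g) selected by ``columns``. Row order is
    preserved.

    Raises
    ------
    ValueError
        If a required column is missing or non-numeric (the offending line
        is named), or if a value exceeds the sensor range in strict mode.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=None, skiprows=skip_rows, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: no data rows found") from exc
    if frame.shape[1] <= max(columns):
        raise ValueError(
            f"{path}: expected at least {max(columns) + 1} columns, found {frame.shape[1]}"
        )
    raw = frame.iloc[:, list(columns)]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        row, col = bad[0]
        raise ValueError(
            f"{path}: non-numeric acceleration value {raw.iat[row, col]!r} "
            f"at data line {row + 1 + skip_rows}, column {columns[col]}"
        )
    out_of_range = np.abs(values) > ACCELERATION_RANGE_G
    if np.any(out_of_range):
        if clip_out_of_range:
            n_bad = int(out_of_range.sum())
            warnings.warn(
                f"{path}: clipped {n_bad} sample value(s) to the "
                f"+/-{ACCELERATION_RANGE_G} g sensor range",
                stacklevel=2,
            )
            values = np.clip(values, -ACCELERATION_RANGE_G, ACCELERATION_RANGE_G)
        else:
            row = int(np.argwhere(out_of_range.any(axis=1))[0][0])
            raise ValueError(
                f"{path}: acceleration value exceeds +/-{ACCELERATION_RANGE_G} g "
                f"at data line {row + 1 + skip_rows}"
            )
    return TriaxialRecording(
        recording_id=recording_id if recording_id is not None else path.stem,
        participant_id=participant_id,
        placement=placement,
        fs=fs,
        samples=values,
    )


def write_recording(recording: TriaxialRecording, path: str | Path) -> None:
    """Write a recording as a headerless x,y,z CSV (one row per sample)."""
    pd.DataFrame(recording.samples).to_csv(path, header=False, index=False)


def read_segments(path: str | Path) -> list[ActivitySegment]:
    """Read an activity-label CSV with columns recording_id,label,start,end."""
    frame = pd.read_csv(path)
    required = {"recording_id", "label", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: label file missing column(s) {sorted(missing)}")
    return [
        ActivitySegment(
            recording_id=str(row.recording_id),
            label=str(row.label),
            start=int(row.start),
            end=int(row.end),
        )
        for row in frame.itertuples()
    ]


def write_segments(segments: Iterable[ActivitySegment], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in segments]).to_csv(path, index=False)


def window_segments(
    recording: TriaxialRecording,
    segments: Sequence[ActivitySegment],
    window_seconds: float = 1.0,
    stride_seconds: float | None = None,
) -> list[LabeledWindow]:
    """Slice labeled segments into fixed-duration windows.

    Windows start at each segment's start and advance by the stride
    (default: the window length, i.e. non-overlapping). A trailing partial
    window is dropped, so a segment shorter than one window yields no
    windows. Windows never span segment boundaries; each inherits its
    segment's label. A segment emits ``max(0, floor((len - W) / S) + 1)``
    windows with ``W`` and ``S`` in samples.
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    if stride_seconds is None:
        stride_seconds = window_seconds
    if stride_seconds <= 0:
        raise ValueError("stride_seconds must be positive")
    window = round(recording.fs * window_seconds)
    stride = round(recording.fs * stride_seconds)
    if window < 1 or stride < 1:
        raise ValueError("window and stride must span at least one sample")

    windows: list[LabeledWindow] = []
    index = 0
    for segment in segments:
        if segment.recording_id != recording.recording_id:
            continue
        if segment.end > len(recording):
            raise ValueError(
                f"segment [{segment.start}, {segment.end}) exceeds recording "
                f"{recording.recording_id!r} of length {len(recording)}"
            )
        start = segment.start
        while start + window <= segment.end:
            windows.append(
                LabeledWindow(
                    participant_id=recording.participant_id,
                    placement=recording.placement,
                    label=segment.label,
                    window_samples=recording.samples[start : start + window],
                    window_index=index,
                )
            )
            index += 1
            start += stride
    return windows


def _expected_columns(feature_names: Sequence[str]) -> list[str]:
    return list(feature_names) + list(METADATA_COLUMNS)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix CSV in the fixed documented column order."""
    from .features import FEATURE_NAMES

    expected = _expected_columns(FEATURE_NAMES)
    missing = [c for c in expected if c not in matrix.columns]
    if missing:
        raise SchemaError(f"feature matrix missing column(s): {missing}")
    matrix.loc[:, expected].to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix CSV, validating the exact column set."""
    from .features import FEATURE_NAMES

    frame = pd.read_csv(
        path, dtype={c: str for c in ("participant_id", "placement", "label")}
    )
    expected = _expected_columns(FEATURE_NAMES)
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: feature matrix schema mismatch"
            + (f"; missing {missing}" if missing else "")
            + (f"; unexpected {extra}" if extra else "")
        )
    return frame.loc[:, expected]


def write_report(report: dict | object, path: str | Path) -> None:
    """Serialize an evaluation report (dataclass or dict) to JSON."""
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        payload = dataclasses.asdict(report)
    elif hasattr(report, "to_dict"):
        payload = report.to_dict()
    else:
        payload = report

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"cannot serialize {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
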