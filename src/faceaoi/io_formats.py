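"""Data containers and CSV readers/writers for every file the pipeline touches.

File dialect (fixed): comma-delimited, period decimal point, mandatory header
row, literal ``NaN`` as the missing-value sentinel.

Landmark numbering: the in-memory model always uses the 1-based numbers of
the standard 68-point facial-landmark scheme (left eye 37-42, right eye
43-48, nose tip 31, ...).  Detector CSV exports commonly name their columns
``x_0..x_67`` (zero-based); the reader translates per ``dialect`` so that
in-memory point *k* (1-based) always means landmark *k*.

Coordinates: origin at the top-left of the video frame, x rightward,
y downward, units pixels.  "Left eye" is the eye on the left of the IMAGE
(viewer perspective), i.e. landmarks 37-42.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import labels as L
from .errors import (
    EmptyFileError,
    MalformedHeaderError,
    NonMonotonicTimestampsError,
)

N_LANDMARKS = 68

ZERO_BASED = "zero_based_columns"
ONE_BASED = "one_based_columns"

_FLOAT_FMT = "%.9g"  # >= 6 significant digits round-trip precision


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkFrame:
    """One video frame of detector output: 68 landmark positions in pixels."""

    frame_index: int
    timestamp: float
    confidence: float
    success: bool
    points: np.ndarray  # (68, 2) float, row k-1 = landmark k (1-based)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(f"points must have shape (68, 2), got {pts.shape}")
        object.__setattr__(self, "points", pts)
        if self.success and not np.all(np.isfinite(pts)):
            raise ValueError("coordinates must be finite when success is true")

    def point(self, number: int) -> np.ndarray:
        """(x, y) of landmark ``number`` in 1-based numbering."""
        if not 1 <= number <= N_LANDMARKS:
            raise IndexError(f"landmark number must be in 1..68, got {number}")
        return self.points[number - 1]


@dataclass
class LandmarkTrack:
    """A full per-frame landmark track for one video."""

    frame_index: np.ndarray   # (n,) int, contiguous from 0
    timestamps: np.ndarray    # (n,) float seconds, strictly increasing
    confidence: np.ndarray    # (n,) float in [0, 1]
    success: np.ndarray       # (n,) bool
    points: np.ndarray        # (n, 68, 2) float pixels
    frame_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.success = np.asarray(self.success, dtype=bool)
        self.points = np.asarray(self.points, dtype=float)
        n = len(self.frame_index)
        if n < 1:
            raise EmptyFileError("landmark track must contain at least one frame")
        for name in ("timestamps", "confidence", "success"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.points.shape != (n, N_LANDMARKS, 2):
            raise ValueError(
                f"points must have shape ({n}, 68, 2), got {self.points.shape}")
        if not np.array_equal(self.frame_index, np.arange(n)):
            raise ValueError("frame_index must be contiguous from 0")
        if np.any(np.diff(self.timestamps) <= 0):
            raise NonMonotonicTimestampsError(
                "timestamps must be strictly increasing")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return len(self.frame_index)

    def __getitem__(self, i: int) -> LandmarkFrame:
        return LandmarkFrame(
            frame_index=int(self.frame_index[i]),
            timestamp=float(self.timestamps[i]),
            confidence=float(self.confidence[i]),
            success=bool(self.success[i]),
            points=self.points[i],
        )


@dataclass
class GazeRecording:
    """Timestamped gaze samples in screen pixels.

    Invalid samples may hold any coordinate; downstream code must never let
    them influence a metric.
    """

    timestamps: np.ndarray  # (n,) seconds, strictly increasing
    x: np.ndarray           # (n,) px
    y: np.ndarray           # (n,) px
    valid: np.ndarray       # (n,) bool
    sampling_rate: float    # Hz

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.timestamps)
        if n == 0:
            raise EmptyFileError("gaze recording has no samples")
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("gaze arrays must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise NonMonotonicTimestampsError(
                "gaze timestamps must be strictly increasing")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class AOICenterSet:
    """AOI cell centers for one frame: one (x, y) pixel pair per facial AOI."""

    centers: dict  # label -> (2,) float array
    valid: bool

    def __getitem__(self, label: str) -> np.ndarray:
        return self.centers[label]


@dataclass
class AOICenterTrack:
    """Per-frame AOI cell centers for the four facial AOIs.

    ``coords[label]`` is an (n, 2) float array; rows of invalid frames hold
    NaN.  ``carried`` marks frames whose centers were carried forward over a
    short detector dropout rather than observed.
    """

    frame_index: np.ndarray  # (n,) int
    timestamps: np.ndarray   # (n,) float seconds
    coords: dict             # label -> (n, 2) float px
    valid: np.ndarray        # (n,) bool
    frame_rate: float
    carried: np.ndarray | None = None  # (n,) bool

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.frame_index)
        if n == 0:
            raise EmptyFileError("center track has no frames")
        if set(self.coords) != set(L.FACIAL_AOIS):
            raise ValueError(
                f"coords must map exactly the four facial AOIs, got {set(self.coords)}")
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}
        for k, v in self.coords.items():
            if v.shape != (n, 2):
                raise ValueError(f"coords[{k!r}] must have shape ({n}, 2)")
        if len(self.valid) != n or len(self.timestamps) != n:
            raise ValueError("array length mismatch")
        if self.carried is None:
            self.carried = np.zeros(n, dtype=bool)
        else:
            self.carried = np.asarray(self.carried, dtype=bool)
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")

    def __len__(self) -> int:
        return len(self.frame_index)

    def __getitem__(self, i: int) -> AOICenterSet:
        return AOICenterSet(
            centers={k: v[i] for k, v in self.coords.items()},
            valid=bool(self.valid[i]),
        )


@dataclass
class AOILabelStream:
    """Per-gaze-sample AOI labels on the gaze timeline."""

    timestamps: np.ndarray      # (n,) seconds
    labels: np.ndarray          # (n,) str from labels.ALL_LABELS
    sampling_rate: float | None = None
    frame_indices: np.ndarray | None = None  # video frame each sample mapped to

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.timestamps) != len(self.labels):
            raise ValueError("timestamps and labels must have equal length")
        unknown = set(self.labels) - set(L.ALL_LABELS)
        if unknown:
            raise ValueError(f"unknown labels: {unknown}")
        if self.frame_indices is not None:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if len(self.frame_indices) != len(self.labels):
                raise ValueError("frame_indices length mismatch")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def sample_interval(self) -> float:
        """Nominal seconds per sample (1/rate, or the median timestamp step)."""
        if self.sampling_rate:
            return 1.0 / self.sampling_rate
        if len(self.timestamps) < 2:
            raise ValueError("cannot infer sample interval from one sample")
        return float(np.median(np.diff(self.timestamps)))


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyFileError(f"{path}: no data") from exc
    if len(df) == 0:
        raise EmptyFileError(f"{path}: header but no rows")
    return df


def _landmark_columns(dialect: str) -> tuple[list[str], list[str]]:
    if dialect == ZERO_BASED:
        idx = range(0, N_LANDMARKS)
    elif dialect == ONE_BASED:
        idx = range(1, N_LANDMARKS + 1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return [f"x_{i}" for i in idx], [f"y_{i}" for i in idx]


def read_landmark_track(
    path,
    dialect: str = ZERO_BASED,
    frame_rate: float | None = None,
    source_id: str | None = None,
) -> LandmarkTrack:
    """Read a 68-point landmark track CSV.

    Expected columns: ``frame, timestamp, confidence, success`` plus 68
    x-columns and 68 y-columns named per ``dialect`` (``x_0..x_67`` for
    zero-based, ``x_1..x_68`` for one-based).  Point *k* (1-based numbering)
    of the returned track maps to the dialect's column for landmark *k*.
    """
    df = _read_csv(path)
    xcols, ycols = _landmark_columns(dialect)
    required = ["frame", "timestamp", "confidence", "success"] + xcols + ycols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedHeaderError(f"{path}: missing columns {missing[:5]}...")
    extra = [c for c in df.columns
             if c.startswith(("x_", "y_")) and c not in xcols and c not in ycols]
    if extra:
        raise MalformedHeaderError(f"{path}: unexpected landmark columns {extra[:5]}")
    n = len(df)
    points = np.empty((n, N_LANDMARKS, 2), dtype=float)
    points[:, :, 0] = df[xcols].to_numpy(dtype=float)
    points[:, :, 1] = df[ycols].to_numpy(dtype=float)
    timestamps = df["timestamp"].to_numpy(dtype=float)
    if frame_rate is None:
        if n >= 2:
            frame_rate = 1.0 / float(np.median(np.diff(timestamps)))
        else:
            frame_rate = 25.0
    return LandmarkTrack(
        frame_index=df["frame"].to_numpy(dtype=int),
        timestamps=timestamps,
        confidence=df["confidence"].to_numpy(dtype=float),
        success=df["success"].to_numpy(dtype=float).astype(bool),
        points=points,
        frame_rate=frame_rate,
        source_id=source_id if source_id is not None else str(path),
    )


def write_landmark_track(track: LandmarkTrack, path, dialect: str = ZERO_BASED) -> None:
    """Write a landmark track in the given column dialect."""
    xcols, ycols = _landmark_columns(dialect)
    data = {
        "frame": track.frame_index,
        "timestamp": track.timestamps,
        "confidence": track.confidence,
        "success": track.success.astype(int),
    }
    for k, c in enumerate(xcols):
        data[c] = track.points[:, k, 0]
    for k, c in enumerate(ycols):
        data[c] = track.points[:, k, 1]
    pd.DataFrame(data).to_csv(path, index=False, na_rep="NaN",
                              float_format=_FLOAT_FMT)


def read_gaze_recording(path, sampling_rate: float | None = None) -> GazeRecording:
    """Read a gaze CSV with columns ``time, x, y, valid``.

    ``sampling_rate`` defaults to 1 / median inter-sample interval.
    """
    df = _read_csv(path)
    required = ["time", "x", "y", "valid"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedHeaderError(f"{path}: missing columns {missing}")
    t = df["time"].to_numpy(dtype=float)
    if sampling_rate is None:
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise NonMonotonicTimestampsError(
                    f"{path}: timestamps must be strictly increasing")
            sampling_rate = 1.0 / float(np.median(dt))
        else:
            raise EmptyFileError(f"{path}: need >= 2 samples to infer sampling rate")
    return GazeRecording(
        timestamps=t,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=float).astype(bool),
        sampling_rate=sampling_rate,
    )


def write_gaze_recording(rec: GazeRecording, path) -> None:
    pd.DataFrame({
        "time": rec.timestamps,
        "x": rec.x,
        "y": rec.y,
        "valid": rec.valid.astype(int),
    }).to_csv(path, index=False, na_rep="NaN", float_format=_FLOAT_FMT)


_CENTER_COLS = [f"{label}_{ax}" for label in L.FACIAL_AOIS for ax in ("x", "y")]


def write_center_track(track: AOICenterTrack, path) -> None:
    """Write an AOI-center track; missing centers encoded as the NaN token."""
    data = {"frame": track.frame_index, "timestamp": track.timestamps,
            "valid": track.valid.astype(int)}
    for label in L.FACIAL_AOIS:
        data[f"{label}_x"] = track.coords[label][:, 0]
        data[f"{label}_y"] = track.coords[label][:, 1]
    data["carried"] = track.carried.astype(int)
    pd.DataFrame(data).to_csv(path, index=False, na_rep="NaN",
                              float_format=_FLOAT_FMT)


def read_center_track(path, frame_rate: float | None = None) -> AOICenterTrack:
    """Read an AOI-center track written by :func:`write_center_track`."""
    df = _read_csv(path)
    required = ["frame", "timestamp", "valid"] + _CENTER_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedHeaderError(f"{path}: missing columns {missing}")
    t = df["timestamp"].to_numpy(dtype=float)
    if frame_rate is None:
        frame_rate = (1.0 / float(np.median(np.diff(t)))) if len(t) >= 2 else 25.0
    coords = {
        label: np.column_stack([
            df[f"{label}_x"].to_numpy(dtype=float),
            df[f"{label}_y"].to_numpy(dtype=float),
        ])
        for label in L.FACIAL_AOIS
    }
    carried = (df["carried"].to_numpy(dtype=float).astype(bool)
               if "carried" in df.columns else None)
    return AOICenterTrack(
        frame_index=df["frame"].to_numpy(dtype=int),
        timestamps=t,
        coords=coords,
        valid=df["valid"].to_numpy(dtype=float).astype(bool),
        frame_rate=frame_rate,
        carried=carried,
    )


def write_label_stream(stream: AOILabelStream, path) -> None:
    frames = (stream.frame_indices if stream.frame_indices is not None
              else np.full(len(stream), -1))
    pd.DataFrame({
        "time": stream.timestamps,
        "frame": frames,
        "label": stream.labels,
    }).to_csv(path, index=False, na_rep="NaN", float_format=_FLOAT_FMT)


def read_label_stream(path, sampling_rate: float | None = None) -> AOILabelStream:
    df = _read_csv(path)
    missing = [c for c in ("time", "frame", "label") if c not in df.columns]
    if missing:
        raise MalformedHeaderError(f"{path}: missing columns {missing}")
    frames = df["frame"].to_numpy(dtype=int)
    return AOILabelStream(
        timestamps=df["time"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=object),
        sampling_rate=sampling_rate,
        frame_indices=None if np.all(frames < 0) else frames,
    )


def write_summary_table(table: pd.DataFrame, path) -> None:
    """Write a dwell or paired-gaze summary table (index column included)."""
    table.to_csv(path, na_rep="NaN", float_format=_FLOAT_FMT)


def read_summary_table(path) -> pd.DataFrame:
    df = _read_csv(path)
    return df.set_index(df.columns[0])
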