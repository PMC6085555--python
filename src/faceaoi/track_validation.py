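"""Statistics for comparing two AOI-center tracks and for temporal stability.

Two tracks of the same video (e.g. from two different AOI-construction
methods) are compared per AOI and axis by the mean and the maximum absolute
coordinate difference over frames.  Temporal stability of a single track is
measured by the RMS of sample-to-sample coordinate differences (RMS-S2S),
the standard precision measure in eye tracking: it asks whether a coordinate
is stable from one frame to the next, and unlike RMS about the mean it is
not inflated by genuine slow head motion.  RMS about the mean is available
as an alternative mode.

Blink artifacts — transient displacements of the eye-AOI centers, downward
and toward the face midline, caused by eyelid closure — are detected with a
Hampel rule (rolling median +/- scaled MAD) and can be filtered out by
interpolation or median replacement.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import labels as L
from .errors import (
    AllFramesFlaggedError,
    InsufficientDataError,
    LengthMismatchError,
    NoOverlappingValidFramesError,
    WindowTooLargeError,
)
from .geometry import HORIZONTAL, VERTICAL, ScreenGeometry, px_to_deg
from .io_formats import AOICenterTrack

AXES = ("x", "y")
_AX_COL = {"x": 0, "y": 1}
_AX_SCREEN = {"x": HORIZONTAL, "y": VERTICAL}

#: Gaussian consistency factor for the median absolute deviation.
MAD_SCALE = 1.4826


def _pairwise_valid(a: AOICenterTrack, b: AOICenterTrack) -> np.ndarray:
    if len(a) != len(b):
        raise LengthMismatchError(f"track lengths differ: {len(a)} vs {len(b)}")
    both = a.valid & b.valid
    if not both.any():
        raise NoOverlappingValidFramesError("no frame is valid in both tracks")
    return both


def mean_abs_diff(a: AOICenterTrack, b: AOICenterTrack) -> pd.DataFrame:
    """Mean |a - b| per AOI and axis over pairwise-valid frames (pixels)."""
    both = _pairwise_valid(a, b)
    rows = []
    for aoi in L.FACIAL_AOIS:
        for ax in AXES:
            c = _AX_COL[ax]
            diff = np.abs(a.coords[aoi][both, c] - b.coords[aoi][both, c])
            rows.append({"aoi": aoi, "axis": ax, "value_px": float(diff.mean())})
    return pd.DataFrame(rows).set_index(["aoi", "axis"])


def max_abs_diff(a: AOICenterTrack, b: AOICenterTrack) -> pd.DataFrame:
    """Max |a - b| per AOI and axis: the single worst frame, not an average."""
    both = _pairwise_valid(a, b)
    rows = []
    for aoi in L.FACIAL_AOIS:
        for ax in AXES:
            c = _AX_COL[ax]
            diff = np.abs(a.coords[aoi][both, c] - b.coords[aoi][both, c])
            rows.append({"aoi": aoi, "axis": ax, "value_px": float(diff.max())})
    return pd.DataFrame(rows).set_index(["aoi", "axis"])


def rms_s2s(track: AOICenterTrack, mode: str = "sample_to_sample") -> pd.DataFrame:
    """RMS deviation of each AOI coordinate over time (pixels).

    ``sample_to_sample`` (default): sqrt(mean of squared successive
    differences) over consecutive valid frame pairs.  ``about_mean``:
    standard deviation about the per-track mean over valid frames.
    """
    if mode not in ("sample_to_sample", "about_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    v = track.valid
    consec = v[1:] & v[:-1]
    if mode == "sample_to_sample" and not consec.any():
        raise InsufficientDataError("need >= 2 consecutive valid frames")
    if mode == "about_mean" and v.sum() < 2:
        raise InsufficientDataError("need >= 2 valid frames")
    rows = []
    for aoi in L.FACIAL_AOIS:
        for ax in AXES:
            coord = track.coords[aoi][:, _AX_COL[ax]]
            if mode == "sample_to_sample":
                d = np.diff(coord)[consec]
                value = float(np.sqrt(np.mean(d ** 2)))
            else:
                value = float(np.std(coord[v]))
            rows.append({"aoi": aoi, "axis": ax, "value_px": value})
    return pd.DataFrame(rows).set_index(["aoi", "axis"])


def compare_tracks(
    a: AOICenterTrack,
    b: AOICenterTrack,
    geom: ScreenGeometry | None = None,
) -> pd.DataFrame:
    """Full comparison report per AOI and axis.

    Columns: mean_abs_diff_px, rms_a_px, rms_b_px, max_abs_diff_px, and the
    corresponding degree columns when a screen geometry is supplied.
    """
    report = pd.DataFrame(index=mean_abs_diff(a, b).index)
    report["mean_abs_diff_px"] = mean_abs_diff(a, b)["value_px"]
    report["rms_a_px"] = rms_s2s(a)["value_px"]
    report["rms_b_px"] = rms_s2s(b)["value_px"]
    report["max_abs_diff_px"] = max_abs_diff(a, b)["value_px"]
    if geom is not None:
        for col in ("mean_abs_diff", "rms_a", "rms_b", "max_abs_diff"):
            deg = [
                px_to_deg(px, geom, _AX_SCREEN[ax])
                for (aoi, ax), px in report[f"{col}_px"].items()
            ]
            report[f"{col}_deg"] = deg
    return report


def detect_spikes(
    track: AOICenterTrack,
    window: int = 7,
    n_mad: float = 3.0,
    aois: tuple[str, ...] = (L.LEFT_EYE, L.RIGHT_EYE),
) -> np.ndarray:
    """Flag frames with transient coordinate excursions (Hampel rule).

    A frame is flagged when any monitored coordinate deviates from its
    centered rolling-window median by more than ``n_mad`` scaled median
    absolute deviations of that window.  By default only the eye AOIs are
    monitored, since blinks displace only the eye landmarks.

    Returns an (n,) boolean array aligned with the track.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > len(track):
        raise WindowTooLargeError(
            f"window {window} exceeds track length {len(track)}")
    half = window // 2
    flags = np.zeros(len(track), dtype=bool)
    for aoi in aois:
        for c in (0, 1):
            x = np.where(track.valid, track.coords[aoi][:, c], np.nan)
            padded = np.pad(x, half, constant_values=np.nan)
            win = np.lib.stride_tricks.sliding_window_view(padded, window)
            with np.errstate(invalid="ignore"):
                med = np.nanmedian(win, axis=1)
                # MAD within each window, about that window's own median
                mad = np.nanmedian(np.abs(win - med[:, None]), axis=1)
                dev = np.abs(x - med)
                flags |= dev > n_mad * MAD_SCALE * mad
    flags &= track.valid  # invalid frames are gaps, not spikes
    return flags


def filter_spikes(
    track: AOICenterTrack,
    flags: np.ndarray,
    method: str = "interpolate",
    window: int = 7,
    aois: tuple[str, ...] = (L.LEFT_EYE, L.RIGHT_EYE),
) -> AOICenterTrack:
    """Replace flagged frames' monitored coordinates; others stay bit-identical.

    ``interpolate`` draws a straight line between the nearest unflagged valid
    neighbours (nearest-neighbour extension at the track ends);
    ``median_replace`` substitutes the centered rolling-window median of the
    unflagged signal.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(track):
        raise ValueError("flags must align with the track")
    if method not in ("interpolate", "median_replace"):
        raise ValueError(f"unknown method {method!r}")
    good = ~flags & track.valid
    if not good.any():
        raise AllFramesFlaggedError("every frame is flagged or invalid")

    idx = np.arange(len(track))
    coords = {k: v.copy() for k, v in track.coords.items()}
    for aoi in aois:
        for c in (0, 1):
            col = coords[aoi][:, c]
            if method == "interpolate":
                # np.interp holds the boundary value outside the good range,
                # giving nearest-neighbour extension at the ends
                col[flags] = np.interp(idx[flags], idx[good], col[good])
            else:
                s = pd.Series(np.where(good, col, np.nan))
                med = s.rolling(window, center=True, min_periods=1).median()
                col[flags] = med.to_numpy()[flags]
    return replace(
        track,
        coords=coords,
        frame_index=track.frame_index.copy(),
        timestamps=track.timestamps.copy(),
        valid=track.valid.copy(),
        carried=track.carried.copy(),
    )
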