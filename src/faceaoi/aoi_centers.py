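"""Derive per-frame AOI cell centers from 68-point landmark tracks.

Each facial AOI (left eye, right eye, nose, mouth) is represented by a single
cell center: the arithmetic mean of a fixed subset of landmark coordinates.
The default subsets are the standard ones for the 68-point scheme:

=========  =================
AOI        landmark numbers
=========  =================
left eye   37-42
right eye  43-48
nose       31 (tip)
mouth      63, 67 (inner-lip midpoints)
=========  =================

"Left eye" is the eye on the left of the image (viewer perspective), not the
anatomical left eye of the person in the video.
"""

from __future__ import annotations

import numpy as np

from . import labels as L
from .errors import AllFramesInvalidError, InvalidFrameError
from .io_formats import AOICenterSet, AOICenterTrack, LandmarkFrame, LandmarkTrack

#: Default AOI definition: label -> tuple of 1-based landmark numbers.
DEFAULT_AOI_DEFINITION: dict[str, tuple[int, ...]] = {
    L.LEFT_EYE: tuple(range(37, 43)),
    L.RIGHT_EYE: tuple(range(43, 49)),
    L.NOSE: (31,),
    L.MOUTH: (63, 67),
}

CARRY_FORWARD = "carry_forward"
MARK_MISSING = "mark_missing"


def validate_definition(definition: dict) -> dict[str, tuple[int, ...]]:
    """Check an AOI definition: four labels, nonempty disjoint 1-based subsets."""
    if set(definition) != set(L.FACIAL_AOIS):
        raise ValueError(
            f"definition must map exactly {set(L.FACIAL_AOIS)}, got {set(definition)}")
    out: dict[str, tuple[int, ...]] = {}
    seen: set[int] = set()
    for label, numbers in definition.items():
        numbers = tuple(int(n) for n in numbers)
        if not numbers:
            raise ValueError(f"{label}: landmark subset must be nonempty")
        if any(not 1 <= n <= 68 for n in numbers):
            raise ValueError(f"{label}: landmark numbers must be in 1..68")
        if seen & set(numbers):
            raise ValueError("landmark subsets must be disjoint")
        seen |= set(numbers)
        out[label] = numbers
    return out


def derive_center_set(
    frame: LandmarkFrame,
    definition: dict | None = None,
) -> AOICenterSet:
    """AOI cell centers for one frame: the mean of each landmark subset.

    A single-landmark AOI (the nose) gets that landmark's coordinate exactly.
    """
    if not frame.success:
        raise InvalidFrameError(
            f"frame {frame.frame_index}: landmark detection failed")
    definition = validate_definition(definition or DEFAULT_AOI_DEFINITION)
    centers = {
        label: frame.points[np.asarray(numbers) - 1].mean(axis=0)
        for label, numbers in definition.items()
    }
    return AOICenterSet(centers=centers, valid=True)


def derive_center_track(
    track: LandmarkTrack,
    definition: dict | None = None,
    gap_policy: str = CARRY_FORWARD,
    max_gap_frames: int = 12,
    min_confidence: float = 0.0,
) -> AOICenterTrack:
    """AOI cell centers for every frame of a landmark track.

    Frames where detection failed (``success`` false, or confidence below
    ``min_confidence``) are handled per ``gap_policy``:

    ``carry_forward``
        Repeat the last valid centers, but only across runs of at most
        ``max_gap_frames`` failed frames (default 12, about half a second at
        25 fps); longer runs — and any leading run — become missing.
    ``mark_missing``
        Every failed frame becomes missing.

    Carried frames are flagged in the output's ``carried`` array.
    """
    if gap_policy not in (CARRY_FORWARD, MARK_MISSING):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    definition = validate_definition(definition or DEFAULT_AOI_DEFINITION)
    n = len(track)
    ok = track.success & (track.confidence >= min_confidence)
    if not ok.any():
        raise AllFramesInvalidError("no frame has a successful detection")

    coords = {label: np.full((n, 2), np.nan) for label in L.FACIAL_AOIS}
    valid = np.zeros(n, dtype=bool)
    carried = np.zeros(n, dtype=bool)

    idx = {label: np.asarray(numbers) - 1 for label, numbers in definition.items()}
    for label, rows in idx.items():
        coords[label][ok] = track.points[ok][:, rows, :].mean(axis=1)
    valid[ok] = True

    if gap_policy == CARRY_FORWARD:
        last_ok = -1
        i = 0
        while i < n:
            if ok[i]:
                last_ok = i
                i += 1
                continue
            j = i
            while j < n and not ok[j]:
                j += 1
            gap = j - i
            if last_ok >= 0 and gap <= max_gap_frames:
                for label in L.FACIAL_AOIS:
                    coords[label][i:j] = coords[label][last_ok]
                valid[i:j] = True
                carried[i:j] = True
            i = j

    return AOICenterTrack(
        frame_index=track.frame_index.copy(),
        timestamps=track.timestamps.copy(),
        coords=coords,
        valid=valid,
        frame_rate=track.frame_rate,
        carried=carried,
    )
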