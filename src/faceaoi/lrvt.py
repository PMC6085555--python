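"""Limited-Radius Voronoi Tessellation (LRVT) gaze-to-AOI assignment.

A gaze coordinate is assigned to the facial AOI whose cell center is nearest
in Euclidean pixel distance, provided that distance does not exceed a maximum
radius (default 4 degrees of visual angle, converted to pixels once using the
horizontal screen axis).  Anything farther from every center than the radius
falls in the "non" AOI.  The boundary is inclusive: distance == radius still
counts as inside, reading "does not exceed" as <=.

Exact distance ties (a measure-zero event for real data) are broken by a
deterministic label order, by default left eye, right eye, nose, mouth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import labels as L
from .errors import DomainError, InvalidCentersError
from .geometry import HORIZONTAL, ScreenGeometry, deg_to_px
from .io_formats import AOICenterSet, AOICenterTrack, AOILabelStream, GazeRecording


@dataclass(frozen=True)
class LRVTConfig:
    """Parameters of the LRVT assignment rule."""

    radius_deg: float = 4.0
    tie_order: tuple[str, ...] = L.FACIAL_AOIS
    boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius_deg) and self.radius_deg > 0):
            raise ValueError(f"radius_deg must be finite and > 0, got {self.radius_deg}")
        if sorted(self.tie_order) != sorted(L.FACIAL_AOIS):
            raise ValueError("tie_order must be a permutation of the four AOI labels")


def align_to_frames(
    timestamps: np.ndarray,
    frame_rate: float,
    offset: float = 0.0,
    n_frames: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map sample times to video frame indices.

    A sample at time *t* belongs to frame ``floor((t - offset) * frame_rate)``.
    When ``n_frames`` is given, indices are clamped to ``[0, n_frames - 1]``
    and the returned boolean array flags clamped samples.
    """
    if not frame_rate > 0:
        raise DomainError(f"frame_rate must be > 0, got {frame_rate}")
    t = np.asarray(timestamps, dtype=float)
    # nudge by half a ulp-scale epsilon so exact frame boundaries (t*fps
    # integral) do not fall to the previous frame through float error
    raw = np.floor((t - offset) * frame_rate + 1e-9).astype(int)
    if n_frames is None:
        return raw, np.zeros(len(raw), dtype=bool)
    clamped_idx = np.clip(raw, 0, n_frames - 1)
    return clamped_idx, raw != clamped_idx


def assign_point(
    point,
    centers: AOICenterSet,
    radius_px: float,
    config: LRVTConfig = LRVTConfig(),
) -> str:
    """Assign one gaze coordinate against one frame's centers.

    Returns the label of the nearest center if within the radius, else "non".
    """
    if not centers.valid:
        raise InvalidCentersError("centers are not valid for this frame")
    if not radius_px > 0:
        raise ValueError(f"radius_px must be > 0, got {radius_px}")
    p = np.asarray(point, dtype=float)
    best_label = None
    best_d = np.inf
    for label in config.tie_order:
        d = float(np.hypot(*(p - centers[label])))
        if d < best_d:  # strict: earlier tie_order label wins exact ties
            best_d, best_label = d, label
    inside = best_d <= radius_px if config.boundary_inclusive else best_d < radius_px
    return best_label if inside else L.NON


def assign_stream(
    gaze: GazeRecording,
    centers: AOICenterTrack,
    config: LRVTConfig = LRVTConfig(),
    geom: ScreenGeometry | None = None,
    offset: float = 0.0,
    radius_px: float | None = None,
) -> AOILabelStream:
    """Assign every gaze sample to an AOI label.

    The radius is converted from degrees to pixels once, on the horizontal
    screen axis (``radius_px`` overrides the conversion when given).  Samples
    that are invalid, or whose aligned video frame has missing centers, are
    labelled "missing".
    """
    if radius_px is None:
        if geom is None:
            raise ValueError("need either geom or an explicit radius_px")
        radius_px = deg_to_px(config.radius_deg, geom, HORIZONTAL)

    n = len(gaze)
    frame_idx, _ = align_to_frames(
        gaze.timestamps, centers.frame_rate, offset, n_frames=len(centers))

    # (n, 4) distance matrix, columns in tie_order; argmin takes the first
    # minimal column, which implements the deterministic tie-break
    cx = np.stack([centers.coords[lab][frame_idx, 0] for lab in config.tie_order], axis=1)
    cy = np.stack([centers.coords[lab][frame_idx, 1] for lab in config.tie_order], axis=1)
    with np.errstate(invalid="ignore"):
        dist = np.hypot(cx - gaze.x[:, None], cy - gaze.y[:, None])

    labels = np.full(n, L.NON, dtype=object)
    frame_ok = centers.valid[frame_idx]
    usable = gaze.valid & frame_ok
    if usable.any():
        d = dist[usable]
        nearest = np.argmin(d, axis=1)
        dmin = d[np.arange(len(d)), nearest]
        inside = dmin <= radius_px if config.boundary_inclusive else dmin < radius_px
        tie_labels = np.asarray(config.tie_order, dtype=object)
        assigned = np.where(inside, tie_labels[nearest], L.NON)
        labels[usable] = assigned
    labels[~usable] = L.MISSING

    return AOILabelStream(
        timestamps=gaze.timestamps.copy(),
        labels=labels,
        sampling_rate=gaze.sampling_rate,
        frame_indices=frame_idx,
    )
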