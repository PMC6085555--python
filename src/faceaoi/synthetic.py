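"""Synthetic landmark tracks and gaze recordings with known ground truth.

The generators emulate the inputs of the pipeline — a 68-point facial
landmark track from a frontal video of one face, and timestamped gaze
recordings of an observer watching that face — so that every stage can be
tested end-to-end against a known answer without any real video.

The face is a hard-coded, anatomically plausible 68-point template spanning
roughly 300 x 400 px, rigidly translated by a per-axis sinusoid (smooth head
motion) with i.i.d. Gaussian landmark jitter on top.  Blinks are modelled as
rectangular displacement pulses on the eye landmarks only: during a blink
the landmark-derived eye centers move downward (+y) and inward toward the
face midline, as eyelid closure drags the detected eye outline.  Ground
truth AOI centers come from the noiseless, blink-free trajectory.

Gaze follows a dwell schedule: each scheduled segment targets one facial
AOI's current center (plus Gaussian noise) or an off-face point, and samples
are dropped i.i.d. to emulate tracker data loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import labels as L
from .aoi_centers import derive_center_track
from .errors import (
    InvalidConfigError,
    ScheduleMismatchError,
    ScheduleOverflowError,
)
from .io_formats import (
    AOICenterTrack,
    AOILabelStream,
    GazeRecording,
    LandmarkTrack,
)
from .paired_gaze import PairedGazeStream

#: Schedule token for an off-face gaze target.
OFF_FACE = "off"


def build_template_face(center: tuple[float, float] = (840.0, 525.0)) -> np.ndarray:
    """A plausible 68-point frontal face layout (approx. 300 x 400 px).

    Landmark numbering follows the standard scheme: jaw 1-17, eyebrows
    18-27, nose bridge 28-31 (31 = tip), nostril line 32-36, left eye 37-42,
    right eye 43-48, outer lip 49-60, inner lip 61-68 (63/67 = inner upper/
    lower lip midpoints).  Coordinates are pixels with y pointing down;
    ``center`` places the face in the video frame.
    """
    pts = np.zeros((68, 2))
    # jaw: elliptical arc ear-to-ear through the chin
    t = np.linspace(0.0, math.pi, 17)
    pts[0:17, 0] = -150.0 * np.cos(t)
    pts[0:17, 1] = -40.0 + 240.0 * np.sin(t)
    # eyebrows: shallow arches
    bx = np.linspace(-110.0, -40.0, 5)
    arch = 10.0 * np.sin(np.linspace(0.0, math.pi, 5))
    pts[17:22] = np.column_stack([bx, -105.0 - arch])
    pts[22:27] = np.column_stack([-bx[::-1], -105.0 - arch])
    # nose bridge (28-31) and nostril line (32-36)
    pts[27:31] = np.column_stack([np.zeros(4), np.array([-75.0, -40.0, -5.0, 30.0])])
    nx = np.linspace(-25.0, 25.0, 5)
    pts[31:36] = np.column_stack([nx, 50.0 + 4.0 * np.cos(np.linspace(0, math.pi, 5))])
    # eyes: hexagonal outlines around (-75, -65) and (75, -65)
    left_eye = np.array([
        [-100.0, -65.0], [-87.0, -72.0], [-63.0, -72.0],
        [-50.0, -65.0], [-63.0, -58.0], [-87.0, -58.0],
    ])
    pts[36:42] = left_eye
    pts[42:48] = np.column_stack([-left_eye[::-1, 0], left_eye[::-1, 1]])
    # outer lip: 12 points clockwise from the left corner; the lip midline
    # sits ~105 px below the nose tip so that adjacent AOI centers are
    # separated by several times any realistic landmark/gaze noise scale
    t = 2.0 * math.pi * np.arange(12) / 12.0
    pts[48:60] = np.column_stack([-50.0 * np.cos(t), 135.0 - 18.0 * np.sin(t)])
    # inner lip: 8 points; index 62 (=63) upper middle, 66 (=67) lower middle
    t = 2.0 * math.pi * np.arange(8) / 8.0
    pts[60:68] = np.column_stack([-35.0 * np.cos(t), 135.0 - 10.0 * np.sin(t)])
    return pts + np.asarray(center, dtype=float)


@dataclass(frozen=True)
class FaceSimConfig:
    """Configuration of the landmark-track generator.

    ``blink_offset`` is (displacement toward the face midline, displacement
    downward), both in pixels, applied to the eye landmarks during blinks.
    """

    n_frames: int = 250
    frame_rate: float = 25.0
    base_landmarks: np.ndarray = field(default_factory=build_template_face)
    motion_amp_px: tuple[float, float] = (20.0, 10.0)
    motion_period_s: tuple[float, float] = (4.0, 3.0)
    jitter_sd: float = 0.5
    blink_schedule: tuple[tuple[int, int], ...] = ()
    blink_offset: tuple[float, float] = (5.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.base_landmarks, dtype=float)
        if pts.shape != (68, 2):
            raise InvalidConfigError("base_landmarks must have shape (68, 2)")
        object.__setattr__(self, "base_landmarks", pts)
        if self.n_frames < 1 or self.frame_rate <= 0:
            raise InvalidConfigError("n_frames >= 1 and frame_rate > 0 required")
        if self.jitter_sd < 0 or any(a < 0 for a in self.motion_amp_px):
            raise InvalidConfigError("amplitudes and jitter_sd must be >= 0")
        for start, dur in self.blink_schedule:
            if start < 0 or dur < 1 or start + dur > self.n_frames:
                raise InvalidConfigError(
                    f"blink window ({start}, {dur}) outside the track")


@dataclass(frozen=True)
class GazeSimConfig:
    """Configuration of the gaze generator.

    ``dwell_schedule`` is a list of (target, duration_s) where target is a
    facial AOI label or :data:`OFF_FACE`; the off-face point defaults to a
    location 500 px beyond the face bounding box, farther than any sensible
    LRVT radius from every center.
    """

    dwell_schedule: tuple[tuple[str, float], ...]
    noise_sd: float = 0.0
    sampling_rate: float = 100.0
    p_missing: float = 0.0
    off_face_point: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dwell_schedule:
            raise InvalidConfigError("dwell_schedule must be nonempty")
        for target, dur in self.dwell_schedule:
            if target not in L.FACIAL_AOIS and target != OFF_FACE:
                raise InvalidConfigError(f"unknown schedule target {target!r}")
            if not dur > 0:
                raise InvalidConfigError("schedule durations must be > 0")
        if not 0.0 <= self.p_missing < 1.0:
            raise InvalidConfigError("p_missing must be in [0, 1)")
        if self.noise_sd < 0 or self.sampling_rate <= 0:
            raise InvalidConfigError("noise_sd >= 0 and sampling_rate > 0 required")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.dwell_schedule))


def generate_landmark_track(
    cfg: FaceSimConfig,
) -> tuple[LandmarkTrack, AOICenterTrack]:
    """Simulate a landmark track; also return the ground-truth center track.

    The truth centers are derived from the noiseless, blink-free trajectory
    (template + rigid motion only).  Same seed, same output, bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    t = np.arange(n) / cfg.frame_rate

    shift = np.zeros((n, 2))
    for ax in (0, 1):
        amp, period = cfg.motion_amp_px[ax], cfg.motion_period_s[ax]
        if amp > 0 and period > 0:
            shift[:, ax] = amp * np.sin(2.0 * math.pi * t / period)

    clean = cfg.base_landmarks[None, :, :] + shift[:, None, :]

    clean_track = LandmarkTrack(
        frame_index=np.arange(n),
        timestamps=t,
        confidence=np.ones(n),
        success=np.ones(n, dtype=bool),
        points=clean,
        frame_rate=cfg.frame_rate,
        source_id="synthetic-truth",
    )
    truth_centers = derive_center_track(clean_track)

    points = clean + rng.normal(0.0, cfg.jitter_sd, size=clean.shape) \
        if cfg.jitter_sd > 0 else clean.copy()

    if cfg.blink_schedule:
        dx, dy = cfg.blink_offset
        midline_x = cfg.base_landmarks[:, 0].mean()
        for start, dur in cfg.blink_schedule:
            frames = slice(start, start + dur)
            for rows in (slice(36, 42), slice(42, 48)):  # landmarks 37-42, 43-48
                eye_x = cfg.base_landmarks[rows, 0].mean()
                toward_mid = 1.0 if eye_x < midline_x else -1.0
                points[frames, rows, 0] += toward_mid * dx
                points[frames, rows, 1] += dy

    track = LandmarkTrack(
        frame_index=np.arange(n),
        timestamps=t,
        confidence=np.ones(n),
        success=np.ones(n, dtype=bool),
        points=points,
        frame_rate=cfg.frame_rate,
        source_id=f"synthetic-seed{cfg.seed}",
    )
    return track, truth_centers


def _default_off_point(centers: AOICenterTrack) -> np.ndarray:
    xs = np.concatenate([c[:, 0] for c in centers.coords.values()])
    ys = np.concatenate([c[:, 1] for c in centers.coords.values()])
    return np.array([np.nanmax(xs) + 500.0, np.nanmax(ys) + 500.0])


def _schedule_lookup(schedule, times: np.ndarray) -> np.ndarray:
    """Target token of each sample time under a (token, duration) schedule."""
    bounds = np.cumsum([d for _, d in schedule])
    # eps keeps samples that land exactly on a segment boundary (up to float
    # accumulation error in the cumsum) in the segment that starts there
    seg = np.searchsorted(bounds, times + 1e-9, side="right")
    seg = np.clip(seg, 0, len(schedule) - 1)
    tokens = np.asarray([tok for tok, _ in schedule], dtype=object)
    return tokens[seg]


def generate_gaze(
    cfg: GazeSimConfig,
    centers: AOICenterTrack,
) -> tuple[GazeRecording, AOILabelStream]:
    """Simulate gaze following a dwell schedule over a center track.

    Returns the recording and the true per-sample label stream (scheduled
    AOI label, "non" for off-face segments, "missing" for dropped samples).
    """
    track_duration = len(centers) / centers.frame_rate
    if cfg.duration_s > track_duration + 1e-9:
        raise ScheduleOverflowError(
            f"schedule {cfg.duration_s:.3f}s exceeds track {track_duration:.3f}s")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    frame_idx = np.minimum((t * centers.frame_rate + 1e-9).astype(int),
                           len(centers) - 1)

    targets = _schedule_lookup(cfg.dwell_schedule, t)
    off = (np.asarray(cfg.off_face_point, dtype=float)
           if cfg.off_face_point is not None else _default_off_point(centers))

    xy = np.empty((n, 2))
    truth = np.empty(n, dtype=object)
    for tok in set(targets):
        sel = targets == tok
        if tok == OFF_FACE:
            xy[sel] = off
            truth[sel] = L.NON
        else:
            xy[sel] = centers.coords[tok][frame_idx[sel]]
            truth[sel] = tok

    if cfg.noise_sd > 0:
        xy += rng.normal(0.0, cfg.noise_sd, size=xy.shape)

    valid = np.ones(n, dtype=bool)
    if cfg.p_missing > 0:
        valid = rng.random(n) >= cfg.p_missing
    frame_ok = centers.valid[frame_idx]
    valid &= frame_ok
    truth[~valid] = L.MISSING

    rec = GazeRecording(timestamps=t, x=xy[:, 0], y=xy[:, 1], valid=valid,
                        sampling_rate=cfg.sampling_rate)
    truth_stream = AOILabelStream(timestamps=t, labels=truth,
                                  sampling_rate=cfg.sampling_rate,
                                  frame_indices=frame_idx)
    return rec, truth_stream


#: Per-participant gaze targets realizing each dyadic state.
_STATE_TARGETS = {
    L.TWO_WAY: (L.LEFT_EYE, L.RIGHT_EYE),
    L.ONE_WAY: (L.LEFT_EYE, L.NOSE),
    L.NO_EYE_GAZE: (L.NOSE, L.MOUTH),
}


def generate_dyad(
    cfg_a: GazeSimConfig,
    cfg_b: GazeSimConfig,
    mutual_schedule: tuple[tuple[str, float], ...],
    centers_a: AOICenterTrack,
    centers_b: AOICenterTrack,
) -> tuple[GazeRecording, GazeRecording, AOILabelStream, AOILabelStream,
           PairedGazeStream]:
    """Simulate a dyad from a shared schedule of paired gaze states.

    ``mutual_schedule`` lists (state, duration_s) with state in
    {two_way, one_way, no_eye_gaze}.  Each participant's dwell schedule is
    derived from it (the ``dwell_schedule`` fields of the configs are
    ignored); noise/missingness settings apply per participant.  Returns
    both recordings, both true label streams, and the true paired-gaze
    stream on the coarser participant's timeline.
    """
    for state, dur in mutual_schedule:
        if state not in _STATE_TARGETS:
            raise ScheduleMismatchError(f"unknown paired state {state!r}")
        if not dur > 0:
            raise ScheduleMismatchError("schedule durations must be > 0")

    sched_a = tuple((_STATE_TARGETS[s][0], d) for s, d in mutual_schedule)
    sched_b = tuple((_STATE_TARGETS[s][1], d) for s, d in mutual_schedule)
    rec_a, truth_a = generate_gaze(replace(cfg_a, dwell_schedule=sched_a), centers_a)
    rec_b, truth_b = generate_gaze(replace(cfg_b, dwell_schedule=sched_b), centers_b)

    base = truth_a if cfg_a.sampling_rate <= cfg_b.sampling_rate else truth_b
    other = truth_b if base is truth_a else truth_a
    t = base.timestamps
    pos = np.clip(np.searchsorted(other.timestamps, t), 0, len(other) - 1)
    left = np.clip(pos - 1, 0, len(other) - 1)
    nearest = np.where(
        np.abs(other.timestamps[pos] - t) < np.abs(other.timestamps[left] - t),
        pos, left)
    states = _schedule_lookup(mutual_schedule, t)
    missing = (base.labels == L.MISSING) | (other.labels[nearest] == L.MISSING)
    states = states.copy()
    states[missing] = L.UNDEFINED
    truth_pair = PairedGazeStream(
        timestamps=t.copy(), states=states,
        sampling_rate=min(cfg_a.sampling_rate, cfg_b.sampling_rate))
    return rec_a, rec_b, truth_a, truth_b, truth_pair
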