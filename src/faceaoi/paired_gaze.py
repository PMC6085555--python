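"""Dyadic paired-gaze states from two participants' AOI label streams.

Each participant of a dyad watches a live video of the other; per time point
the pair is in one of three states:

* ``two_way``     — both are looking at the partner's eyes,
* ``one_way``     — exactly one is looking at the eyes,
* ``no_eye_gaze`` — neither is (but both signals are present).

"Looking at the eyes" means the sample's label is left_eye or right_eye.
A missing sample on either side makes the joint state ``undefined``: absence
of data is not evidence of looking away, and keeping undefined separate lets
the four state totals tile the session duration exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import labels as L
from .errors import EmptyStreamError
from .io_formats import AOILabelStream

_EYE_LABELS = {L.LEFT_EYE, L.RIGHT_EYE}


@dataclass
class PairedGazeStream:
    """Per-sample dyadic gaze states on a shared timeline."""

    timestamps: np.ndarray
    states: np.ndarray  # str from labels.PAIRED_STATES
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.states = np.asarray(self.states, dtype=object)
        if len(self.timestamps) != len(self.states):
            raise ValueError("timestamps and states must have equal length")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def sample_interval(self) -> float:
        if self.sampling_rate:
            return 1.0 / self.sampling_rate
        if len(self.timestamps) < 2:
            raise ValueError("cannot infer sample interval from one sample")
        return float(np.median(np.diff(self.timestamps)))


def join_timelines(
    a: AOILabelStream,
    b: AOILabelStream,
    tolerance_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Nearest-timestamp join of two label streams.

    The joint timeline is the coarser (lower-rate) stream's; each of its
    samples is paired with the partner's nearest-in-time sample.  Partner
    samples farther away than ``tolerance_s`` (default: half the coarser
    sample interval) count as missing.

    Returns ``(timestamps, labels_base, labels_partner, sampling_rate)``
    where the base is the coarser stream.
    """
    if len(a) == 0 or len(b) == 0:
        raise EmptyStreamError("cannot join an empty label stream")
    dt_a, dt_b = a.sample_interval, b.sample_interval
    base, other = (a, b) if dt_a >= dt_b else (b, a)
    swap = base is b
    if tolerance_s is None:
        tolerance_s = base.sample_interval / 2.0

    t_base = base.timestamps
    t_other = other.timestamps
    pos = np.searchsorted(t_other, t_base)
    pos = np.clip(pos, 1, len(t_other) - 1) if len(t_other) > 1 else np.zeros(
        len(t_base), dtype=int)
    left = np.clip(pos - 1, 0, len(t_other) - 1)
    nearest = np.where(
        np.abs(t_other[pos] - t_base) < np.abs(t_other[left] - t_base), pos, left)
    dt = np.abs(t_other[nearest] - t_base)
    partner = other.labels[nearest].copy()
    partner[dt > tolerance_s + 1e-12] = L.MISSING

    rate = base.sampling_rate or 1.0 / base.sample_interval
    if swap:
        return t_base.copy(), partner, base.labels.copy(), rate
    return t_base.copy(), base.labels.copy(), partner, rate


def classify_state(label_a: str, label_b: str) -> str:
    """Dyadic state of one sample pair (symmetric in its arguments)."""
    if label_a == L.MISSING or label_b == L.MISSING:
        return L.UNDEFINED
    eyes_a = label_a in _EYE_LABELS
    eyes_b = label_b in _EYE_LABELS
    if eyes_a and eyes_b:
        return L.TWO_WAY
    if eyes_a or eyes_b:
        return L.ONE_WAY
    return L.NO_EYE_GAZE


def pair_streams(
    a: AOILabelStream,
    b: AOILabelStream,
    tolerance_s: float | None = None,
) -> PairedGazeStream:
    """Join two label streams and classify every joint sample."""
    t, la, lb, rate = join_timelines(a, b, tolerance_s)
    eyes_a = np.isin(la.astype(str), list(_EYE_LABELS))
    eyes_b = np.isin(lb.astype(str), list(_EYE_LABELS))
    missing = (la == L.MISSING) | (lb == L.MISSING)
    states = np.full(len(t), L.NO_EYE_GAZE, dtype=object)
    states[eyes_a ^ eyes_b] = L.ONE_WAY
    states[eyes_a & eyes_b] = L.TWO_WAY
    states[missing] = L.UNDEFINED
    return PairedGazeStream(timestamps=t, states=states, sampling_rate=rate)


def summarize_states(stream: PairedGazeStream) -> pd.DataFrame:
    """Episode statistics per paired-gaze state.

    An episode is a maximal run of one state; each sample occupies one sample
    interval.  Returns a DataFrame indexed by state with columns
    ``total_time_s``, ``mean_episode_s``, ``n_episodes`` and
    ``episodes_per_min`` (the episode count as a rate over the session).
    """
    if len(stream) == 0:
        raise EmptyStreamError("paired-gaze stream has no samples")
    dt = stream.sample_interval
    t = stream.timestamps
    session = float(t[-1] + dt - t[0])

    totals = {s: 0.0 for s in L.PAIRED_STATES}
    counts = {s: 0 for s in L.PAIRED_STATES}
    n = len(stream)
    i = 0
    while i < n:
        j = i + 1
        while j < n and stream.states[j] == stream.states[i]:
            j += 1
        s = stream.states[i]
        totals[s] += float(t[j - 1] + dt - t[i])
        counts[s] += 1
        i = j

    records = []
    for s in L.PAIRED_STATES:
        records.append({
            "state": s,
            "total_time_s": totals[s],
            "mean_episode_s": totals[s] / counts[s] if counts[s] else 0.0,
            "n_episodes": counts[s],
            "episodes_per_min": 60.0 * counts[s] / session if session > 0 else 0.0,
        })
    return pd.DataFrame.from_records(records).set_index("state")
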