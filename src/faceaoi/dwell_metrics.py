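"""Dwell segmentation and per-AOI dwell statistics.

A *dwell* is a maximal run of consecutive gaze samples carrying the same
non-missing AOI label.  Each sample is taken to occupy one sample interval,
so a one-sample dwell lasts 1/sampling_rate seconds and the dwell durations
plus missing time tile the recording exactly.

Runs of missing samples no longer than ``gap_tolerance_s`` that are flanked
by the same label on both sides are bridged into a single dwell (default
tolerance 0: no bridging, every missing sample splits dwells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import labels as L
from .errors import EmptyStreamError, UnknownLabelError
from .io_formats import AOILabelStream

#: Default combined-AOI map: "eyes" aggregates the two eye AOIs.
DEFAULT_COMBINE: dict[str, frozenset] = {
    L.EYES: frozenset({L.LEFT_EYE, L.RIGHT_EYE}),
}

#: Labels reported in a dwell summary, in output order.
SUMMARY_LABELS: tuple[str, ...] = (
    L.LEFT_EYE, L.RIGHT_EYE, L.EYES, L.NOSE, L.MOUTH, L.NON)


@dataclass(frozen=True)
class Dwell:
    """One maximal same-label run of gaze samples."""

    label: str
    start: float      # onset time of the first sample, s
    end: float        # offset = last sample time + one sample interval, s
    n_samples: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def _runs(values: np.ndarray):
    """Yield (start_idx, end_idx_exclusive, value) for maximal equal runs."""
    n = len(values)
    i = 0
    while i < n:
        j = i + 1
        while j < n and values[j] == values[i]:
            j += 1
        yield i, j, values[i]
        i = j


def segment_dwells(
    stream: AOILabelStream,
    gap_tolerance_s: float = 0.0,
    min_dwell_s: float = 0.0,
) -> list[Dwell]:
    """Segment a label stream into dwells.

    Missing runs of duration <= ``gap_tolerance_s`` flanked by the same label
    are bridged; dwells shorter than ``min_dwell_s`` are dropped afterwards.
    """
    if len(stream) == 0:
        raise EmptyStreamError("label stream has no samples")
    dt = stream.sample_interval
    t = stream.timestamps

    # bridge short missing runs with identical flanks
    merged: list[tuple[int, int, str]] = []
    for i, j, lab in _runs(stream.labels):
        if (lab != L.MISSING and len(merged) >= 2
                and merged[-1][2] == L.MISSING and merged[-2][2] == lab):
            gi, gj, _ = merged[-1]
            gap_dur = (t[gj - 1] + dt) - t[gi]
            if gap_dur <= gap_tolerance_s + 1e-12:
                merged.pop()                    # gap absorbed into the dwell
                pi, _, _ = merged.pop()
                merged.append((pi, j, lab))
                continue
        merged.append((i, j, lab))

    dwells = []
    for i, j, lab in merged:
        if lab == L.MISSING:
            continue
        n_samples = int(np.sum(stream.labels[i:j] != L.MISSING))
        d = Dwell(label=lab, start=float(t[i]), end=float(t[j - 1] + dt),
                  n_samples=n_samples)
        if d.duration >= min_dwell_s:
            dwells.append(d)
    return dwells


def _merge_adjacent(dwells: list[Dwell], eps: float = 1e-6) -> list[Dwell]:
    """Merge temporally contiguous dwells that share a label."""
    out: list[Dwell] = []
    for d in dwells:
        if out and out[-1].label == d.label and abs(d.start - out[-1].end) <= eps:
            prev = out[-1]
            out[-1] = Dwell(label=d.label, start=prev.start, end=d.end,
                            n_samples=prev.n_samples + d.n_samples)
        else:
            out.append(d)
    return out


def summarize_dwells(
    dwells: list[Dwell],
    combine: dict | None = None,
) -> pd.DataFrame:
    """Per-AOI dwell statistics: total dwell time, mean dwell time, dwell count.

    ``combine`` maps a new label to the set of labels it aggregates (default:
    "eyes" = left + right eye).  Under a combined label, temporally adjacent
    left/right dwells merge into one dwell, so the combined total is additive
    but the combined count can be smaller than the sum of the parts.

    Returns a DataFrame indexed by label with columns ``total_dwell_time_s``,
    ``mean_dwell_time_s``, ``n_dwells``.
    """
    combine = DEFAULT_COMBINE if combine is None else combine
    known = set(L.ALL_LABELS)
    flat: set[str] = set()
    for new_label, parts in combine.items():
        parts = set(parts)
        if not parts <= known:
            raise UnknownLabelError(f"{new_label}: unknown labels {parts - known}")
        if flat & parts:
            raise ValueError("combine sets must be disjoint")
        flat |= parts

    rows = {}
    base_labels = [lab for lab in SUMMARY_LABELS if lab not in combine]
    for lab in base_labels:
        sel = [d for d in dwells if d.label == lab]
        rows[lab] = sel
    for new_label, parts in combine.items():
        relabeled = [
            Dwell(label=new_label, start=d.start, end=d.end, n_samples=d.n_samples)
            for d in dwells if d.label in parts
        ]
        rows[new_label] = _merge_adjacent(relabeled)

    order = [lab for lab in SUMMARY_LABELS if lab in rows] + \
            [lab for lab in rows if lab not in SUMMARY_LABELS]
    records = []
    for lab in order:
        sel = rows[lab]
        total = float(sum(d.duration for d in sel))
        n = len(sel)
        records.append({
            "label": lab,
            "total_dwell_time_s": total,
            "mean_dwell_time_s": total / n if n else 0.0,
            "n_dwells": n,
        })
    return pd.DataFrame.from_records(records).set_index("label")


def percent_difference(measure_a: float, measure_ref: float) -> float:
    """Absolute difference of ``measure_a`` from a reference, in percent.

    ``100 * |a - ref| / ref``; the reference is the comparison method's value.
    """
    if measure_ref == 0:
        raise ZeroDivisionError("reference measure is zero")
    return 100.0 * abs(measure_a - measure_ref) / measure_ref


def missing_time(stream: AOILabelStream) -> float:
    """Total duration of missing samples (one sample interval each)."""
    return float(np.sum(stream.labels == L.MISSING)) * stream.sample_interval


def stream_duration(stream: AOILabelStream) -> float:
    """Recording duration under the one-interval-per-sample convention."""
    if len(stream) == 0:
        return 0.0
    return float(stream.timestamps[-1] + stream.sample_interval
                 - stream.timestamps[0])
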