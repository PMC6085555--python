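import numpy as np
import pytest

import faceaoi as fa
from faceaoi import labels as L


@pytest.fixture(scope="session")
def screen() -> fa.ScreenGeometry:
    """22-inch 1680x1050 display with the inferred ~81 cm viewing distance."""
    return fa.study_screen()


def make_center_track(
    centers: dict | None = None,
    n: int = 10,
    frame_rate: float = 25.0,
    valid=None,
) -> fa.AOICenterTrack:
    """Constant-center AOI track for hand-built scenarios."""
    if centers is None:
        centers = {
            L.LEFT_EYE: (100.0, 100.0),
            L.RIGHT_EYE: (200.0, 100.0),
            L.NOSE: (150.0, 160.0),
            L.MOUTH: (150.0, 220.0),
        }
    coords = {k: np.tile(np.asarray(v, dtype=float), (n, 1))
              for k, v in centers.items()}
    if valid is None:
        valid = np.ones(n, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    for k in coords:
        coords[k][~valid] = np.nan
    return fa.AOICenterTrack(
        frame_index=np.arange(n),
        timestamps=np.arange(n) / frame_rate,
        coords=coords,
        valid=valid,
        frame_rate=frame_rate,
    )


def make_label_stream(labels, sampling_rate: float = 10.0) -> fa.AOILabelStream:
    labels = np.asarray(labels, dtype=object)
    t = np.arange(len(labels)) / sampling_rate
    return fa.AOILabelStream(timestamps=t, labels=labels,
                             sampling_rate=sampling_rate)


def make_landmark_track(points, frame_rate: float = 25.0, success=None,
                        confidence=None) -> fa.LandmarkTrack:
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if success is None:
        success = np.ones(n, dtype=bool)
    if confidence is None:
        confidence = np.ones(n)
    return fa.LandmarkTrack(
        frame_index=np.arange(n),
        timestamps=np.arange(n) / frame_rate,
        confidence=confidence,
        success=np.asarray(success, dtype=bool),
        points=points,
        frame_rate=frame_rate,
    )
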