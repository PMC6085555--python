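"""Limited-radius Voronoi gaze assignment and frame alignment."""

import numpy as np
import pytest

import faceaoi as fa
from faceaoi import labels as L
from faceaoi.errors import DomainError, InvalidCentersError
from conftest import make_center_track

CENTERS = {
    L.LEFT_EYE: (100.0, 100.0),
    L.RIGHT_EYE: (200.0, 100.0),
    L.NOSE: (150.0, 160.0),
    L.MOUTH: (150.0, 220.0),
}


def brute_force_label(point, centers, radius_px, inclusive=True,
                      tie_order=L.FACIAL_AOIS):
    """Independent oracle: argmin over all centers with a radius threshold."""
    p = np.asarray(point, dtype=float)
    dists = {lab: float(np.linalg.norm(p - np.asarray(centers[lab])))
             for lab in tie_order}
    best = min(dists, key=lambda lab: (dists[lab], tie_order.index(lab)))
    ok = dists[best] <= radius_px if inclusive else dists[best] < radius_px
    return best if ok else L.NON


def center_set(centers=CENTERS):
    return fa.AOICenterSet(
        centers={k: np.asarray(v, float) for k, v in centers.items()}, valid=True)


class TestAlignToFrames:
    def test_time_zero_is_frame_zero(self):
        idx, clamped = fa.align_to_frames(np.array([0.0]), 25.0)
        assert idx[0] == 0 and not clamped[0]

    def test_one_frame_interval_is_frame_one(self):
        idx, _ = fa.align_to_frames(np.array([0.04]), 25.0)
        assert idx[0] == 1

    def test_beyond_track_clamps_with_flag(self):
        idx, clamped = fa.align_to_frames(np.array([10.0]), 25.0, n_frames=100)
        assert idx[0] == 99 and clamped[0]

    def test_offset_shifts_mapping(self):
        idx, _ = fa.align_to_frames(np.array([0.5]), 25.0, offset=0.5)
        assert idx[0] == 0

    def test_nonpositive_frame_rate(self):
        with pytest.raises(DomainError):
            fa.align_to_frames(np.array([0.0]), 0.0)


class TestAssignPoint:
    def test_near_left_eye(self):
        assert fa.assign_point((110, 105), center_set(), 80.0) == L.LEFT_EYE

    def test_outside_radius_is_non(self):
        # distance 90 to the mouth center, radius 80
        assert fa.assign_point((150, 310), center_set(), 80.0) == L.NON

    def test_exactly_at_nose_center(self):
        assert fa.assign_point((150, 160), center_set(), 1.0) == L.NOSE

    def test_boundary_inclusive_vs_exclusive(self):
        # gaze exactly radius away from the nose, farther from all others
        cfg_in = fa.LRVTConfig(boundary_inclusive=True)
        cfg_out = fa.LRVTConfig(boundary_inclusive=False)
        point = (150.0 - 40.0, 160.0)
        assert fa.assign_point(point, center_set(), 40.0, cfg_in) == L.NOSE
        assert fa.assign_point(point, center_set(), 40.0, cfg_out) != L.NOSE

    def test_tie_broken_by_configured_order(self):
        # midpoint between the two eye centers, both at distance 50
        point = (150.0, 100.0)
        assert fa.assign_point(point, center_set(), 80.0) == L.LEFT_EYE
        cfg = fa.LRVTConfig(tie_order=(L.RIGHT_EYE, L.LEFT_EYE, L.NOSE, L.MOUTH))
        assert fa.assign_point(point, center_set(), 80.0, cfg) == L.RIGHT_EYE

    def test_invalid_centers_rejected(self):
        cs = fa.AOICenterSet(centers={k: np.full(2, np.nan) for k in CENTERS},
                             valid=False)
        with pytest.raises(InvalidCentersError):
            fa.assign_point((0, 0), cs, 10.0)

    def test_oracle_equivalence_random_configurations(self):
        """assign_point equals brute force on 10^4 random points/centers."""
        rng = np.random.default_rng(42)
        cs_template = center_set()
        n_checked = 0
        for _ in range(100):
            centers = {lab: tuple(rng.uniform(0, 500, 2))
                       for lab in L.FACIAL_AOIS}
            cs = center_set(centers)
            radius = float(rng.uniform(10, 300))
            points = rng.uniform(-100, 600, size=(100, 2))
            for p in points:
                got = fa.assign_point(p, cs, radius)
                assert got == brute_force_label(p, centers, radius)
                n_checked += 1
        assert n_checked == 10_000


class TestAssignStream:
    def make_gaze(self, xy, sampling_rate=100.0, valid=None):
        xy = np.asarray(xy, float)
        n = len(xy)
        if valid is None:
            valid = np.ones(n, dtype=bool)
        return fa.GazeRecording(np.arange(n) / sampling_rate, xy[:, 0],
                                xy[:, 1], valid, sampling_rate)

    def test_constant_gaze_at_left_eye(self, screen):
        centers = make_center_track(CENTERS, n=100, frame_rate=25.0)
        gaze = self.make_gaze(np.tile([100.0, 100.0], (100, 1)))
        stream = fa.assign_stream(gaze, centers, fa.LRVTConfig(), screen)
        assert (stream.labels == L.LEFT_EYE).all()

    def test_invalid_sample_isolated(self, screen):
        centers = make_center_track(CENTERS, n=100)
        valid = np.ones(10, dtype=bool)
        valid[4] = False
        gaze = self.make_gaze(np.tile([150.0, 160.0], (10, 1)), valid=valid)
        stream = fa.assign_stream(gaze, centers, fa.LRVTConfig(), screen)
        assert stream.labels[4] == L.MISSING
        assert stream.labels[3] == L.NOSE and stream.labels[5] == L.NOSE

    def test_missing_frame_centers_give_missing(self, screen):
        valid = np.ones(4, dtype=bool)
        valid[2] = False
        centers = make_center_track(CENTERS, n=4, frame_rate=25.0, valid=valid)
        gaze = self.make_gaze(np.tile([150.0, 160.0], (4, 1)),
                              sampling_rate=25.0)
        stream = fa.assign_stream(gaze, centers, fa.LRVTConfig(), screen)
        assert stream.labels[2] == L.MISSING
        assert stream.labels[1] == L.NOSE

    def test_matches_brute_force_on_random_stream(self, screen):
        rng = np.random.default_rng(7)
        n_frames = 50
        coords = {lab: rng.uniform(100, 400, size=(n_frames, 2))
                  for lab in L.FACIAL_AOIS}
        centers = fa.AOICenterTrack(
            frame_index=np.arange(n_frames),
            timestamps=np.arange(n_frames) / 25.0,
            coords=coords, valid=np.ones(n_frames, dtype=bool), frame_rate=25.0)
        gaze = self.make_gaze(rng.uniform(0, 500, size=(200, 2)))
        radius_px = fa.deg_to_px(4.0, screen)
        stream = fa.assign_stream(gaze, centers, fa.LRVTConfig(), screen)
        for i in range(200):
            f = min(int(gaze.timestamps[i] * 25.0 + 1e-9), n_frames - 1)
            want = brute_force_label(
                (gaze.x[i], gaze.y[i]),
                {lab: coords[lab][f] for lab in L.FACIAL_AOIS}, radius_px)
            assert stream.labels[i] == want

    def test_partition_every_sample_gets_one_label(self, screen):
        rng = np.random.default_rng(1)
        centers = make_center_track(CENTERS, n=100)
        gaze = self.make_gaze(rng.uniform(-200, 800, size=(500, 2)),
                              valid=rng.random(500) > 0.1)
        stream = fa.assign_stream(gaze, centers, fa.LRVTConfig(), screen)
        assert set(stream.labels) <= set(L.ALL_LABELS)
        assert len(stream) == 500

    def test_radius_monotonicity(self, screen):
        """Growing the radius never sends a facial label back to non."""
        rng = np.random.default_rng(5)
        centers = make_center_track(CENTERS, n=100)
        gaze = self.make_gaze(rng.uniform(0, 400, size=(400, 2)))
        small = fa.assign_stream(gaze, centers, fa.LRVTConfig(radius_deg=2.0),
                                 screen)
        large = fa.assign_stream(gaze, centers, fa.LRVTConfig(radius_deg=4.0),
                                 screen)
        facial = set(L.FACIAL_AOIS)
        for s, l in zip(small.labels, large.labels):
            if s in facial:
                assert l in facial
        assert (large.labels == L.NON).sum() <= (small.labels == L.NON).sum()

    def test_rigid_translation_invariance(self, screen):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 400, size=(200, 2))
        shift = np.array([123.0, -45.0])
        centers = make_center_track(CENTERS, n=100)
        shifted = make_center_track(
            {k: tuple(np.asarray(v) + shift) for k, v in CENTERS.items()}, n=100)
        a = fa.assign_stream(self.make_gaze(xy), centers, fa.LRVTConfig(), screen)
        b = fa.assign_stream(self.make_gaze(xy + shift), shifted,
                             fa.LRVTConfig(), screen)
        np.testing.assert_array_equal(a.labels, b.labels)
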