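"""Track-comparison statistics, temporal stability, and blink-spike handling."""

import numpy as np
import pytest

import faceaoi as fa
from faceaoi import labels as L
from faceaoi.errors import (
    AllFramesFlaggedError,
    InsufficientDataError,
    LengthMismatchError,
    NoOverlappingValidFramesError,
    WindowTooLargeError,
)
from conftest import make_center_track


def track_from_coord(values, aoi=L.LEFT_EYE, axis=0, frame_rate=25.0):
    """Constant track with one AOI coordinate replaced by ``values``."""
    n = len(values)
    track = make_center_track(n=n, frame_rate=frame_rate)
    track.coords[aoi][:, axis] = np.asarray(values, dtype=float)
    return track


class TestMeanAbsDiff:
    def test_identical_tracks_give_zero(self):
        a, b = make_center_track(n=5), make_center_track(n=5)
        assert (fa.mean_abs_diff(a, b)["value_px"] == 0).all()

    def test_hand_computed_two_frame_case(self):
        a = track_from_coord([0.0, 2.0])
        b = track_from_coord([1.0, 1.0])
        assert fa.mean_abs_diff(a, b).loc[(L.LEFT_EYE, "x"), "value_px"] == 1.0

    def test_joint_translation_invariance(self):
        rng = np.random.default_rng(0)
        a = track_from_coord(rng.uniform(0, 100, 20))
        b = track_from_coord(rng.uniform(0, 100, 20))
        before = fa.mean_abs_diff(a, b)
        shift = np.array([50.0, -30.0])
        for track in (a, b):
            for lab in L.FACIAL_AOIS:
                track.coords[lab] += shift
        after = fa.mean_abs_diff(a, b)
        np.testing.assert_allclose(after["value_px"], before["value_px"])

    def test_symmetry(self):
        a = track_from_coord([0.0, 3.0, 1.0])
        b = track_from_coord([2.0, 2.0, 2.0])
        np.testing.assert_allclose(fa.mean_abs_diff(a, b)["value_px"],
                                   fa.mean_abs_diff(b, a)["value_px"])

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            fa.mean_abs_diff(make_center_track(n=4), make_center_track(n=5))

    def test_no_overlapping_valid_frames(self):
        a = make_center_track(n=4, valid=[1, 1, 0, 0])
        b = make_center_track(n=4, valid=[0, 0, 1, 1])
        with pytest.raises(NoOverlappingValidFramesError):
            fa.mean_abs_diff(a, b)

    def test_invalid_frames_excluded_pairwise(self):
        a = track_from_coord([0.0, 100.0, 0.0])
        b = track_from_coord([1.0, 0.0, 1.0])
        a.valid[1] = False
        a.coords[L.LEFT_EYE][1] = np.nan
        assert fa.mean_abs_diff(a, b).loc[(L.LEFT_EYE, "x"), "value_px"] == 1.0


class TestMaxAbsDiff:
    def test_single_worst_frame(self):
        a = track_from_coord([0.0, 0.0, 7.0, 1.0])
        b = track_from_coord([0.0, 0.0, 0.0, 0.0])
        assert fa.max_abs_diff(a, b).loc[(L.LEFT_EYE, "x"), "value_px"] == 7.0

    def test_dominates_mean(self):
        rng = np.random.default_rng(1)
        a = track_from_coord(rng.uniform(0, 50, 30))
        b = track_from_coord(rng.uniform(0, 50, 30))
        assert (fa.max_abs_diff(a, b)["value_px"]
                >= fa.mean_abs_diff(a, b)["value_px"] - 1e-12).all()


class TestRmsS2S:
    def test_constant_coordinate_is_zero(self):
        assert (fa.rms_s2s(make_center_track(n=10))["value_px"] == 0).all()

    def test_alternating_unit_steps(self):
        track = track_from_coord([0.0, 1.0, 0.0, 1.0, 0.0])
        assert fa.rms_s2s(track).loc[(L.LEFT_EYE, "x"), "value_px"] == \
            pytest.approx(1.0)

    def test_two_px_steps(self):
        track = track_from_coord([0.0, 2.0, 0.0])
        assert fa.rms_s2s(track).loc[(L.LEFT_EYE, "x"), "value_px"] == \
            pytest.approx(2.0)

    def test_about_mean_mode(self):
        track = track_from_coord([0.0, 2.0, 0.0, 2.0])
        got = fa.rms_s2s(track, mode="about_mean").loc[(L.LEFT_EYE, "x"),
                                                       "value_px"]
        assert got == pytest.approx(1.0)

    def test_insufficient_data(self):
        track = make_center_track(n=4, valid=[1, 0, 1, 0])
        with pytest.raises(InsufficientDataError):
            fa.rms_s2s(track)


class TestCompareTracks:
    def test_report_columns_and_degree_mapping(self, screen):
        a = track_from_coord([0.0, 2.0, 1.0])
        b = make_center_track(n=3)
        report = fa.compare_tracks(a, b, screen)
        row = report.loc[(L.LEFT_EYE, "x")]
        assert row["max_abs_diff_px"] >= row["mean_abs_diff_px"]
        # degree columns are the pixel columns through the px->deg map
        assert row["mean_abs_diff_deg"] == pytest.approx(
            fa.px_to_deg(row["mean_abs_diff_px"], screen), rel=1e-9)


class TestDetectSpikes:
    def test_constant_track_has_no_flags(self):
        assert not fa.detect_spikes(make_center_track(n=20)).any()

    def test_single_excursion_flagged_exactly(self):
        values = np.full(21, 100.0)
        values[10] += 15.0
        track = track_from_coord(values, axis=1)
        flags = fa.detect_spikes(track, window=7, n_mad=3.0)
        assert list(np.where(flags)[0]) == [10]

    def test_slow_linear_drift_not_flagged(self):
        track = track_from_coord(np.linspace(0.0, 30.0, 60))
        assert not fa.detect_spikes(track, window=7, n_mad=3.0).any()

    def test_nose_excursion_ignored_by_default(self):
        values = np.full(21, 100.0)
        values[10] += 25.0
        track = track_from_coord(values, aoi=L.NOSE)
        assert not fa.detect_spikes(track).any()
        assert fa.detect_spikes(track, aois=(L.NOSE,)).any()

    def test_window_too_large(self):
        with pytest.raises(WindowTooLargeError):
            fa.detect_spikes(make_center_track(n=5), window=7)

    def test_blink_injection_full_recall_no_false_positives(self):
        """Synthetic blinks above threshold: 100% recall, 0 false alarms."""
        # with head motion in the window, the displacement must clear the
        # motion-driven MAD floor: 20 px down is a large but realistic spike
        cfg = fa.FaceSimConfig(n_frames=200, motion_amp_px=(15.0, 8.0),
                               jitter_sd=0.0,
                               blink_schedule=((40, 2), (100, 3), (160, 1)),
                               blink_offset=(6.0, 20.0), seed=21)
        track, _ = fa.generate_landmark_track(cfg)
        centers = fa.derive_center_track(track)
        flags = fa.detect_spikes(centers, window=9, n_mad=3.0)
        expected = np.zeros(200, dtype=bool)
        for start, dur in cfg.blink_schedule:
            expected[start:start + dur] = True
        np.testing.assert_array_equal(flags, expected)


class TestFilterSpikes:
    def test_no_flags_leaves_track_identical(self):
        track = make_center_track(n=10)
        out = fa.filter_spikes(track, np.zeros(10, dtype=bool))
        for lab in L.FACIAL_AOIS:
            np.testing.assert_array_equal(out.coords[lab], track.coords[lab])

    def test_spike_restored_by_interpolation(self):
        values = np.full(21, 100.0)
        values[10] += 15.0
        track = track_from_coord(values, axis=1)
        flags = fa.detect_spikes(track)
        out = fa.filter_spikes(track, flags)
        np.testing.assert_allclose(out.coords[L.LEFT_EYE][:, 1], 100.0)

    def test_median_replace_method(self):
        values = np.full(21, 100.0)
        values[10] += 15.0
        track = track_from_coord(values, axis=1)
        out = fa.filter_spikes(track, fa.detect_spikes(track),
                               method="median_replace")
        np.testing.assert_allclose(out.coords[L.LEFT_EYE][:, 1], 100.0)

    def test_edge_spikes_use_nearest_neighbour(self):
        values = np.full(11, 50.0)
        values[0] += 20.0
        values[-1] += 20.0
        track = track_from_coord(values)
        flags = np.zeros(11, dtype=bool)
        flags[[0, -1]] = True
        out = fa.filter_spikes(track, flags)
        np.testing.assert_allclose(out.coords[L.LEFT_EYE][:, 0], 50.0)

    def test_all_flagged_rejected(self):
        track = make_center_track(n=5)
        with pytest.raises(AllFramesFlaggedError):
            fa.filter_spikes(track, np.ones(5, dtype=bool))

    def test_filtering_reduces_rms_on_spiked_track(self):
        cfg = fa.FaceSimConfig(n_frames=150, motion_amp_px=(0.0, 0.0),
                               jitter_sd=0.0, blink_schedule=((50, 2),),
                               blink_offset=(6.0, 14.0), seed=3)
        track, _ = fa.generate_landmark_track(cfg)
        centers = fa.derive_center_track(track)
        filtered = fa.filter_spikes(centers, fa.detect_spikes(centers))
        assert (fa.rms_s2s(filtered)["value_px"]
                <= fa.rms_s2s(centers)["value_px"] + 1e-12).all()
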