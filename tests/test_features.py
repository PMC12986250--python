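"""VertDist, Ratio and marker-pair selection."""

import dataclasses

import numpy as np
import pytest

import facesym as fs
from facesym.features import ratio, select_exercise_markers, vert_dist
from facesym.geometry import axis_series

from conftest import make_eyes, make_track, static_recording


def rigid_transform(points, theta, shift):
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    return points @ R.T + shift


def transform_recording(rec, theta, shift):
    out = fs.Recording(
        rec.recording_id, rec.exercise, rec.fps,
        {mid: t.copy() for mid, t in rec.markers.items()},
        rec.eyes.copy(), rec.label,
    )
    for t in [*out.markers.values(), out.eyes.left, out.eyes.right]:
        t.xy[t.valid] = rigid_transform(t.xy[t.valid], theta, shift)
    return out


class TestSelectExerciseMarkers:
    def test_default_pairs(self):
        assert (select_exercise_markers("eyebrow_raising").left_id,
                select_exercise_markers("eyebrow_raising").right_id) == ("00", "01")
        assert (select_exercise_markers("smiling").left_id,
                select_exercise_markers("smiling").right_id) == ("10", "11")

    def test_override_returned_verbatim(self):
        spec = select_exercise_markers(
            "smiling", {fs.Exercise.SMILING: ("02", "03")}
        )
        assert (spec.left_id, spec.right_id) == ("02", "03")

    def test_unknown_exercise_rejected(self):
        with pytest.raises(ValueError):
            select_exercise_markers("frowning")


class TestVertDist:
    def test_absolute_difference_order_free(self):
        ti = make_track("00", [(0, 10.0), (0, 10.0)])
        tj = make_track("01", [(5, 7.0), (5, 13.0)])
        fwd = vert_dist(ti, tj)
        rev = vert_dist(tj, ti)
        np.testing.assert_allclose(fwd.values, [3.0, 3.0])
        np.testing.assert_allclose(rev.values, fwd.values)

    def test_mirrored_equal_height_markers_zero(self):
        rec = static_recording()
        out = vert_dist(rec.markers["00"], rec.markers["01"])
        assert np.all(out.values == 0.0)

    def test_invalid_frames_omitted(self):
        ti = make_track("00", [(0, 1.0), (0, 2.0), (0, 3.0)], valid=[1, 0, 1])
        tj = make_track("01", [(0, 0.0), (0, 0.0), (0, 0.0)])
        out = vert_dist(ti, tj)
        assert out.frames.tolist() == [0, 2]

    def test_no_common_frames_rejected(self):
        ti = make_track("00", [(0, 1.0)], start_frame=0)
        tj = make_track("01", [(0, 1.0)], start_frame=5)
        with pytest.raises(fs.InsufficientDataError):
            vert_dist(ti, tj)


class TestRatio:
    def test_symmetric_layout_ratio_one(self):
        rec = static_recording(exercise="smiling")
        axes = axis_series(rec.eyes)
        rt, dl, dr = ratio(rec, axes, select_exercise_markers("smiling"))
        np.testing.assert_allclose(rt.values, 1.0, atol=1e-12)
        np.testing.assert_allclose(dl.values, dr.values, atol=1e-12)

    def test_known_distance_quotient(self):
        rec = static_recording(exercise="smiling")
        # axis is x=500; put the pair at distances 2 (left) and 4 (right)
        rec.markers["10"].xy[:, 0] = 498.0
        rec.markers["11"].xy[:, 0] = 504.0
        axes = axis_series(rec.eyes)
        rt, _, _ = ratio(rec, axes, select_exercise_markers("smiling"))
        np.testing.assert_allclose(rt.values, 0.5, atol=1e-12)

    def test_orientation_duality(self):
        rec = static_recording(exercise="smiling")
        rec.markers["10"].xy[:, 0] = 470.0
        axes = axis_series(rec.eyes)
        lr, _, _ = ratio(rec, axes, select_exercise_markers("smiling"),
                         orientation="left_over_right")
        rl, _, _ = ratio(rec, axes, select_exercise_markers("smiling"),
                         orientation="right_over_left")
        np.testing.assert_allclose(rl.values, 1.0 / lr.values, atol=0)

    def test_denominator_on_axis_dropped_not_infinite(self):
        rec = static_recording(n_frames=4, exercise="smiling")
        rec.markers["11"].xy[1, 0] = 500.0  # exactly on the axis
        axes = axis_series(rec.eyes)
        rt, _, _ = ratio(rec, axes, select_exercise_markers("smiling"))
        assert rt.frames.tolist() == [0, 2, 3]
        assert np.all(np.isfinite(rt.values))

    def test_laterality_from_median_position(self):
        rec = static_recording(exercise="smiling")
        # stored "left" id is actually on the image-right side
        rec.markers["10"].xy[:, 0] = 540.0
        rec.markers["11"].xy[:, 0] = 450.0
        axes = axis_series(rec.eyes)
        rt, dl, dr = ratio(rec, axes, select_exercise_markers("smiling"))
        # image-left member (id "11", at x=450, distance 50) over image-right
        np.testing.assert_allclose(rt.values, 50.0 / 40.0)
        assert rt.meta["left_id"] == "11"


class TestFeatureInvariants:
    def test_mirror_identity_under_translation(self, symmetric_recording):
        """Exactly mirrored marker pairs give Ratio=1 and VertDist=0
        regardless of global translation."""
        rec = transform_recording(symmetric_recording, 0.0, np.array([37.0, -12.0]))
        feats = fs.compute_features(rec, axis_series(rec.eyes))
        np.testing.assert_allclose(feats["Ratio"].values, 1.0, atol=1e-9)
        np.testing.assert_allclose(feats["VertDist"].values, 0.0, atol=1e-9)

    def test_ratio_rigid_invariance(self, symmetric_recording, rng):
        import dataclasses
        params = fs.SimulationParams(
            exercise="smiling", asymmetry_amplitude=0.6, noise_sd_px=0.0,
            tremor_sd_px=0.0, head_drift_px_per_s=0.0, head_roll_deg_per_s=0.0,
            seed=11,
        )
        rec, _ = fs.simulate_recording(params)
        base = fs.compute_features(rec, axis_series(rec.eyes))["Ratio"]
        for _ in range(3):
            theta = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(-300, 300, 2)
            moved = transform_recording(rec, theta, shift)
            got = fs.compute_features(moved, axis_series(moved.eyes))["Ratio"]
            np.testing.assert_allclose(got.values, base.values, atol=1e-9)

    def test_vertdist_translation_invariance_and_scale_covariance(
        self, symmetric_recording
    ):
        params = fs.SimulationParams(exercise="eyebrow_raising",
                                     asymmetry_amplitude=0.5, noise_sd_px=0.0,
                                     tremor_sd_px=0.0, head_drift_px_per_s=0.0,
                                     head_roll_deg_per_s=0.0, seed=13)
        rec, _ = fs.simulate_recording(params)
        base = fs.compute_features(rec, axis_series(rec.eyes))
        shifted = transform_recording(rec, 0.0, np.array([-40.0, 55.0]))
        got = fs.compute_features(shifted, axis_series(shifted.eyes))
        np.testing.assert_allclose(got["VertDist"].values,
                                   base["VertDist"].values, atol=1e-9)

        scaled = transform_recording(rec, 0.0, np.zeros(2))
        for t in [*scaled.markers.values(), scaled.eyes.left, scaled.eyes.right]:
            t.xy *= 3.0
        got = fs.compute_features(scaled, axis_series(scaled.eyes))
        np.testing.assert_allclose(got["VertDist"].values,
                                   3.0 * base["VertDist"].values, atol=1e-9)
        np.testing.assert_allclose(got["dist_left"].values,
                                   3.0 * base["dist_left"].values, atol=1e-9)
        np.testing.assert_allclose(got["Ratio"].values,
                                   base["Ratio"].values, atol=1e-9)
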