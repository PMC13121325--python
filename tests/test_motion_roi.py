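"""NCC, frame-selection rules, synthetic reference, registration, trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lafovkin.motion_roi import (
    Transform6DOF,
    apply_transform,
    motion_metric,
    ncc,
    rigid_register,
    select_reference_frame,
    select_start_frame,
    synthetic_reference,
    trim_roi,
)
from lafovkin.petdata import TAC, DynamicImage, FrameSchedule, LabelImage


class TestNcc:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.a = rng.uniform(0, 10, (8, 8, 8))

    def test_identity_and_negation(self):
        assert ncc(self.a, self.a) == pytest.approx(1.0)
        assert ncc(self.a, -self.a + 3.0) == pytest.approx(-1.0)

    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_positive_affine_invariance(self, scale, offset):
        assert ncc(self.a, scale * self.a + offset) == pytest.approx(
            1.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ncc(self.a, np.full_like(self.a, 2.0))

    def test_mask_restriction(self):
        b = self.a.copy()
        b[4:] = 0.0  # corrupt outside mask
        mask = np.zeros_like(self.a, bool)
        mask[:4] = True
        assert ncc(self.a, b, mask) == pytest.approx(1.0)


class TestStartFrame:
    def test_water_half_peak_rule(self):
        sched = FrameSchedule.from_durations([10.0] * 5)
        tac = TAC(sched, [10.0, 100.0, 80.0, 49.0, 30.0])
        assert select_start_frame(tac, "H2O") == 3

    def test_criterion_never_met_warns_and_returns_last(self):
        sched = FrameSchedule.from_durations([10.0] * 5)
        tac = TAC(sched, [1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning):
            assert select_start_frame(tac, "H2O") == 4

    def test_fdg_ncc_rule(self, rng):
        base = rng.uniform(0, 10, (6, 6, 6))
        frames = np.stack([rng.uniform(0, 10, base.shape),
                           rng.uniform(0, 10, base.shape),
                           base + rng.normal(0, 0.1, base.shape),
                           base], axis=3)
        img = DynamicImage(frames, np.ones(3),
                           FrameSchedule.from_durations([60.0] * 4))
        tac = TAC(img.schedule, [1.0, 2.0, 3.0, 4.0])
        got = select_start_frame(tac, "FDG", img=img, reference_index=3)
        assert got == 2

    def test_phantom_water_start_in_washout_window(self, water_phantom):
        img, seg, truth = water_phantom
        from lafovkin.petdata import roi_tac

        heart = roi_tac(img, seg, "myocardium")
        idx = select_start_frame(heart, "H2O")
        peak = np.argmax(heart.values)
        assert idx > peak
        assert heart.values[idx] < 0.5 * heart.values.max()


class TestReferenceFrame:
    def test_single_frame(self, rng):
        vol = rng.uniform(0, 1, (5, 5, 5, 1))
        img = DynamicImage(vol, np.ones(3),
                           FrameSchedule.from_durations([10.0]))
        assert select_reference_frame(img, rng.uniform(0, 1, (5, 5, 5))) == 0

    def test_exact_copy_wins(self, rng):
        ct = rng.uniform(0, 10, (6, 6, 6))
        frames = np.stack([rng.uniform(0, 10, ct.shape), ct,
                           rng.uniform(0, 10, ct.shape)], axis=3)
        img = DynamicImage(frames, np.ones(3),
                           FrameSchedule.from_durations([10.0] * 3))
        assert select_reference_frame(img, ct) == 1

    def test_tie_prefers_later_frame(self, rng):
        ct = rng.uniform(0, 10, (6, 6, 6))
        frames = np.stack([ct, ct], axis=3)
        img = DynamicImage(frames, np.ones(3),
                           FrameSchedule.from_durations([10.0] * 2))
        assert select_reference_frame(img, ct) == 1

    def test_phantom_fdg_reference_after_bolus(self, fdg_phantom):
        # once the bolus has passed, frames resemble anatomy more than the
        # blood-dominated early frames do
        img, seg, truth = fdg_phantom
        ct_like = (seg.labels > 0).astype(float)  # anatomy stand-in
        idx = select_reference_frame(img, ct_like)
        assert idx >= img.schedule.n_frames // 2
        assert idx > int(np.argmax(truth.input.values))


class TestSyntheticReference:
    def test_exact_painting_rule(self, water_schedule):
        labels = np.zeros((4, 4, 4), int)
        labels[:2] = 1
        seg = LabelImage(labels, {1: "organ"}, np.ones(3))
        vals = np.arange(water_schedule.n_frames, dtype=float)
        ref = synthetic_reference(seg, {1: TAC(water_schedule, vals)}, 2)
        assert np.all(ref[labels == 1] == 2.0)
        assert np.all(ref[labels == 0] == 0.0)

    def test_zero_tacs_give_zero_image(self, water_schedule):
        labels = np.ones((3, 3, 3), int)
        seg = LabelImage(labels, {1: "organ"}, np.ones(3))
        zeros = TAC(water_schedule, np.zeros(water_schedule.n_frames))
        assert np.all(synthetic_reference(seg, {"organ": zeros}, 0) == 0.0)

    def test_missing_tac_is_error(self, water_schedule):
        labels = np.ones((3, 3, 3), int)
        seg = LabelImage(labels, {1: "organ"}, np.ones(3))
        with pytest.raises(ValueError, match="organ"):
            synthetic_reference(seg, {}, 0)

    def test_identity_on_noiseless_phantom(self, water_phantom):
        img, seg, truth = water_phantom
        tacs = {info["label"]: info["tac"]
                for info in truth.organs.values()}
        for frame in (0, 7, 20):
            ref = synthetic_reference(seg, tacs, frame)
            inside = seg.labels > 0
            np.testing.assert_array_equal(ref[inside],
                                          img.voxels[..., frame][inside])


@pytest.fixture(scope="module")
def smooth_volume():
    """Smooth multi-blob volume for registration tests."""
    rng = np.random.default_rng(5)
    vol = np.zeros((32, 32, 32))
    idx = np.indices(vol.shape)
    for _ in range(6):
        c = rng.uniform(8, 24, 3)
        w = rng.uniform(3, 6)
        vol += rng.uniform(1, 3) * np.exp(
            -(((idx[0] - c[0]) ** 2 + (idx[1] - c[1]) ** 2
               + (idx[2] - c[2]) ** 2) / (2 * w ** 2)))
    return vol


class TestRigidRegister:
    VS = np.array([3.0, 3.0, 3.0])

    def test_identity_when_aligned(self, smooth_volume):
        res = rigid_register(smooth_volume, smooth_volume, self.VS)
        assert np.all(np.abs(res.transform.translation_mm) < 0.1)
        assert np.all(np.abs(res.transform.rotation_deg) < 0.1)

    def test_translation_recovery(self, smooth_volume):
        t = Transform6DOF([4.0, -2.0, 3.0], [0.0, 0.0, 0.0])
        fixed = apply_transform(smooth_volume, t, self.VS)
        res = rigid_register(smooth_volume, fixed, self.VS)
        assert res.improved
        np.testing.assert_allclose(res.transform.translation_mm,
                                   t.translation_mm, atol=0.5 * self.VS[0])

    def test_rotation_recovery(self, smooth_volume):
        t = Transform6DOF([0.0, 0.0, 0.0], [0.0, 0.0, 5.0])
        fixed = apply_transform(smooth_volume, t, self.VS)
        res = rigid_register(smooth_volume, fixed, self.VS)
        assert abs(res.transform.rotation_deg[2] - 5.0) <= 1.0

    def test_inverse_consistency(self, smooth_volume):
        t = Transform6DOF([3.0, 1.5, -2.0], [0.0, 0.0, 2.0])
        moved = apply_transform(smooth_volume, t, self.VS)
        res = rigid_register(moved, smooth_volume, self.VS)
        # composing the recovered transform with t is close to identity:
        # the tracked centre moves back to within half a voxel
        centre = (np.array(smooth_volume.shape) - 1) / 2 * self.VS
        p = centre + np.array([10.0, -5.0, 8.0])
        back = res.transform.apply_point(t.apply_point(p, centre), centre)
        assert np.linalg.norm(back - p) <= 0.5 * self.VS[0]


class TestTrimRoi:
    def test_zero_distance_identity(self, rng):
        mask = rng.random((10, 10, 10)) > 0.5
        np.testing.assert_array_equal(trim_roi(mask, 0.0, np.ones(3)), mask)

    def test_sphere_erosion_matches_analytic_volume(self):
        vs = np.array([2.0, 2.0, 2.0])
        idx = (np.indices((40, 40, 40)).T * vs).T
        centre = 39.0  # mm
        r = np.sqrt(((idx[0] - centre) ** 2 + (idx[1] - centre) ** 2
                     + (idx[2] - centre) ** 2))
        sphere = r <= 25.0
        eroded = trim_roi(sphere, 10.0, vs)
        got_mL = eroded.sum() * vs.prod() / 1000.0
        expected_mL = 4.0 / 3.0 * np.pi * 15.0 ** 3 / 1000.0
        assert got_mL == pytest.approx(expected_mL, rel=0.10)

    def test_slab_thinner_than_margin_errors(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[:, :, 5:10] = True  # 10 mm-thick slab at 2 mm voxels
        with pytest.raises(ValueError, match="slab"):
            trim_roi(mask, 10.0, np.array([2.0, 2.0, 2.0]), name="slab")

    def test_monotone_in_distance(self):
        vs = np.ones(3) * 2.0
        idx = (np.indices((30, 30, 30)).T * vs).T
        r = np.sqrt(((idx - 29.0) ** 2).sum(axis=0))
        sphere = r <= 20.0
        small = trim_roi(sphere, 4.0, vs)
        large = trim_roi(sphere, 8.0, vs)
        assert np.all(small[large])  # larger margin ⇒ subset


class TestMotionMetric:
    def _seg(self):
        labels = np.zeros((10, 10, 10), int)
        labels[2:5, 3:6, 4:7] = 1
        return LabelImage(labels, {1: "organ"}, np.array([2.0, 2.0, 2.0]))

    def test_identity_transforms_give_zero(self):
        traces = motion_metric(self._seg(), [Transform6DOF()] * 4)
        np.testing.assert_array_equal(traces["organ"].displacement_mm,
                                      np.zeros(4))

    def test_three_four_five_translation(self):
        t = Transform6DOF([3.0, 4.0, 0.0], [0.0, 0.0, 0.0])
        traces = motion_metric(self._seg(), [t] * 3)
        np.testing.assert_allclose(traces["organ"].displacement_mm,
                                   np.full(3, 5.0))

    def test_empty_roi_skipped_with_warning(self):
        labels = np.zeros((5, 5, 5), int)
        labels[0, 0, 0] = 1
        seg = LabelImage(labels, {1: "a", 2: "ghost"}, np.ones(3))
        with pytest.warns(UserWarning, match="ghost"):
            traces = motion_metric(seg, [Transform6DOF()])
        assert "ghost" not in traces and "a" in traces

    def test_phantom_injected_shift_recovered(self, water_phantom):
        _, seg, _ = water_phantom
        shift = Transform6DOF([2.0, -1.0, 2.5], [0.0, 0.0, 0.0])
        traces = motion_metric(seg, [Transform6DOF(), shift])
        mag = np.linalg.norm(shift.translation_mm)
        for trace in traces.values():
            assert trace.displacement_mm[0] == 0.0
            assert trace.displacement_mm[1] == pytest.approx(mag, abs=1e-9)
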