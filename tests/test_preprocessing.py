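import dataclasses

import numpy as np
import pytest

from tagspark.preprocessing import (
    MotionEstimate,
    OptimizerConfig,
    apply_translation,
    coregister_structural,
    correct_motion,
    estimate_motion,
    mattes_mi,
    normalized_mi,
    temporal_correct,
)
from tagspark.synthetic import PhantomSpec, make_dataset
from tagspark.volume_io import AcquisitionMeta, Volume3D, Volume4D


def _series(data, delays, rate=1.0):
    z = data.shape[1]
    meta = AcquisitionMeta(dz_um=1.0, volume_rate_hz=rate,
                           delay_map=np.asarray(delays, float),
                           rest_window=(0, 1))
    return Volume4D(data, meta)


@pytest.fixture(scope="module")
def motion_spec():
    return PhantomSpec(shape=(8, 32, 64, 64), motion_sd_px=1.0,
                       baseline_photons=8.0, delay_model="none", rest_frames=2)


class TestTemporalCorrect:
    def test_zero_delays_identity(self):
        data = np.random.default_rng(0).normal(size=(4, 3, 2, 2))
        out = temporal_correct(_series(data, [0, 0, 0]))
        np.testing.assert_array_equal(out.data, data)

    def test_constant_voxels_unchanged(self):
        data = np.ones((5, 3, 2, 2)) * np.array([1, 2, 3])[None, :, None, None]
        out = temporal_correct(_series(data, [0.0, 0.3, 0.6]))
        np.testing.assert_allclose(out.data, data)

    def test_hand_worked_interpolation_with_clamp(self):
        # voxel series [0,1,2,3] at T=1, delay 0.5, phase 0 -> [0, 0.5, 1.5, 2.5]
        data = np.arange(4.0)[:, None, None, None] * np.ones((4, 1, 1, 1))
        out = temporal_correct(_series(data, [0.5]))
        np.testing.assert_allclose(out.data[:, 0, 0, 0], [0.0, 0.5, 1.5, 2.5])

    def test_exact_on_linear_series_interior(self):
        # machine-precision exactness for voxels linear in time, interior frames
        t = np.arange(10.0)
        rng = np.random.default_rng(1)
        slopes = rng.normal(size=(4, 2, 2))
        offsets = rng.normal(size=(4, 2, 2))
        data = offsets + slopes * t[:, None, None, None]
        delays = [0.0, 0.2, 0.55, 0.9]
        out = temporal_correct(_series(data, delays))
        expected = offsets + slopes * (t[:, None, None, None] - np.asarray(delays)[None, :, None, None])
        np.testing.assert_allclose(out.data[1:-1], expected[1:-1], rtol=1e-12, atol=1e-12)

    def test_missing_delay_map_is_config_error(self):
        meta = AcquisitionMeta(dz_um=1.0, volume_rate_hz=1.0, rest_window=(0, 1))
        with pytest.raises(ValueError):
            temporal_correct(Volume4D(np.zeros((3, 2, 2, 2)), meta))


class TestMutualInformation:
    def test_self_information_positive_and_maximal(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64)).cumsum(axis=0)  # structured
        assert mattes_mi(img, img, 32) > 0
        assert mattes_mi(img, img, 32) >= mattes_mi(img, np.roll(img, 5, axis=1), 32)

    def test_independent_noise_has_negligible_information(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(128, 128))
        b = rng.uniform(size=(128, 128))
        assert mattes_mi(a, b, 32) <= 0.05

    def test_constant_image_defined_as_zero(self):
        assert mattes_mi(np.ones((8, 8)), np.random.default_rng(0).normal(size=(8, 8))) == 0.0

    def test_nmi_aligned_exceeds_misaligned(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(64, 64)).cumsum(axis=1)
        assert normalized_mi(img, img) > normalized_mi(img, np.roll(img, 10, axis=0))


class TestApplyTranslation:
    def test_zero_shift_identity(self):
        data = np.random.default_rng(0).normal(size=(3, 8, 8))
        np.testing.assert_array_equal(apply_translation(data, 0.0, 0.0), data)

    def test_integer_shift_equals_index_shift(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 100, size=(2, 8, 8)).astype(float)
        out = apply_translation(data, 2.0, 0.0)
        expected = np.zeros_like(data)
        expected[:, :, 2:] = data[:, :, :-2]
        np.testing.assert_allclose(out, expected)

    def test_near_inverse_on_smooth_volume(self, reference_dataset):
        # shift-and-unshift is not the identity (two bilinear resamplings
        # smooth once each); away from the border the residual is bounded by
        # the local curvature, so it is small in RMS and concentrated on the
        # ~1-px lateral edges of the structures
        smooth = reference_dataset.clean.data[0]
        out = apply_translation(apply_translation(smooth, 1.5, 0.0), -1.5, 0.0)
        interior = (slice(None), slice(2, -2), slice(2, -2))
        diff = out[interior] - smooth[interior]
        assert np.sqrt(np.mean(diff**2)) <= 0.02 * smooth.max()
        assert np.abs(diff).max() <= 0.25 * smooth.max()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            apply_translation(np.zeros((2, 4, 4)), np.nan, 0.0)


class TestEstimateMotion:
    def test_identity_when_aligned(self, motion_spec):
        ds = make_dataset(dataclasses.replace(motion_spec, motion_sd_px=0.0, seed=5))
        est = estimate_motion(ds.noisy.data[1], ds.noisy.data[1], OptimizerConfig(seed=1))
        assert abs(est.tx_px) <= 0.25 and abs(est.ty_px) <= 0.25

    def test_known_shift_recovered(self, motion_spec):
        ds = make_dataset(dataclasses.replace(motion_spec, motion_sd_px=0.0, seed=5))
        moved = apply_translation(ds.noisy.data[2], 3.0, -2.0)
        for seed in range(3):
            est = estimate_motion(ds.noisy.data[1], moved, OptimizerConfig(seed=seed))
            assert est.tx_px == pytest.approx(3.0, abs=0.5)
            assert est.ty_px == pytest.approx(-2.0, abs=0.5)

    def test_accepted_metric_log_is_monotone(self, motion_spec):
        ds = make_dataset(dataclasses.replace(motion_spec, seed=7))
        est = estimate_motion(ds.noisy.data[0], ds.noisy.data[3], OptimizerConfig(seed=2))
        for log in est.stage_logs:
            assert all(a <= b for a, b in zip(log, log[1:]))

    def test_more_iterations_never_worse_for_flat_search(self, motion_spec):
        # with a single pyramid stage the candidate sequence is a prefix, so
        # extra iterations can only improve the accepted metric
        ds = make_dataset(dataclasses.replace(motion_spec, motion_sd_px=0.0, seed=5))
        moved = apply_translation(ds.noisy.data[2], 1.0, -1.0)
        oc = OptimizerConfig(seed=3, pyramid_levels=1, max_iterations=100)
        short = estimate_motion(ds.noisy.data[1], moved, oc)
        long = estimate_motion(ds.noisy.data[1], moved,
                               dataclasses.replace(oc, max_iterations=200))
        assert long.metric_value >= short.metric_value

    def test_agrees_with_simpleitk(self, motion_spec):
        """Independent oracle: SimpleITK's MI + 1+1-ES translation registration."""
        sitk = pytest.importorskip("SimpleITK")
        ds = make_dataset(dataclasses.replace(motion_spec, motion_sd_px=0.0, seed=5))
        ref = ds.noisy.data[1].mean(axis=0)
        moved = apply_translation(ds.noisy.data[2], 2.0, -1.0).mean(axis=0)
        ours = estimate_motion(ds.noisy.data[1],
                               apply_translation(ds.noisy.data[2], 2.0, -1.0),
                               OptimizerConfig(seed=0))
        fixed = sitk.GetImageFromArray(ref.astype(np.float32))
        moving = sitk.GetImageFromArray(moved.astype(np.float32))
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(50)
        reg.SetOptimizerAsOnePlusOneEvolutionary(
            numberOfIterations=400, epsilon=1.5e-6, initialRadius=1.0, growthFactor=1.05,
            shrinkFactor=0.98, seed=1,
        )
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetInitialTransform(sitk.TranslationTransform(2), inPlace=True)
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        tform = reg.Execute(fixed, moving)
        # ITK maps fixed -> moving coordinates, so its offset is the motion
        ox, oy = tform.GetParameters()
        assert ours.tx_px == pytest.approx(ox, abs=0.5)
        assert ours.ty_px == pytest.approx(oy, abs=0.5)


class TestCorrectMotion:
    def test_motion_free_series_estimates_near_zero(self, motion_spec):
        ds = make_dataset(dataclasses.replace(motion_spec, motion_sd_px=0.0, seed=6,
                                              shape=(4, 32, 64, 64)))
        _, ests = correct_motion(ds.noisy, OptimizerConfig(seed=0))
        for e in ests:
            assert abs(e.tx_px) <= 0.25 and abs(e.ty_px) <= 0.25

    def test_injected_random_walk_recovered(self, motion_spec):
        ds = make_dataset(dataclasses.replace(motion_spec, seed=11))
        _, ests = correct_motion(ds.noisy, OptimizerConfig(seed=0))
        inj = ds.injected_motion
        residuals = [
            0.5 * (abs(e.tx_px - inj[t, 0]) + abs(e.ty_px - inj[t, 1]))
            for t, e in enumerate(ests)
        ]
        assert np.mean(residuals) <= 0.5

    def test_mean_mi_improves_after_correction(self, motion_spec):
        ds = make_dataset(dataclasses.replace(motion_spec, seed=42))
        corrected, _ = correct_motion(ds.noisy, OptimizerConfig(seed=0))
        def mean_mi(vol):
            ref = vol.data[0].mean(axis=0)
            return np.mean([
                mattes_mi(ref, vol.data[t].mean(axis=0)) for t in range(1, vol.n_frames)
            ])
        assert mean_mi(corrected) >= mean_mi(ds.noisy)

    def test_idempotent_within_quarter_pixel(self, motion_spec):
        ds = make_dataset(dataclasses.replace(motion_spec, seed=13, shape=(4, 32, 64, 64)))
        corrected, _ = correct_motion(ds.noisy, OptimizerConfig(seed=0))
        _, ests2 = correct_motion(corrected, OptimizerConfig(seed=1))
        for e in ests2[1:]:
            assert abs(e.tx_px) <= 0.25 and abs(e.ty_px) <= 0.25


class TestCoregisterStructural:
    def test_projection_against_itself(self, reference_dataset):
        func = reference_dataset.clean
        proj = func.data[: 4].mean(axis=0)
        structural = Volume3D(proj, func.meta)
        est = coregister_structural(func, structural, projection_seconds=0.4)
        assert abs(est.tx_px) <= 0.5 and abs(est.ty_px) <= 0.5

    def test_known_offset_recovered(self, reference_dataset):
        func = reference_dataset.clean
        proj = func.data[:4].mean(axis=0)
        structural = Volume3D(apply_translation(proj, 4.0, 4.0), func.meta)
        est = coregister_structural(func, structural, projection_seconds=0.4,
                                    oc=OptimizerConfig(seed=2))
        assert est.tx_px == pytest.approx(4.0, abs=1.0)
        assert est.ty_px == pytest.approx(4.0, abs=1.0)
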