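import numpy as np
import pytest

from tagspark.analysis_metrics import (
    CalciumTrace,
    classify_response,
    db_to_percent,
    dff,
    extract_trace,
    moving_average_reference,
    pairwise_correlation,
    pcc,
    psnr,
    snr,
    spike_peak_matches,
)
from tagspark.volume_io import AcquisitionMeta, LabelMask, Volume4D


def _series(data, dz=1.0):
    meta = AcquisitionMeta(dz_um=dz, volume_rate_hz=1.0, rest_window=(0, 2))
    return Volume4D(data, meta)


class TestExtractTrace:
    def test_single_voxel_mask(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 2, size=(5, 2, 3, 3))
        labels = np.zeros((2, 3, 3), dtype=np.int64)
        labels[1, 2, 0] = 1
        tr = extract_trace(_series(data), LabelMask(labels), 1)
        np.testing.assert_allclose(tr.values, data[:, 1, 2, 0])

    def test_all_ones_mask_gives_grand_sum(self):
        data = np.random.default_rng(1).uniform(size=(4, 2, 2, 2))
        labels = np.ones((2, 2, 2), dtype=np.int64)
        tr = extract_trace(_series(data), LabelMask(labels), 1)
        np.testing.assert_allclose(tr.values, data.sum(axis=(1, 2, 3)))

    def test_additivity_over_disjoint_rois(self):
        data = np.random.default_rng(2).uniform(size=(4, 3, 4, 4))
        labels = np.zeros((3, 4, 4), dtype=np.int64)
        labels[0, :2] = 1
        labels[2, 2:] = 2
        union = np.where(labels > 0, 3, 0).astype(np.int64)
        t1 = extract_trace(_series(data), LabelMask(labels), 1).values
        t2 = extract_trace(_series(data), LabelMask(labels), 2).values
        tu = extract_trace(_series(data), LabelMask(union), 3).values
        np.testing.assert_allclose(t1 + t2, tu)

    def test_empty_roi_rejected(self):
        data = np.zeros((2, 2, 2, 2))
        with pytest.raises(ValueError):
            extract_trace(_series(data), LabelMask(np.zeros((2, 2, 2), dtype=np.int64)), 1)

    def test_depth_is_weighted_centroid_times_dz(self):
        data = np.ones((2, 4, 2, 2))
        labels = np.zeros((4, 2, 2), dtype=np.int64)
        labels[1, 0, 0] = 1
        labels[3, 0, 0] = 1
        tr = extract_trace(_series(data, dz=0.5), LabelMask(labels), 1)
        assert tr.depth_um == pytest.approx(2.0 * 0.5)


class TestDff:
    def test_constant_trace_gives_zero(self):
        tr = CalciumTrace(1, np.full(6, 5.0))
        out = dff(tr, (0, 3))
        np.testing.assert_allclose(out.dff, 0.0)
        assert out.f0 == 5.0

    def test_doubling_baseline_gives_unity(self):
        values = np.array([2.0, 2.0, 4.0])
        out = dff(CalciumTrace(1, values), (0, 2))
        assert out.dff[2] == pytest.approx(1.0)

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(1, 3, size=10)
        a = dff(CalciumTrace(1, values), (0, 4)).dff
        b = dff(CalciumTrace(1, values * 7.3), (0, 4)).dff
        np.testing.assert_allclose(a, b)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            dff(CalciumTrace(1, np.zeros(5)), (0, 2))


class TestClassifyResponse:
    @pytest.mark.parametrize("mean_dff,label", [
        (0.3, "positive"), (-0.3, "negative"), (0.0, "neutral"),
        (0.2, "neutral"), (-0.2, "neutral"),  # boundary values are neutral
    ])
    def test_three_way_rule(self, mean_dff, label):
        tr = CalciumTrace(1, np.ones(4), dff=np.full(4, mean_dff), f0=1.0)
        assert classify_response(tr, (0, 4)).label == label

    def test_peak_statistic_option(self):
        d = np.array([0.0, -0.5, 0.1, 0.0])
        tr = CalciumTrace(1, np.ones(4), dff=d, f0=1.0)
        assert classify_response(tr, (0, 4), statistic="peak").label == "negative"


class TestPairwiseCorrelation:
    def _trace(self, rid, d, depth):
        return CalciumTrace(rid, np.ones_like(d), dff=d, f0=1.0, depth_um=depth)

    def test_identical_and_negated_traces(self):
        d = np.sin(np.linspace(0, 4, 20))
        traces = [self._trace(1, d, 1.0), self._trace(2, d, 1.0),
                  self._trace(3, -d, 1.0)]
        (bin0,) = pairwise_correlation(traces, [0.0, 2.0])
        assert bin0.matrix[0, 1] == pytest.approx(1.0)
        assert bin0.matrix[0, 2] == pytest.approx(-1.0)

    def test_constant_traces_excluded_not_zero_filled(self):
        d = np.sin(np.linspace(0, 4, 20))
        traces = [self._trace(1, d, 1.0), self._trace(2, d, 1.0),
                  self._trace(3, np.zeros(20), 1.0)]
        (bin0,) = pairwise_correlation(traces, [0.0, 2.0])
        assert np.isnan(bin0.matrix[0, 2])
        assert bin0.off_diagonal_mean == pytest.approx(1.0)


class TestImageQualityMetrics:
    def test_pcc_identities(self):
        a = np.random.default_rng(0).normal(size=(5, 5, 5))
        assert pcc(a, a) == pytest.approx(1.0)
        assert pcc(a, -a) == pytest.approx(-1.0)
        assert pcc(a, a + 3.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pcc(a, np.zeros_like(a))

    def test_psnr_closed_forms(self):
        ref = np.zeros((4, 4)); ref[0, 0] = 1.0
        assert psnr(ref, ref) == np.inf
        test = ref + 0.1
        assert psnr(ref, test, peak=1.0) == pytest.approx(20.0)
        test2 = ref + 0.05
        assert psnr(ref, test2, peak=1.0) - psnr(ref, test, peak=1.0) == pytest.approx(
            20 * np.log10(2), abs=1e-9)

    def test_snr_closed_form(self):
        fg = np.zeros((2, 5), dtype=bool); fg[0] = True  # 5 foreground voxels
        ref = np.ones((2, 5))
        sig = np.full((2, 5), 1.5)
        # 10*log10(5 / (5*0.25)) = 10*log10(4)
        assert snr(sig, ref, fg) == pytest.approx(10 * np.log10(4.0))
        assert snr(ref, ref, fg) == np.inf
        with pytest.raises(ValueError):
            snr(sig, np.zeros_like(ref), fg)

    def test_metrics_match_bruteforce_definitions(self):
        """pcc / psnr / loss agree with literal definitional recomputation."""
        from tagspark.denoiser import loss

        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(2.0, 1.0, size=(8, 8, 8))
            b = rng.normal(2.0, 1.0, size=(8, 8, 8))
            af, bf = a.ravel(), b.ravel()
            pcc_ref = (
                ((af - af.mean()) * (bf - bf.mean())).sum()
                / np.sqrt(((af - af.mean()) ** 2).sum() * ((bf - bf.mean()) ** 2).sum())
            )
            assert abs(pcc(a, b) - pcc_ref) <= 1e-10 * abs(pcc_ref)
            mse = ((a - b) ** 2).sum() / a.size
            psnr_ref = 10 * np.log10(a.max() ** 2 / mse)
            assert abs(psnr(a, b) - psnr_ref) <= 1e-10 * abs(psnr_ref)
            loss_ref = 0.5 * np.abs(a - b).sum() / a.size + 0.5 * ((a - b) ** 2).sum() / a.size
            assert abs(loss(a, b) - loss_ref) <= 1e-10 * abs(loss_ref)


class TestMovingAverage:
    def test_window_one_is_identity(self):
        data = np.random.default_rng(0).uniform(size=(5, 2, 2, 2))
        out = moving_average_reference(_series(data), n_frames=1)
        np.testing.assert_array_equal(out.data, data)

    def test_constant_series_unchanged(self):
        data = np.ones((8, 2, 2, 2)) * 3.0
        out = moving_average_reference(_series(data), n_frames=4)
        np.testing.assert_allclose(out.data, data)

    def test_noise_variance_shrinks_n_fold(self):
        # averaging n i.i.d. frames divides the residual variance by ~n
        n = 10
        rng = np.random.default_rng(5)
        var_ratios = []
        for _ in range(20):
            data = rng.normal(0.0, 1.0, size=(60, 2, 4, 4)) + 10.0
            out = moving_average_reference(_series(data), n_frames=n)
            interior = slice(n, 60 - n)
            var_ratios.append(
                np.var(data[interior] - 10.0) / np.var(out.data[interior] - 10.0)
            )
        se = np.std(var_ratios) / np.sqrt(len(var_ratios))
        assert abs(np.mean(var_ratios) - n) <= 3 * se + 0.5

    def test_bad_window(self):
        data = np.ones((4, 1, 1, 1))
        with pytest.raises(ValueError):
            moving_average_reference(_series(data), n_frames=0)


class TestDbToPercent:
    def test_zero_db_is_hundred_percent(self):
        assert db_to_percent(0.0) == pytest.approx(100.0)

    def test_published_conversions(self):
        assert db_to_percent(8.1, rounding="int") == 645.0
        assert db_to_percent(5.6, rounding="ten") == 360.0


class TestSpikePeakMatches:
    def test_identical_traces_match_fully(self):
        tr = np.zeros(20)
        events = [4, 10, 16]
        for f in events:
            tr[f:] += np.exp(-(np.arange(20 - f)) / 1.5)
        matched, total = spike_peak_matches(tr, tr, np.array(events))
        assert (matched, total) == (3, 3)

    def test_colliding_events_are_excluded(self):
        tr = np.zeros(20)
        for f in (4, 5, 12):
            tr[f:] += np.exp(-(np.arange(20 - f)) / 1.5)
        _, total = spike_peak_matches(tr, tr, np.array([4, 5, 12]))
        assert total == 1  # only the isolated event at 12 is evaluated

    def test_shifted_peak_is_a_mismatch(self):
        tr = np.zeros(20)
        tr[10:] = np.exp(-(np.arange(10)) / 1.5)
        shifted = np.roll(tr, 1)
        matched, total = spike_peak_matches(tr, shifted, np.array([10]))
        assert (matched, total) == (0, 1)
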