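import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oriquant as oq
from oriquant.errors import DegenerateDataError, EmptyMaskError
from oriquant.histogram import (
    IntensityHistogram,
    average_group,
    default_grid,
    mixture_curve,
    overlap_area,
)


def _hist_from_counts(counts, lo=0.0, hi=None, background_removed=True):
    counts = np.asarray(counts)
    hi = hi if hi is not None else float(len(counts))
    edges = np.linspace(lo, hi, len(counts) + 1)
    return IntensityHistogram(edges, counts, total_voxels=int(counts.sum()),
                              background_removed=background_removed)


class TestBuildHistogram:
    def test_counts_conserve_mask_size(self, default_phantom):
        _, vol, labels, _ = default_phantom
        hist = oq.build_histogram(vol, labels.var_mask)
        assert hist.retained == labels.var_mask.sum() == hist.total_voxels

    def test_two_values_split_evenly_into_two_bins(self):
        vox = np.zeros((1, 10, 10))
        vox[0, :5] = 1.0
        vox[0, 5:] = 3.0
        hist = oq.build_histogram(oq.IntensityVolume(vox), np.ones((1, 10, 10), bool), 2)
        np.testing.assert_array_equal(hist.counts, [50, 50])

    def test_phantom_var_histogram_is_bimodal(self, default_phantom):
        _, vol, labels, _ = default_phantom
        hist = oq.build_histogram(vol, labels.var_mask, 256)
        smooth = np.convolve(hist.counts, np.ones(5) / 5, mode="same")
        interior = smooth[3:-3]
        peaks = np.flatnonzero((interior > np.roll(interior, 1)) &
                               (interior >= np.roll(interior, -1)) &
                               (interior > 0.1 * interior.max()))
        assert len(peaks) >= 2

    def test_empty_mask_and_constant_values_rejected(self):
        vol = oq.IntensityVolume(np.ones((2, 2, 2)))
        with pytest.raises(EmptyMaskError):
            oq.build_histogram(vol, np.zeros((2, 2, 2), bool))
        with pytest.raises(DegenerateDataError):
            oq.build_histogram(vol, np.ones((2, 2, 2), bool))


class TestRemoveBackground:
    def test_zero_cutoff_changes_only_the_flag(self, default_phantom):
        _, vol, labels, _ = default_phantom
        hist = oq.build_histogram(vol, labels.var_mask)
        out = oq.remove_background(hist, 0.0)
        assert out.background_removed
        np.testing.assert_array_equal(out.counts, hist.counts)

    def test_cutoff_above_background_mode_retains_tissue(self):
        # histogram over the whole phantom: background plus tissue
        spec = oq.PhantomSpec(rng_seed=4)
        vol, labels, _ = oq.generate_heart_phantom(spec)
        mask = np.ones(vol.shape, bool)
        hist = oq.build_histogram(vol, mask, 512)
        cutoff = spec.background_level + 3 * spec.background_sigma
        out = oq.remove_background(hist, cutoff)
        tissue = (labels.labels > 0) & ~labels.mask(oq.LABEL_LUMEN)
        assert out.retained == pytest.approx(tissue.sum(), rel=0.01)

    def test_cutoff_above_all_data_rejected(self, default_phantom):
        _, vol, labels, _ = default_phantom
        hist = oq.build_histogram(vol, labels.var_mask)
        with pytest.raises(DegenerateDataError):
            oq.remove_background(hist, float(hist.bin_edges[-1]) + 1)

    def test_quantile_mode_drops_requested_mass(self, default_phantom):
        _, vol, labels, _ = default_phantom
        hist = oq.build_histogram(vol, labels.var_mask)
        out = oq.remove_background(hist, 0.05, mode="quantile")
        assert out.retained <= hist.retained
        assert out.retained >= 0.93 * hist.retained


class TestTrimFoot:
    def test_hand_built_ten_bin_oracle_keeps_six_central_bins(self):
        counts = [1, 2, 50_000, 100_000, 200_000, 150_000, 100_000, 50_000, 2, 1]
        out = oq.trim_foot(_hist_from_counts(counts), 2e-5)
        np.testing.assert_array_equal(out.counts, counts[2:8])
        assert out.discarded_foot == 6
        np.testing.assert_allclose(out.bin_edges, np.arange(2.0, 9.0))

    def test_all_bins_above_threshold_unchanged(self):
        counts = [100, 200, 300, 200]
        out = oq.trim_foot(_hist_from_counts(counts), 2e-5)
        np.testing.assert_array_equal(out.counts, counts)

    def test_zero_threshold_unchanged(self):
        counts = [1, 100, 1]
        out = oq.trim_foot(_hist_from_counts(counts), 0.0 + 1e-300)
        np.testing.assert_array_equal(out.counts, counts)

    def test_requires_background_stage_first(self):
        hist = _hist_from_counts([1, 2, 3], background_removed=False)
        with pytest.raises(ValueError):
            oq.trim_foot(hist)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=4, max_size=64))
    def test_conservation_counts_plus_discarded(self, counts):
        if sum(counts) == 0:
            return
        hist = _hist_from_counts(counts)
        try:
            out = oq.trim_foot(hist, 2e-3)
        except DegenerateDataError:
            return
        assert out.retained + out.discarded_foot == hist.retained


class TestNormalizeRange:
    def _trimmed(self, counts, lo=10.0, hi=20.0):
        h = _hist_from_counts(counts, lo, hi)
        return oq.trim_foot(h, 1e-12)

    def test_frequencies_sum_to_one(self):
        freq = oq.normalize_range(self._trimmed([5, 10, 20, 10]))
        assert freq.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unit_range_input_keeps_centers(self):
        trimmed = self._trimmed([5, 10, 20, 10], lo=0.0, hi=1.0)
        freq = oq.normalize_range(trimmed)
        np.testing.assert_allclose(freq.bin_centers, trimmed.bin_centers)

    def test_single_retained_bin_rejected(self):
        h = _hist_from_counts([1000])
        h = oq.trim_foot(h, 1e-12)
        with pytest.raises(DegenerateDataError):
            oq.normalize_range(h)

    def test_full_chain_affine_invariance(self, default_phantom):
        _, vol, labels, _ = default_phantom
        f1, _ = oq.run_chain(vol, labels.var_mask)
        rescaled = oq.IntensityVolume(vol.as_float() * 2.5 + 40.0)
        f2, _ = oq.run_chain(rescaled, labels.var_mask)
        np.testing.assert_allclose(f2.frequencies, f1.frequencies, atol=1e-9)
        np.testing.assert_allclose(f2.bin_centers, f1.bin_centers, atol=1e-9)


class TestAverageGroup:
    def test_single_histogram_is_identity(self):
        grid = default_grid(32)
        f = np.full(32, 1 / 32)
        h = oq.FrequencyHistogram(grid, f)
        out = average_group([h])
        np.testing.assert_allclose(out.frequencies, f)

    def test_two_identical_histograms_average_to_themselves(self):
        grid = default_grid(64)
        f = np.exp(-0.5 * ((grid - 0.5) / 0.1) ** 2)
        f /= f.sum()
        out = average_group([oq.FrequencyHistogram(grid, f)] * 2)
        assert out.n_hearts == 2
        np.testing.assert_allclose(out.frequencies, f)

    def test_two_disjoint_single_bin_histograms_average_half_half(self):
        grid = default_grid(256)
        a = oq.FrequencyHistogram([grid[10]], [1.0])
        b = oq.FrequencyHistogram([grid[200]], [1.0])
        out = average_group([a, b])
        assert out.frequencies[10] == pytest.approx(0.5)
        assert out.frequencies[200] == pytest.approx(0.5)
        assert out.frequencies.sum() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_group([])


class TestTwoGaussianFit:
    def test_exact_mixture_curve_recovered(self):
        x = default_grid(256)
        f = mixture_curve(x, (0.3, 0.7), (0.25, 0.65), (0.07, 0.10), 1 / 256)
        freq = oq.FrequencyHistogram(x, f / f.sum())
        fit = oq.fit_two_gaussians(freq, seed=0)
        assert abs(fit.w1 - 0.3) <= 0.01
        assert abs(fit.mu1 - 0.25) <= 0.01
        assert abs(fit.mu2 - 0.65) <= 0.01
        assert abs(fit.sigma2 - 0.10) <= 0.01
        assert fit.mean_residual <= 1e-6

    def test_weights_sum_to_one_and_components_ordered(self):
        from conftest import mixture_frequency_histogram

        fit = oq.fit_two_gaussians(mixture_frequency_histogram(3), seed=0)
        assert fit.w1 + fit.w2 == pytest.approx(1.0, abs=1e-9)
        assert fit.mu1 < fit.mu2
        assert fit.median_right == fit.mu2

    def test_unimodal_data_flagged_degenerate_via_overlap(self):
        x = default_grid(256)
        f = mixture_curve(x, (1.0,), (0.5,), (0.1,), 1 / 256)
        freq = oq.FrequencyHistogram(x, f / f.sum())
        fit = oq.fit_two_gaussians(freq, seed=0)
        assert fit.overlap_area >= 0.9 * min(fit.w1, fit.w2)
        assert fit.degenerate

    def test_too_few_bins_rejected(self):
        grid = default_grid(4)
        with pytest.raises(DegenerateDataError):
            oq.fit_two_gaussians(oq.FrequencyHistogram(grid, np.full(4, 0.25)), seed=0)


class TestFitMetrics:
    def test_identical_components_overlap_half(self):
        fit = oq.TwoGaussianFit(w1=0.5, mu1=0.5, sigma1=0.1, w2=0.5, mu2=0.5, sigma2=0.1)
        assert overlap_area(fit) == pytest.approx(0.5, abs=1e-4)

    def test_widely_separated_components_overlap_negligible(self):
        fit = oq.TwoGaussianFit(w1=0.5, mu1=0.2, sigma1=0.03, w2=0.5, mu2=0.8, sigma2=0.03)
        assert overlap_area(fit) <= 1e-3

    def test_overlap_bounded_by_smaller_surface(self):
        for w1 in (0.2, 0.5, 0.8):
            fit = oq.TwoGaussianFit(w1=w1, mu1=0.3, sigma1=0.08,
                                    w2=1 - w1, mu2=0.6, sigma2=0.1)
            assert 0 <= overlap_area(fit) <= min(fit.w1, fit.w2) + 1e-9

    def test_perfect_fit_zero_residual(self):
        x = default_grid(128)
        fit = oq.TwoGaussianFit(w1=0.4, mu1=0.3, sigma1=0.06, w2=0.6, mu2=0.7, sigma2=0.09)
        f = fit.curve(x, 1 / 128)
        # renormalize so the frequencies sum to exactly 1
        freq = oq.FrequencyHistogram(x, f / f.sum())
        out = oq.fit_metrics(fit, freq)
        assert out.mean_residual <= 1e-4


class TestModelComparison:
    def _noisy(self, weights, mus, sds, seed=3):
        x = default_grid(256)
        f = mixture_curve(x, weights, mus, sds, 1 / 256)
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0, 2e-5, f.size), 0, None)
        return oq.FrequencyHistogram(x, f / f.sum())

    def test_one_gaussian_data_selects_k1(self):
        res = oq.compare_gaussian_models(self._noisy((1.0,), (0.5,), (0.1,)), seed=0)
        assert res["chosen_k"] == 1

    def test_separated_two_mixture_selects_k2(self):
        res = oq.compare_gaussian_models(
            self._noisy((0.4, 0.6), (0.25, 0.7), (0.06, 0.08)), seed=0)
        assert res["chosen_k"] == 2

    def test_single_candidate_returned(self):
        res = oq.compare_gaussian_models(self._noisy((1.0,), (0.5,), (0.1,)),
                                         k_candidates=[2], seed=0)
        assert res["chosen_k"] == 2
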