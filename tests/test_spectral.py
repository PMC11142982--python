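import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oriquant as oq
from oriquant.errors import DegenerateDataError, EmptyMaskError, SpectrumError
from oriquant.spectral import (
    correct_dichroic_gaps,
    depth_profile,
    depth_redshift_trend,
    linear_unmix,
    mean_spectrum,
    nearest_channel,
    normalize_spectrum_at_peak,
    redshift_index,
)


def _axis():
    return np.arange(500.0, 731.0, 5.0)


class TestGapCorrection:
    def test_no_blocked_bands_is_identity(self):
        sp = oq.WavelengthSpectrum(_axis(), np.linspace(1, 3, _axis().size))
        out = correct_dichroic_gaps(sp)
        np.testing.assert_array_equal(out.intensities, sp.intensities)

    def test_linear_spectrum_interpolated_exactly(self):
        w = _axis()
        sp = oq.WavelengthSpectrum(w, w / 100.0, [(560.0, 570.0)])
        out = correct_dichroic_gaps(sp)
        np.testing.assert_allclose(out.intensities, w / 100.0, atol=1e-12)

    def test_edge_gap_filled_with_nearest_valid_value(self):
        w = _axis()
        intens = np.linspace(2.0, 4.0, w.size)
        sp = oq.WavelengthSpectrum(w, intens, [(495.0, 512.0)])
        out = correct_dichroic_gaps(sp)
        first_valid = np.flatnonzero(w > 512.0)[0]
        assert np.all(out.intensities[:first_valid] == intens[first_valid])

    def test_off_gap_points_untouched(self):
        w = _axis()
        rng = np.random.default_rng(0)
        intens = rng.random(w.size) + 1
        sp = oq.WavelengthSpectrum(w, intens, [(560.0, 570.0)])
        out = correct_dichroic_gaps(sp)
        outside = (w < 560) | (w > 570)
        np.testing.assert_array_equal(out.intensities[outside], intens[outside])

    def test_gap_covering_whole_axis_rejected(self):
        sp = oq.WavelengthSpectrum(_axis(), np.ones(_axis().size), [(400.0, 800.0)])
        with pytest.raises(SpectrumError):
            correct_dichroic_gaps(sp)


class TestPeakNormalization:
    def test_peak_channel_becomes_one(self):
        w = _axis()
        intens = 2000.0 * np.exp(-0.5 * ((w - 585) / 30) ** 2)
        out = normalize_spectrum_at_peak(oq.WavelengthSpectrum(w, intens))
        assert out.intensities[nearest_channel(w, 585.0)] == 1.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_idempotent_and_scale_invariant(self, scale):
        w = _axis()
        base = 1.0 + np.exp(-0.5 * ((w - 585) / 30) ** 2)
        once = normalize_spectrum_at_peak(oq.WavelengthSpectrum(w, base * scale))
        twice = normalize_spectrum_at_peak(once)
        unscaled = normalize_spectrum_at_peak(oq.WavelengthSpectrum(w, base))
        np.testing.assert_allclose(once.intensities, unscaled.intensities, rtol=1e-12)
        np.testing.assert_allclose(once.intensities, twice.intensities, rtol=1e-12)

    def test_zero_peak_intensity_rejected(self):
        w = _axis()
        with pytest.raises(SpectrumError):
            normalize_spectrum_at_peak(oq.WavelengthSpectrum(w, np.zeros(w.size)))

    def test_nearest_channel_tie_breaks_short(self):
        assert nearest_channel(np.array([580.0, 590.0]), 585.0) == 0


class TestMeanSpectrum:
    def test_single_voxel_mask_returns_that_spectrum(self, endmembers):
        spec = oq.PhantomSpec(shape=(2, 2, 2))
        field = np.random.default_rng(0).random((2, 2, 2, 2))
        sv, _ = oq.generate_spectral_phantom(spec, endmembers, field, ["carbmb", "metmb"])
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[1, 0, 1] = True
        np.testing.assert_allclose(mean_spectrum(sv, mask).intensities, sv.voxels[1, 0, 1])

    def test_half_and_half_mixture_averages_per_channel(self):
        w = _axis()
        a, b = np.full(w.size, 2.0), np.full(w.size, 6.0)
        vox = np.empty((2, 1, 1, w.size))
        vox[0, 0, 0], vox[1, 0, 0] = a, b
        sv = oq.SpectralVolume(vox, w)
        out = mean_spectrum(sv, np.ones((2, 1, 1), dtype=bool))
        np.testing.assert_allclose(out.intensities, (a + b) / 2)

    def test_empty_mask_rejected(self):
        sv = oq.SpectralVolume(np.ones((2, 2, 2, 4)), [500.0, 550.0, 600.0, 650.0])
        with pytest.raises(EmptyMaskError):
            mean_spectrum(sv, np.zeros((2, 2, 2), dtype=bool))


class TestLinearUnmix:
    def test_pure_endmember_voxel_gets_unit_coefficient(self, endmembers):
        A = endmembers.spectra["carbmb"]
        B = endmembers.spectra["metmb"]
        vox = np.broadcast_to(A.intensities, (1, 1, 1, len(A))).copy()
        res = linear_unmix(oq.SpectralVolume(vox, A.wavelengths), [A, B], ["a", "b"])
        np.testing.assert_allclose(res.coefficient_map("a"), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.coefficient_map("b"), 0.0, atol=1e-9)
        assert res.residual_norm.max() < 1e-9

    def test_noiseless_mixture_recovered_to_1e6(self, endmembers):
        spec = oq.PhantomSpec(shape=(3, 4, 4))
        field = np.zeros((3, 4, 4, 2))
        field[..., 0], field[..., 1] = 0.3, 0.7
        sv, _ = oq.generate_spectral_phantom(spec, endmembers, field, ["sham_like", "var_like"])
        res = linear_unmix(sv, [endmembers.spectra["sham_like"], endmembers.spectra["var_like"]])
        assert np.abs(res.coefficients - field).max() <= 1e-6

    def test_unmix_is_a_fixed_point_on_reconstructions(self, endmembers):
        names = ["carbmb", "oxymb", "metmb"]
        ems = [endmembers.spectra[n] for n in names]
        rng = np.random.default_rng(1)
        field = rng.random((2, 3, 3, 3))
        spec = oq.PhantomSpec(shape=(2, 3, 3))
        sv, _ = oq.generate_spectral_phantom(spec, endmembers, field, names)
        first = linear_unmix(sv, ems, names)
        recon = first.coefficients @ endmembers.matrix(names).T
        second = linear_unmix(oq.SpectralVolume(recon, endmembers.wavelengths), ems, names)
        np.testing.assert_allclose(second.coefficients, first.coefficients, atol=1e-8)

    def test_negative_direction_voxel_clipped_and_matches_grid_oracle(self, endmembers):
        A = endmembers.spectra["sham_like"].intensities
        B = endmembers.spectra["var_like"].intensities
        y = np.clip(1.2 * B - 0.5 * A, 0.0, None)  # pulls the A coefficient negative
        sv = oq.SpectralVolume(y.reshape(1, 1, 1, -1), endmembers.wavelengths)
        res = linear_unmix(sv, [endmembers.spectra["sham_like"], endmembers.spectra["var_like"]])
        c = res.coefficients[0, 0, 0]
        assert np.all(c >= 0)
        assert res.residual_norm[0, 0, 0] > 0
        # coarse-to-fine brute-force search over the coefficient plane
        M = np.column_stack([A, B])
        best = np.zeros(2)
        lo, hi, step = np.zeros(2), np.full(2, 2.0), 0.02
        for _ in range(3):
            g0 = np.arange(lo[0], hi[0] + step, step)
            g1 = np.arange(lo[1], hi[1] + step, step)
            G0, G1 = np.meshgrid(g0, g1, indexing="ij")
            C = np.stack([G0.ravel(), G1.ravel()], axis=1)
            rss = ((C @ M.T - y) ** 2).sum(axis=1)
            best = C[np.argmin(rss)]
            lo, hi, step = np.maximum(best - 2 * step, 0), best + 2 * step, step / 10
        assert np.abs(c - best).max() <= 1e-3

    def test_noise_ladder_rmse_monotone(self, endmembers):
        names = ["sham_like", "var_like"]
        ems = [endmembers.spectra[n] for n in names]
        spec = oq.PhantomSpec(shape=(4, 8, 8))
        field = np.zeros((4, 8, 8, 2))
        field[..., 0], field[..., 1] = 0.4, 0.6
        rmses = []
        for sigma in (0.05, 0.01, 0.001):
            sv, _ = oq.generate_spectral_phantom(spec, endmembers, field, names,
                                                 noise_sigma=sigma, seed=7)
            res = linear_unmix(sv, ems, names)
            rmses.append(float(np.sqrt(((res.coefficients - field) ** 2).mean())))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_rank_deficient_endmembers_rejected(self, endmembers):
        A = endmembers.spectra["carbmb"]
        twiceA = oq.WavelengthSpectrum(A.wavelengths, 2 * A.intensities)
        sv = oq.SpectralVolume(np.ones((1, 1, 1, len(A))), A.wavelengths)
        with pytest.raises(DegenerateDataError):
            linear_unmix(sv, [A, twiceA])


class TestRedshiftIndex:
    def test_flat_unit_spectrum_has_index_one(self):
        w = _axis()
        assert redshift_index(oq.WavelengthSpectrum(w, np.ones(w.size))) == 1.0

    def test_metmb_index_exceeds_carbmb(self, endmembers):
        i_met = redshift_index(normalize_spectrum_at_peak(endmembers.spectra["metmb"]))
        i_carb = redshift_index(normalize_spectrum_at_peak(endmembers.spectra["carbmb"]))
        assert i_met > i_carb

    def test_scale_then_renormalize_leaves_index_unchanged(self, endmembers):
        sp = endmembers.spectra["metmb"]
        doubled = oq.WavelengthSpectrum(sp.wavelengths, 2 * sp.intensities)
        i1 = redshift_index(normalize_spectrum_at_peak(sp))
        i2 = redshift_index(normalize_spectrum_at_peak(doubled))
        assert i1 == pytest.approx(i2, rel=1e-12)

    def test_band_outside_axis_rejected(self):
        sp = oq.WavelengthSpectrum(np.arange(500.0, 560.0, 5.0), np.ones(12))
        with pytest.raises(SpectrumError):
            redshift_index(sp, band=(620.0, 660.0))


class TestDepthProfile:
    def _uniform_field(self, shape):
        field = np.zeros(shape + (1,))
        field[..., 0] = 1.0
        return field

    def test_single_slab_equals_whole_volume_mean(self, endmembers):
        spec = oq.PhantomSpec(shape=(8, 4, 4))
        sv, _ = oq.generate_spectral_phantom(spec, endmembers,
                                             self._uniform_field((8, 4, 4)), ["sham_like"])
        profiles = depth_profile(sv, slab_thickness=8)
        assert len(profiles) == 1
        whole = normalize_spectrum_at_peak(mean_spectrum(sv, np.ones((8, 4, 4), bool)))
        np.testing.assert_allclose(profiles[0][1].intensities, whole.intensities)

    def test_attenuation_on_red_shifts_with_depth(self, endmembers):
        spec = oq.PhantomSpec(shape=(32, 6, 6), depth_attenuation_per_um=0.002)
        sv, _ = oq.generate_spectral_phantom(spec, endmembers,
                                             self._uniform_field((32, 6, 6)), ["sham_like"])
        profiles = depth_profile(sv, slab_thickness=4)
        idx = [redshift_index(sp) for _, sp in profiles]
        assert np.all(np.diff(idx) > 0)

    def test_attenuation_off_shows_no_monotone_trend(self, endmembers):
        spec = oq.PhantomSpec(shape=(32, 6, 6), depth_attenuation_per_um=0.0)
        sv, _ = oq.generate_spectral_phantom(spec, endmembers,
                                             self._uniform_field((32, 6, 6)), ["sham_like"],
                                             noise_sigma=0.01, seed=5)
        rho, p = depth_redshift_trend(depth_profile(sv, slab_thickness=4),
                                      n_permutations=499, seed=1)
        assert p > 0.05

    def test_slab_thicker_than_extent_rejected(self, endmembers):
        spec = oq.PhantomSpec(shape=(4, 4, 4))
        sv, _ = oq.generate_spectral_phantom(spec, endmembers,
                                             self._uniform_field((4, 4, 4)), ["sham_like"])
        with pytest.raises(ValueError):
            depth_profile(sv, slab_thickness=5)
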