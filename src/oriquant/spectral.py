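"""Spectrum-level computations.

Dichroic-gap repair, 585 nm peak normalization, mask-restricted mean
spectra, per-voxel non-negative linear unmixing, the 620-660 nm red-shift
index and depth profiling of spectral stacks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.stats import spearmanr

from .errors import DegenerateDataError, EmptyMaskError, SpectrumError
from .types import SpectralVolume, WavelengthSpectrum


def _in_bands(wavelengths: np.ndarray, bands) -> np.ndarray:
    blocked = np.zeros(wavelengths.shape, dtype=bool)
    for lo, hi in bands:
        blocked |= (wavelengths >= lo) & (wavelengths <= hi)
    return blocked


def correct_dichroic_gaps(spectrum: WavelengthSpectrum) -> WavelengthSpectrum:
    """Repair blocked dichroic-mirror bands by linear interpolation.

    Intensities inside every blocked band are replaced by linear
    interpolation between the nearest valid neighbours; gaps touching an
    axis edge are filled with the nearest valid intensity. Points outside
    the gaps are returned unchanged and the repaired spectrum carries no
    blocked bands.
    """
    if not spectrum.blocked_bands:
        return WavelengthSpectrum(spectrum.wavelengths.copy(), spectrum.intensities.copy())
    blocked = _in_bands(spectrum.wavelengths, spectrum.blocked_bands)
    valid = ~blocked
    if not valid.any():
        raise SpectrumError("blocked bands cover the entire wavelength axis")
    repaired = spectrum.intensities.copy()
    repaired[blocked] = np.interp(
        spectrum.wavelengths[blocked],
        spectrum.wavelengths[valid],
        spectrum.intensities[valid],
    )
    return WavelengthSpectrum(spectrum.wavelengths.copy(), repaired)


def nearest_channel(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the channel nearest ``target_nm``; ties break toward the
    shorter wavelength (determinism on even grids)."""
    dist = np.abs(np.asarray(wavelengths, dtype=float) - target_nm)
    return int(np.argmin(dist))


def normalize_spectrum_at_peak(
    spectrum: WavelengthSpectrum, peak_wavelength_nm: float = 585.0
) -> WavelengthSpectrum:
    """Divide a spectrum by its intensity at the channel nearest the peak.

    After normalization the value at the peak channel is exactly 1; the
    operation is idempotent and invariant to positive global scaling.
    """
    idx = nearest_channel(spectrum.wavelengths, peak_wavelength_nm)
    spacing = np.min(np.diff(spectrum.wavelengths)) if len(spectrum) > 1 else np.inf
    if abs(spectrum.wavelengths[idx] - peak_wavelength_nm) > spacing:
        raise SpectrumError(
            f"no channel within one spacing of {peak_wavelength_nm} nm "
            f"(nearest is {spectrum.wavelengths[idx]} nm)"
        )
    peak = spectrum.intensities[idx]
    if peak <= 0:
        raise SpectrumError(f"zero or missing intensity at the {peak_wavelength_nm} nm channel")
    return WavelengthSpectrum(
        spectrum.wavelengths.copy(), spectrum.intensities / peak, list(spectrum.blocked_bands)
    )


def mean_spectrum(spectral_volume: SpectralVolume, mask: np.ndarray) -> WavelengthSpectrum:
    """Per-channel arithmetic mean spectrum over the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spectral_volume.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} != volume spatial shape {spectral_volume.spatial_shape}"
        )
    if not mask.any():
        raise EmptyMaskError("mean_spectrum requires a non-empty mask")
    vals = spectral_volume.voxels[mask].astype(np.float64, copy=False)
    return WavelengthSpectrum(spectral_volume.channel_wavelengths.copy(), vals.mean(axis=0))


@dataclass
class UnmixResult:
    """Per-voxel non-negative unmixing coefficients and residuals."""

    coefficients: np.ndarray  # (z, y, x, n_endmembers), all >= 0
    residual_norm: np.ndarray  # (z, y, x)
    endmember_names: list[str]

    def __post_init__(self) -> None:
        if self.coefficients.min() < -1e-12:
            raise ValueError("unmixed coefficients must be non-negative")
        if self.residual_norm.min() < 0:
            raise ValueError("residual norms must be non-negative")

    def coefficient_map(self, name: str) -> np.ndarray:
        return self.coefficients[..., self.endmember_names.index(name)]

    def classify(self) -> np.ndarray:
        """Arg-max class index per voxel (spectral segmentation map)."""
        return np.argmax(self.coefficients, axis=-1)


def linear_unmix(
    spectral_volume: SpectralVolume,
    endmembers: Sequence[WavelengthSpectrum],
    names: Sequence[str] | None = None,
) -> UnmixResult:
    """Per-voxel non-negative least-squares unmixing onto endmember spectra.

    Coefficients minimise the Euclidean residual subject to non-negativity;
    no sum-to-one closure is imposed (fluorescence scales with emitter
    concentration). Voxels whose unconstrained least-squares solution is
    already non-negative are solved in one vectorised pass; only the
    remainder runs the active-set NNLS solver.
    """
    ems = list(endmembers)
    if len(ems) < 2:
        raise ValueError("need at least two endmembers")
    axis = spectral_volume.channel_wavelengths
    for i, em in enumerate(ems):
        if not np.allclose(em.wavelengths, axis):
            raise SpectrumError(f"endmember {i} is not on the volume's wavelength axis")
    A = np.column_stack([em.intensities for em in ems])  # (C, K)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise DegenerateDataError("endmember matrix is rank-deficient")

    shape = spectral_volume.spatial_shape
    Y = spectral_volume.voxels.reshape(-1, A.shape[0]).astype(np.float64, copy=False)
    coef, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
    coef = coef.T  # (N, K)
    neg = (coef < -1e-12).any(axis=1)
    for i in np.flatnonzero(neg):
        coef[i], _ = nnls(A, Y[i])
    coef = np.clip(coef, 0.0, None)
    resid = np.linalg.norm(Y - coef @ A.T, axis=1)
    names = list(names) if names is not None else [f"endmember_{i}" for i in range(len(ems))]
    return UnmixResult(coef.reshape(shape + (A.shape[1],)), resid.reshape(shape), names)


def redshift_index(
    spectrum: WavelengthSpectrum, band: tuple[float, float] = (620.0, 660.0)
) -> float:
    """Mean normalized intensity over the red band (620-660 nm by default).

    The spectrum should be peak-normalized first, making the index a
    scale-free measure of the CarbMb-to-MetMb red shift.
    """
    lo, hi = band
    sel = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not sel.any():
        raise SpectrumError(f"no channels inside the band [{lo}, {hi}] nm")
    return float(spectrum.intensities[sel].mean())


def depth_profile(
    spectral_volume: SpectralVolume,
    axis: int = 0,
    slab_thickness: int = 4,
    voxel_size_um: float = 1.0,
    peak_wavelength_nm: float = 585.0,
) -> list[tuple[float, WavelengthSpectrum]]:
    """Peak-normalized mean spectrum per consecutive slab along an axis.

    Returns ``(mid_depth_um, spectrum)`` pairs; the trailing partial slab
    is kept when non-empty. A slab thickness exceeding the axis extent is
    an error; thickness equal to the extent yields the whole-volume mean.
    """
    extent = spectral_volume.spatial_shape[axis]
    if slab_thickness < 1 or slab_thickness > extent:
        raise ValueError(f"slab thickness {slab_thickness} outside 1..{extent}")
    vox = np.moveaxis(spectral_volume.voxels, axis, 0)
    out: list[tuple[float, WavelengthSpectrum]] = []
    for start in range(0, extent, slab_thickness):
        stop = min(start + slab_thickness, extent)
        mean = vox[start:stop].mean(axis=(0, 1, 2))
        sp = WavelengthSpectrum(spectral_volume.channel_wavelengths.copy(), mean)
        sp = normalize_spectrum_at_peak(sp, peak_wavelength_nm)
        out.append((((start + stop) / 2.0) * voxel_size_um, sp))
    return out


def depth_redshift_trend(
    profiles: Sequence[tuple[float, WavelengthSpectrum]],
    band: tuple[float, float] = (620.0, 660.0),
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman trend of the red-shift index with depth, with permutation p.

    Returns ``(rho, p_value)`` where the p-value is the two-sided
    permutation probability of an |rho| at least as large under random
    reshuffling of depths. Used as the control that attenuation-free
    volumes show no in-depth red shift.
    """
    depths = np.array([d for d, _ in profiles])
    idx = np.array([redshift_index(sp, band) for _, sp in profiles])
    if len(depths) < 3:
        raise ValueError("need at least 3 slabs for a trend test")
    rho = spearmanr(depths, idx).statistic
    rng = np.random.default_rng(seed)
    hits = 1  # include the observed ordering
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        r = spearmanr(depths, perm).statistic
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return float(rho), hits / (n_permutations + 1)
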