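"""Core domain containers for oxidation-reduction imaging (ORI) analysis.

Axis convention is (z, y, x), 0-based; the TIFF page index maps to z.
Voxel intensities keep their acquired dtype (uint8 / uint16 / float32) and
are promoted to floating point only inside computations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import SpectrumError

# Anatomical label codes shared by every label volume in the package.
LABEL_BACKGROUND = 0
LABEL_LV_WALL = 1
LABEL_RV = 2
LABEL_LUMEN = 3
LABEL_VAR = 4
LABEL_HEALTHY = 5

LABEL_MAP: dict[int, str] = {
    LABEL_BACKGROUND: "background",
    LABEL_LV_WALL: "lv_wall",
    LABEL_RV: "rv",
    LABEL_LUMEN: "lumen",
    LABEL_VAR: "var",
    LABEL_HEALTHY: "healthy",
}

#: Labels that together make up the left-ventricular wall. The VAR and the
#: healthy (dye-quenched) region are subdivisions of the wall.
LV_WALL_LABELS = (LABEL_LV_WALL, LABEL_VAR, LABEL_HEALTHY)


@dataclass
class IntensityVolume:
    """A 3D scalar fluorescence volume with physical voxel size.

    Parameters
    ----------
    voxels
        3D array (z, y, x) of non-negative, finite intensities in arbitrary
        fluorescence units.
    voxel_size
        Physical voxel edge lengths ``(z, y, x)`` in micrometres. Defaults
        to isotropic 1 um when the acquisition metadata is absent.
    channel_meta
        Free-form acquisition metadata, e.g. ``{"excitation_nm": 633,
        "emission": ">650 nm longpass"}``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z,y,x), got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError(f"all voxel dimensions must be >= 1, got {self.voxels.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        vals = self.voxels
        if np.issubdtype(vals.dtype, np.floating):
            if not np.all(np.isfinite(vals)):
                raise ValueError("voxel values must be finite")
        if vals.size and float(vals.min()) < 0:
            raise ValueError("voxel values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_size
        return z * y * x

    def as_float(self) -> np.ndarray:
        """Voxels promoted to float64 for computation (raw data untouched)."""
        return self.voxels.astype(np.float64, copy=False)


@dataclass
class LabelVolume:
    """Per-voxel anatomical labels on the same grid as a parent volume."""

    labels: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(LABEL_MAP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z,y,x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        present = np.unique(self.labels)
        unknown = set(int(v) for v in present) - set(self.label_map)
        if unknown:
            raise ValueError(f"label values {sorted(unknown)} missing from label_map")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given label codes."""
        return np.isin(self.labels, codes)

    @property
    def lv_wall_mask(self) -> np.ndarray:
        return self.mask(*LV_WALL_LABELS)

    @property
    def var_mask(self) -> np.ndarray:
        return self.mask(LABEL_VAR)


@dataclass
class OxidationMask:
    """Boolean grid of voxels classified as oxidized (MetMb-like signal)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z,y,x)")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class WavelengthSpectrum:
    """Emission intensity versus wavelength for one sample or region.

    ``blocked_bands`` lists [lo, hi] nm intervals carrying no valid signal
    (dichroic-mirror gaps); they are repaired by
    :func:`oriquant.spectral.correct_dichroic_gaps`.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    blocked_bands: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumError("wavelengths and intensities must be 1D")
        if self.wavelengths.size != self.intensities.size:
            raise SpectrumError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumError("intensities must be finite")
        self.blocked_bands = [(float(lo), float(hi)) for lo, hi in self.blocked_bands]
        for lo, hi in self.blocked_bands:
            if hi <= lo:
                raise SpectrumError(f"blocked band [{lo}, {hi}] is empty")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class SpectralVolume:
    """4D grid (z, y, x, channel) with one emission wavelength per channel."""

    voxels: np.ndarray
    channel_wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.channel_wavelengths = np.asarray(self.channel_wavelengths, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError("spectral voxels must be 4D (z,y,x,channel)")
        if self.voxels.shape[3] != self.channel_wavelengths.size:
            raise ValueError(
                f"channel count {self.voxels.shape[3]} != "
                f"{self.channel_wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.channel_wavelengths) <= 0):
            raise ValueError("channel wavelengths must be strictly increasing")
        if self.voxels.size and float(self.voxels.min()) < 0:
            raise ValueError("spectral voxel values must be >= 0")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[3]


#: Emission wavelengths (nm) of the dichroic mirrors whose reflection bands
#: leave gaps in spectral-detector acquisitions.
DICHROIC_LINES_NM = (405.0, 488.0, 565.0, 647.0)


@dataclass
class RunConfig:
    """Run-wide constants of the quantification pipeline.

    Attributes
    ----------
    bin_count
        Number of equal-width intensity histogram bins (default 256).
    background_cutoff
        Low-intensity cutoff deleting background voxels from the histogram;
        interpreted per ``background_cutoff_mode`` (absolute intensity or a
        quantile of the masked voxels). Default 0 = no background deletion.
    foot_threshold_fraction
        Relative per-bin frequency below which the feet of the distribution
        are trimmed; default 2e-5 (i.e. 0.002 %).
    oxidation_threshold
        Normalized-intensity threshold above which a VAR voxel counts as
        oxidized; default 0.485 (48.5 % of the maximal intensity).
    peak_wavelength_nm
        Wavelength of the emission peak used for spectrum normalization
        (default 585 nm).
    redshift_band_nm
        Band over which the red-shift index averages the normalized
        intensity (default 620-660 nm).
    blocked_band_halfwidth_nm
        Half-width of the blocked band around each dichroic line.
    """

    bin_count: int = 256
    background_cutoff: float = 0.0
    background_cutoff_mode: str = "absolute"  # or "quantile"
    foot_threshold_fraction: float = 2e-5
    oxidation_threshold: float = 0.485
    peak_wavelength_nm: float = 585.0
    redshift_band_nm: tuple[float, float] = (620.0, 660.0)
    blocked_band_halfwidth_nm: float = 10.0
    dichroic_lines_nm: tuple[float, ...] = DICHROIC_LINES_NM
    min_component_size: int = 64
    bootstrap_samples: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_count < 16:
            raise ValueError(f"bin_count must be >= 16, got {self.bin_count}")
        if not 0 < self.foot_threshold_fraction < 1:
            raise ValueError("foot_threshold_fraction must lie in (0, 1)")
        if not 0 < self.oxidation_threshold < 1:
            raise ValueError("oxidation_threshold must lie in (0, 1)")
        if self.background_cutoff_mode not in ("absolute", "quantile"):
            raise ValueError("background_cutoff_mode must be 'absolute' or 'quantile'")
        lo, hi = self.redshift_band_nm
        if hi <= lo:
            raise ValueError("redshift_band_nm must be an increasing interval")

    @property
    def blocked_bands(self) -> list[tuple[float, float]]:
        """Default dichroic gap intervals, one per mirror line."""
        h = self.blocked_band_halfwidth_nm
        return [(line - h, line + h) for line in self.dichroic_lines_nm]

    def to_dict(self) -> dict:
        return {
            "bin_count": self.bin_count,
            "background_cutoff": self.background_cutoff,
            "background_cutoff_mode": self.background_cutoff_mode,
            "foot_threshold_fraction": self.foot_threshold_fraction,
            "oxidation_threshold": self.oxidation_threshold,
            "peak_wavelength_nm": self.peak_wavelength_nm,
            "redshift_band_nm": list(self.redshift_band_nm),
            "blocked_band_halfwidth_nm": self.blocked_band_halfwidth_nm,
            "dichroic_lines_nm": list(self.dichroic_lines_nm),
            "min_component_size": self.min_component_size,
            "bootstrap_samples": self.bootstrap_samples,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "redshift_band_nm" in d:
            d["redshift_band_nm"] = tuple(d["redshift_band_nm"])
        if "dichroic_lines_nm" in d:
            d["dichroic_lines_nm"] = tuple(d["dichroic_lines_nm"])
        return cls(**d)
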