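"""Readers and writers for volumes, masks, spectra, configs and reports.

Volumes and label masks travel as multi-page grayscale TIFF (page index =
z), spectra and tabular results as UTF-8 CSV with a header row, nested fit
records as JSON, and run configuration as YAML. Round trips are bit-exact
for integer dtypes.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import NonGrayscaleError, SpectrumError, VolumeFormatError
from .types import IntensityVolume, LabelVolume, OxidationMask, RunConfig, WavelengthSpectrum


def read_volume(path, voxel_size=(1.0, 1.0, 1.0), channel_meta=None) -> IntensityVolume:
    """Read a multi-page grayscale TIFF stack as an :class:`IntensityVolume`.

    Pages become z-slices in page order. All pages must share one shape and
    dtype and carry a single sample per pixel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    pages_data = []
    with tifffile.TiffFile(path) as tf:
        first = tf.pages[0]
        ref_shape, ref_dtype = first.shape, first.dtype
        for i, page in enumerate(tf.pages):
            if page.samplesperpixel != 1 or len(page.shape) != 2:
                raise NonGrayscaleError(
                    f"page {i} of {path} is not single-channel grayscale "
                    f"(shape {page.shape}, {page.samplesperpixel} samples/pixel)"
                )
            if page.shape != ref_shape or page.dtype != ref_dtype:
                raise VolumeFormatError(
                    f"page {i} of {path} has shape {page.shape} ({page.dtype}), "
                    f"expected {ref_shape} ({ref_dtype})"
                )
            pages_data.append(page.asarray())
    voxels = np.stack(pages_data, axis=0)
    return IntensityVolume(voxels, voxel_size=voxel_size, channel_meta=dict(channel_meta or {}))


def write_volume(volume: IntensityVolume, path) -> Path:
    """Write an :class:`IntensityVolume` as a multi-page grayscale TIFF."""
    path = Path(path)
    tifffile.imwrite(path, volume.voxels, photometric="minisblack")
    return path


def read_labels(path) -> LabelVolume:
    """Read a uint8 label-mask TIFF using the standard label map."""
    vol = read_volume(path)
    return LabelVolume(vol.voxels.astype(np.int64))


def write_labels(labels: LabelVolume, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint8), photometric="minisblack")
    return path


def read_mask(path) -> OxidationMask:
    vol = read_volume(path)
    return OxidationMask(vol.voxels > 0)


def write_mask(mask: OxidationMask, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8), photometric="minisblack")
    return path


def read_spectra_table(path, blocked_bands=()) -> dict[str, WavelengthSpectrum]:
    """Read named spectra sharing one wavelength axis from a CSV table.

    The wavelength column is the one named ``wavelength`` (any case) or,
    failing that, the first column; every other column yields one spectrum
    keyed by its header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectra table not found: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectrumError(f"{path}: need a wavelength column and >=1 intensity column")
    wl_col = next((c for c in df.columns if str(c).lower() == "wavelength"), df.columns[0])
    wavelengths = df[wl_col].to_numpy(dtype=float)
    if np.any(np.diff(wavelengths) <= 0):
        raise SpectrumError(f"{path}: wavelengths must be strictly increasing")
    spectra: dict[str, WavelengthSpectrum] = {}
    for col in df.columns:
        if col == wl_col:
            continue
        intens = df[col].to_numpy(dtype=float)
        if np.any(intens < 0):
            raise SpectrumError(f"{path}: negative intensities in column {col!r}")
        spectra[str(col)] = WavelengthSpectrum(wavelengths, intens, list(blocked_bands))
    return spectra


def write_spectra_table(spectra: dict[str, WavelengthSpectrum], path) -> Path:
    """Write named spectra (common axis) as CSV: wavelength + one column each."""
    path = Path(path)
    names = list(spectra)
    axis = spectra[names[0]].wavelengths
    for name in names[1:]:
        if not np.array_equal(spectra[name].wavelengths, axis):
            raise SpectrumError("spectra must share one wavelength axis to be tabulated")
    df = pd.DataFrame({"wavelength": axis})
    for name in names:
        df[name] = spectra[name].intensities
    df.to_csv(path, index=False)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results, path, columns: Sequence[str] | None = None) -> Path:
    """Serialize pipeline results: CSV for record lists, JSON otherwise.

    A list of dicts/dataclasses (possibly empty, with ``columns`` naming the
    header) goes to CSV; a single record or nested mapping goes to JSON,
    chosen by the path suffix.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
    if not isinstance(results, (list, tuple)):
        raise TypeError("CSV reports need a list of records; use a .json path for nested records")
    records = [
        dataclasses.asdict(r) if dataclasses.is_dataclass(r) and not isinstance(r, type) else dict(r)
        for r in results
    ]
    if records:
        df = pd.DataFrame([_jsonable(r) for r in records])
    else:
        df = pd.DataFrame(columns=list(columns or []))
    df.to_csv(path, index=False)
    return path


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
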