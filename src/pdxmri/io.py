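"""NIfTI-1 readers/writers for volumes, dynamic series, masks and maps.

All spatial metadata is carried through the NIfTI affine: spacing on the
diagonal, origin in the translation column.  Round-tripping a volume
preserves values bit-exactly (data are stored as float64).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from pdxmri.datamodel import DynamicImageSeries, ImageVolume, ParameterMap, ROIMask


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _load(path: str) -> nib.Nifti1Image:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return nib.load(path)


def read_volume(path: str) -> ImageVolume:
    """Read a 3D NIfTI volume.

    A 4D payload is rejected explicitly (no silent squeeze), naming the
    offending dimensionality.
    """
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 3D volume, found {data.ndim}D data "
            f"with shape {data.shape}"
        )
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    origin = tuple(float(img.affine[i, 3]) for i in range(3))
    return ImageVolume(values=data, spacing=spacing, origin=origin)


def write_volume(vol: ImageVolume, path: str) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.spacing, vol.origin))
    nib.save(img, path)


def read_series(path: str, timestamps) -> DynamicImageSeries:
    """Read a 4D NIfTI (time on the last axis) into a dynamic series."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4D series, found {data.ndim}D data "
            f"with shape {data.shape}"
        )
    timestamps = np.asarray(timestamps, dtype=float)
    if data.shape[-1] != timestamps.size:
        raise FormatError(
            f"{path}: {data.shape[-1]} frames but {timestamps.size} timestamps"
        )
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    origin = tuple(float(img.affine[i, 3]) for i in range(3))
    frames = [
        ImageVolume(values=data[..., t], spacing=spacing, origin=origin)
        for t in range(data.shape[-1])
    ]
    return DynamicImageSeries(frames=frames, timestamps=timestamps)


def write_series(series: DynamicImageSeries, path: str) -> None:
    vol0 = series.frames[0]
    img = nib.Nifti1Image(
        series.as_array().astype(np.float64), _affine(vol0.spacing, vol0.origin)
    )
    nib.save(img, path)


def read_mask(path: str, label: str = "") -> ROIMask:
    """Read a binary mask volume; any nonzero voxel is in the ROI."""
    vol = read_volume(path)
    return ROIMask(mask=vol.values != 0, label=label or os.path.basename(path))


def write_mask(roi: ROIMask, path: str, spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(spacing, (0, 0, 0)))
    nib.save(img, path)


def read_map(path: str, name: str, units: str) -> ParameterMap:
    """Read a parameter map; NaN voxels are marked invalid."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D map, found {data.ndim}D")
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    return ParameterMap(
        name=name, values=data, valid=np.isfinite(data), units=units, spacing=spacing
    )


def write_map(pmap: ParameterMap, path: str) -> None:
    """Write a parameter map; invalid voxels are stored as NaN."""
    data = np.where(pmap.valid, pmap.values, np.nan)
    img = nib.Nifti1Image(data.astype(np.float64), _affine(pmap.spacing, (0, 0, 0)))
    nib.save(img, path)
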