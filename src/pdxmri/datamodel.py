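"""Core in-memory containers shared by every fitting stage.

Conventions: voxel indices are 0-based and row-major (C order); masks must
share their reference grid exactly — no resampling is performed anywhere in
the package, so inputs are required to be pre-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Raised when two grids expected to be voxel-aligned are not."""


class EmptyROIError(ValueError):
    """Raised when an ROI contains no usable voxels for a summary."""


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities, arbitrary units.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"ImageVolume requires a 3D grid, got {self.values.ndim}D "
                f"with shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageVolume values must all be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DynamicImageSeries:
    """An ordered stack of co-registered volumes with acquisition times.

    ``timestamps`` are seconds from the first frame and must be strictly
    increasing; every frame shares one grid (shape and spacing).
    """

    frames: list[ImageVolume]
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.frames) != self.timestamps.size:
            raise ValueError(
                f"{len(self.frames)} frames but {self.timestamps.size} timestamps"
            )
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        ref = self.frames[0]
        for i, f in enumerate(self.frames[1:], start=1):
            if f.shape != ref.shape or f.spacing != ref.spacing:
                raise GridMismatchError(
                    f"frame {i} grid {f.shape}/{f.spacing} differs from "
                    f"frame 0 grid {ref.shape}/{ref.spacing}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.frames[0].spacing

    def as_array(self) -> np.ndarray:
        """Stack frames into a 4D array with time on the last axis."""
        return np.stack([f.values for f in self.frames], axis=-1)


@dataclass
class ROIMask:
    """A binary region-of-interest aligned to a reference grid."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"ROI mask must be 3D, got {self.mask.ndim}D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_grid(self, shape: tuple[int, ...]) -> None:
        if self.mask.shape != tuple(shape):
            raise GridMismatchError(
                f"ROI '{self.label}' grid {self.mask.shape} does not match "
                f"reference grid {tuple(shape)}"
            )


@dataclass
class ParameterMap:
    """A per-voxel fitted quantity plus a fit-validity mask.

    ``values`` must be finite wherever ``valid`` is True; invalid voxels may
    hold NaN.  ``units`` is a non-empty human-readable unit string.
    """

    name: str
    values: np.ndarray
    valid: np.ndarray
    units: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid).astype(bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid grids differ in shape")
        if not self.units:
            raise ValueError("units must be non-empty")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError(f"map '{self.name}' has non-finite values marked valid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class AcquisitionParams:
    """Sequence timing and encoding parameters for the supported protocols.

    Only the fields relevant to a given stage need to be set: ``b_values``
    for diffusion, ``tr_list`` for saturation recovery, ``frame_times`` for
    DCE and hyperpolarized acquisitions.
    """

    tr: float | None = None              # repetition time, s
    te: float | None = None              # echo time, s
    flip_deg: float | None = None        # flip angle, degrees
    b_values: np.ndarray | None = None   # s/mm^2
    tr_list: np.ndarray | None = None    # saturation-recovery TRs, s
    frame_times: np.ndarray | None = None  # dynamic frame schedule, s

    def __post_init__(self) -> None:
        if self.flip_deg is not None and not (0 < self.flip_deg <= 90):
            raise ValueError(f"flip angle must be in (0, 90], got {self.flip_deg}")
        if self.b_values is not None:
            self.b_values = np.asarray(self.b_values, dtype=float)
            if np.any(self.b_values < 0):
                raise ValueError("b-values must be non-negative")
            if not np.all(np.diff(self.b_values) > 0):
                raise ValueError("b-values must be strictly increasing")
            if self.b_values.size < 2:
                raise ValueError("need at least 2 b-values")
        for nm in ("tr_list", "frame_times"):
            v = getattr(self, nm)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, nm, v)
                if v.size < 2:
                    raise ValueError(f"{nm} needs at least 2 entries")


def extract_roi_values(pmap: ParameterMap, roi: ROIMask) -> np.ndarray:
    """Values of valid map voxels inside an ROI, in row-major order.

    The arithmetic mean of the returned vector is the "mean tumor" summary
    used throughout the package.  Raises :class:`EmptyROIError` if no voxel
    is both in the ROI and fit-valid.
    """
    roi.check_grid(pmap.shape)
    sel = roi.mask & pmap.valid
    if not sel.any():
        raise EmptyROIError(
            f"ROI '{roi.label}' contains no valid voxels of map '{pmap.name}'"
        )
    return pmap.values[sel]  # boolean indexing is row-major by construction


@dataclass
class GrowthSeries:
    """Longitudinal tumor volumes for one animal."""

    times_days: np.ndarray
    volumes_mm3: np.ndarray

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.volumes_mm3 = np.asarray(self.volumes_mm3, dtype=float)
        if self.times_days.size != self.volumes_mm3.size:
            raise ValueError("times and volumes differ in length")
        if self.times_days.size >= 2 and not np.all(np.diff(self.times_days) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes_mm3 <= 0):
            raise ValueError("volumes must be positive")


@dataclass
class HPDynamics:
    """Per-voxel hyperpolarized 13C metabolite time courses on one slice.

    ``pyr``, ``lac`` and ``urea`` are (nx, ny, nt) amplitude arrays on a
    uniform time grid (nominally TR 4.2 s, 15 frames, 8x8 in-plane).
    ``sigma`` is the magnitude-noise standard deviation once estimated.
    """

    pyr: np.ndarray
    lac: np.ndarray
    urea: np.ndarray
    timestamps: np.ndarray
    flip_deg: float = 10.0
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.pyr = np.asarray(self.pyr, dtype=float)
        self.lac = np.asarray(self.lac, dtype=float)
        self.urea = np.asarray(self.urea, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        shapes = {self.pyr.shape, self.lac.shape, self.urea.shape}
        if len(shapes) != 1:
            raise ValueError(f"metabolite arrays differ in shape: {shapes}")
        if self.pyr.shape[-1] != self.timestamps.size:
            raise ValueError("last axis must match the number of timestamps")
        dt = np.diff(self.timestamps)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("HP time grid must be uniform")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive once estimated")

    @property
    def tr(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)
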