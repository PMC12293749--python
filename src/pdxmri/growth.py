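"""Tumor volume and doubling-time estimation from longitudinal scans.

Doubling time T_d = ln 2 / b, where b is the ordinary least-squares slope of
ln(volume) against time in days — the linearized form of exponential growth
V(t) = V0 * 2^(t / T_d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from pdxmri.datamodel import GrowthSeries, ROIMask


def volume_from_mask(roi: ROIMask, spacing_mm) -> float:
    """Segmented volume in mm^3: voxel count times voxel volume."""
    spacing_mm = tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("spacing must be positive")
    n = roi.n_voxels
    if n == 0:
        warnings.warn(f"ROI '{roi.label}' is empty; volume is 0", stacklevel=2)
    return n * float(np.prod(spacing_mm))


@dataclass
class DoublingTimeResult:
    td_days: float     # NaN when non-growing
    slope_per_day: float
    growing: bool


def doubling_time(series: GrowthSeries, min_slope: float = 1e-12) -> DoublingTimeResult:
    """ln 2 over the OLS slope of log-volume vs time.

    A non-positive (or numerically zero) slope means the tumor is not
    growing exponentially; no finite doubling time exists and the result is
    flagged rather than returning a negative T_d.
    """
    t = series.times_days
    v = series.volumes_mm3
    if t.size < 2:
        raise ValueError("doubling time needs >= 2 time points")
    slope = float(np.polyfit(t, np.log(v), 1)[0])
    if slope <= min_slope:
        return DoublingTimeResult(td_days=float("nan"), slope_per_day=slope, growing=False)
    return DoublingTimeResult(td_days=float(np.log(2) / slope), slope_per_day=slope, growing=True)
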