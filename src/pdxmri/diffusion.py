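"""Voxel-wise apparent diffusion coefficient (ADC) from multi-b DWI.

Mono-exponential model S_b / S_0 = exp(-b * ADC), fitted log-linearly.  The
emulated protocol uses 7 b-values between 11 and 600 s/mm^2, a range low
enough that noise-floor bias is modest and the log-linear estimate is the
natural primary fit; a nonlinear fit serves as a test oracle only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pdxmri.datamodel import ParameterMap


@dataclass
class ADCFitResult:
    adc: float        # mm^2/s
    s0: float         # extrapolated b=0 signal, a.u.
    r_squared: float  # of the log-linear fit; NaN when degenerate
    valid: bool


def fit_adc(signals, b_values) -> ADCFitResult:
    """Least-squares fit of ln S = ln S0 - b * ADC.

    Voxels with any non-positive signal cannot be log-transformed and are
    returned invalid.  A perfectly flat signal gives ADC = 0 with the
    R-squared flagged NaN (zero variance to explain).
    """
    signals = np.asarray(signals, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if np.any(b_values < 0):
        raise ValueError("b-values must be non-negative")
    if np.unique(b_values).size < 2:
        raise ValueError("ADC fit needs >= 2 distinct b-values")
    if signals.shape != b_values.shape:
        raise ValueError("signals and b-values differ in length")
    if np.any(signals <= 0) or not np.all(np.isfinite(signals)):
        return ADCFitResult(np.nan, np.nan, np.nan, valid=False)

    logs = np.log(signals)
    if np.ptp(logs) == 0.0:
        # flat signal: decay is exactly zero, variance leaves R^2 undefined
        return ADCFitResult(adc=0.0, s0=float(signals[0]), r_squared=np.nan, valid=True)
    slope, intercept = np.polyfit(b_values, logs, 1)
    adc = float(-slope)
    s0 = float(np.exp(intercept))
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    resid = logs - (intercept + slope * b_values)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return ADCFitResult(adc=adc, s0=s0, r_squared=r2, valid=adc >= 0)


def fit_adc_map(series_4d: np.ndarray, b_values, spacing=(1.0, 1.0, 1.0)) -> ParameterMap:
    """Fit ADC voxel-by-voxel on a (nx, ny, nz, nb) DWI stack.

    The map carries mm^2/s internally; CSV summaries report the paper-style
    1e-3 mm^2/s scale (see :mod:`pdxmri.pipeline`).
    """
    series_4d = np.asarray(series_4d, dtype=float)
    nx, ny, nz, _ = series_4d.shape
    adc = np.full((nx, ny, nz), np.nan)
    valid = np.zeros((nx, ny, nz), dtype=bool)
    for idx in np.ndindex(nx, ny, nz):
        res = fit_adc(series_4d[idx], b_values)
        if res.valid and np.isfinite(res.adc):
            adc[idx] = res.adc
            valid[idx] = True
    return ParameterMap(name="adc", values=adc, valid=valid, units="mm^2/s", spacing=spacing)
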