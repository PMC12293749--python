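"""Hyperpolarized [1-13C]pyruvate / 13C-urea quantification.

Dynamic metabolite amplitudes (nominally an 8x8 grid sampled every 4.2 s for
15 frames at a 10 degree flip) are reduced to two study endpoints:

* ``k_PL`` — the apparent pyruvate-to-lactate conversion rate from an
  "inputless" single-compartment unidirectional fit: the measured pyruvate
  time course itself drives lactate production, so no arterial input model
  is assumed.
* ``urea_AUC`` — the area under the urea dynamic curve, normalized to a
  blood-vessel ROI, as a permeability-independent perfusion index.

Only voxels whose peak metabolite amplitude reaches a signal-to-noise ratio
of at least 3 (inclusive) enter any summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from pdxmri.datamodel import HPDynamics

DEFAULT_T1_LACTATE_S = 25.0  # fixed lactate relaxation constant for the fit
SNR_THRESHOLD = 3.0


class NormalizationError(ValueError):
    """Raised when the vessel reference for urea AUC is unusable."""


def estimate_noise(dyn: HPDynamics, background: np.ndarray) -> float:
    """Noise standard deviation from a signal-free background region.

    ``background`` is a boolean grid over the spatial axes, disjoint from
    tumor and vessel ROIs; all three metabolite channels contribute their
    background voxel-time samples.  A degenerate (zero-spread) background
    raises rather than returning sigma = 0.
    """
    background = np.asarray(background).astype(bool)
    if background.shape != dyn.pyr.shape[:-1]:
        raise ValueError("background grid does not match the spatial grid")
    samples = np.concatenate(
        [dyn.pyr[background].ravel(), dyn.lac[background].ravel(), dyn.urea[background].ravel()]
    )
    if samples.size < 8:
        raise ValueError("background must provide >= 8 voxel-time samples")
    sigma = float(np.std(samples))
    if sigma <= 0:
        raise ValueError("background has zero spread; cannot estimate noise")
    return sigma


def snr_mask(channel: np.ndarray, sigma: float, threshold: float = SNR_THRESHOLD) -> np.ndarray:
    """Per-voxel inclusion mask: peak-over-time amplitude / sigma >= threshold.

    Inclusive at equality, so a voxel peaking at exactly 3 sigma is kept.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    peak = np.max(np.asarray(channel, dtype=float), axis=-1)
    return peak / sigma >= threshold


# ---------------------------------------------------------------------------
# Inputless k_PL


def _drive_integrals(pyr: np.ndarray, tr: float, cos_a: float, t1_lac: float) -> np.ndarray:
    """Per-interval pyruvate drive integral_[t_n, t_n+1] P(tau) K(tau) dtau.

    Pyruvate is taken piecewise-linear between the post-excitation sample
    (P_n cos a) and the next pre-excitation sample P_{n+1}; the integrand
    carries the lactate relaxation kernel K = exp(-(t_{n+1}-tau)/T1L) so the
    interval solution is exact for linear P (the plain integral without the
    kernel overestimates k_PL by ~TR/(2 T1L)).
    """
    a = pyr[:-1] * cos_a
    b = pyr[1:]
    x = tr / t1_lac
    if x < 1e-4:
        # series in TR/T1L avoids cancellation as relaxation vanishes
        g1 = tr * (1.0 - x / 2.0 + x * x / 6.0)
        g2 = tr * tr * (0.5 - x / 6.0 + x * x / 24.0)
    else:
        tau = t1_lac
        e = np.exp(-x)
        g1 = tau * (1.0 - e)
        g2 = tau * (tr - tau * (1.0 - e))
    return a * g1 + (b - a) / tr * g2


def predict_lactate(
    pyr: np.ndarray,
    lac0: float,
    kpl: float,
    flip_deg: float,
    tr: float,
    t1_lac: float,
) -> np.ndarray:
    """Forward inter-frame lactate model used by the inputless fit.

    L(t_{n+1}) = L(t_n) cos(a) exp(-TR/T1L) + k_PL * (drive integral), with
    L anchored at the measured value on the first frame of the window.
    """
    c = np.cos(np.deg2rad(flip_deg))
    e = np.exp(-tr / t1_lac)
    drive = _drive_integrals(pyr, tr, c, t1_lac)
    out = np.empty(pyr.size)
    out[0] = lac0
    for n in range(pyr.size - 1):
        out[n + 1] = out[n] * c * e + kpl * drive[n]
    return out


@dataclass
class KPLFit:
    kpl: float            # s^-1
    residual_norm: float  # a.u.
    valid: bool


def fit_kpl_inputless(
    pyr,
    lac,
    flip_deg: float = 10.0,
    tr: float = 4.2,
    t1_lac: float = DEFAULT_T1_LACTATE_S,
) -> KPLFit:
    """Inputless single-compartment unidirectional k_PL fit for one voxel.

    The fit window starts at the pyruvate-maximum frame (bolus arrival is
    not modeled); k_PL >= 0 is estimated by nonlinear least squares on the
    lactate curve.  All-zero lactate with nonzero pyruvate legitimately
    yields k_PL = 0; all-zero pyruvate cannot constrain the model and the
    voxel is flagged invalid.
    """
    pyr = np.asarray(pyr, dtype=float)
    lac = np.asarray(lac, dtype=float)
    if pyr.shape != lac.shape or pyr.ndim != 1:
        raise ValueError("pyr and lac must be 1D time courses of equal length")
    if not pyr.any():
        return KPLFit(np.nan, np.nan, valid=False)
    i0 = int(np.argmax(pyr))
    p, l = pyr[i0:], lac[i0:]
    if p.size < 5:
        return KPLFit(np.nan, np.nan, valid=False)
    if not l.any():
        return KPLFit(0.0, 0.0, valid=True)

    target = l[1:]

    def resid(x):
        return predict_lactate(p, l[0], x[0], flip_deg, tr, t1_lac)[1:] - target

    # crude slope start: early lactate rise over pyruvate drive
    denom = float(np.trapezoid(p[:3], dx=tr))
    k0 = max((l[min(2, l.size - 1)] - l[0]) / denom, 1e-4) if denom > 0 else 1e-3
    sol = least_squares(resid, x0=[k0], bounds=([0.0], [10.0]), xtol=1e-14, ftol=1e-14)
    return KPLFit(
        kpl=float(sol.x[0]),
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        valid=bool(np.isfinite(sol.x[0])),
    )


@dataclass
class KPLResult:
    kpl_map: np.ndarray       # s^-1, NaN where unfit
    valid: np.ndarray
    tumor_mean_kpl: float     # mean of valid tumor voxels, s^-1
    n_voxels_used: int


def fit_kpl_map(
    dyn: HPDynamics,
    tumor_roi: np.ndarray,
    sigma: float,
    threshold: float = SNR_THRESHOLD,
    t1_lac: float = DEFAULT_T1_LACTATE_S,
) -> KPLResult:
    """Per-voxel k_PL over the tumor ROI, then the whole-tumor mean.

    A voxel is fitted only if both its pyruvate and lactate peaks pass the
    SNR rule; the tumor summary is the arithmetic mean of the passing fits.
    """
    tumor_roi = np.asarray(tumor_roi).astype(bool)
    include = tumor_roi & snr_mask(dyn.pyr, sigma, threshold) & snr_mask(dyn.lac, sigma, threshold)
    shape = dyn.pyr.shape[:-1]
    kpl = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for idx in np.argwhere(include):
        idx = tuple(idx)
        fit = fit_kpl_inputless(dyn.pyr[idx], dyn.lac[idx], dyn.flip_deg, dyn.tr, t1_lac)
        if fit.valid:
            kpl[idx] = fit.kpl
            valid[idx] = True
    n = int(valid.sum())
    mean = float(np.mean(kpl[valid])) if n else float("nan")
    return KPLResult(kpl_map=kpl, valid=valid, tumor_mean_kpl=mean, n_voxels_used=n)


# ---------------------------------------------------------------------------
# Urea perfusion AUC


@dataclass
class UreaAUCResult:
    urea_auc: float    # dimensionless, vessel-normalized
    vessel_auc: float  # a.u.
    n_tumor_voxels: int
    n_vessel_voxels: int


def urea_auc(
    dyn: HPDynamics,
    tumor_roi: np.ndarray,
    vessel_roi: np.ndarray,
    sigma: float | None = None,
    threshold: float = SNR_THRESHOLD,
) -> UreaAUCResult:
    """Vessel-normalized urea AUC: mean tumor trapezoid AUC / mean vessel AUC.

    With ``sigma`` given, the SNR >= threshold rule is applied to the urea
    channel in both ROIs first.  The result is dimensionless, so it is
    invariant to any global amplitude rescaling.
    """
    tumor_roi = np.asarray(tumor_roi).astype(bool)
    vessel_roi = np.asarray(vessel_roi).astype(bool)
    if sigma is not None:
        mask = snr_mask(dyn.urea, sigma, threshold)
        tumor_roi = tumor_roi & mask
        vessel_roi = vessel_roi & mask
    if not vessel_roi.any():
        raise NormalizationError("vessel ROI empty (after SNR masking)")
    if not tumor_roi.any():
        raise NormalizationError("tumor ROI empty (after SNR masking)")
    auc = np.trapezoid(dyn.urea, x=dyn.timestamps, axis=-1)
    vessel = float(np.mean(auc[vessel_roi]))
    if vessel <= 0:
        raise NormalizationError(f"vessel AUC is {vessel}; cannot normalize")
    tumor = float(np.mean(auc[tumor_roi]))
    return UreaAUCResult(
        urea_auc=tumor / vessel,
        vessel_auc=vessel,
        n_tumor_voxels=int(tumor_roi.sum()),
        n_vessel_voxels=int(vessel_roi.sum()),
    )
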