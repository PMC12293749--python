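"""Dynamic contrast-enhanced (DCE) MRI pharmacokinetics.

Signal-to-concentration conversion through the spoiled-gradient-echo (SPGR)
steady-state equation and a known contrast-agent relaxivity (Magnevist at
3 T: 3.8 mM^-1 s^-1), followed by extended-Tofts model fitting for Ktrans,
v_e and v_p, and a three-class enhancement-curve-shape classifier
(persistent / plateau / washout).

The arterial input function is a population biexponential (Weinmann form),
since preclinical studies of this kind rarely measure one; its parameters
are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class SPGRParams:
    """Spoiled-gradient-echo sequence timing."""

    tr: float          # s
    flip_deg: float    # degrees
    te: float = 0.0    # s; unused by the T1-weighted model but carried

    def __post_init__(self) -> None:
        if not (0 < self.flip_deg <= 90):
            raise ValueError(f"flip angle must be in (0, 90], got {self.flip_deg}")
        if self.tr <= 0:
            raise ValueError("TR must be positive")


@dataclass
class RelaxivityModel:
    """Longitudinal relaxivity r1 of the contrast agent, per mM per s."""

    r1: float = 3.8  # Magnevist at 3 T

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise ValueError("relaxivity must be positive")


#: Weinmann population plasma-clearance parameters for a gadolinium bolus:
#: amplitudes in kg/L, rates in 1/min, dose in mmol/kg -> Cp in mM.
WEINMANN_DEFAULTS = {"a1": 3.99, "a2": 4.78, "m1": 0.144, "m2": 0.0111, "dose": 0.1}


@dataclass
class AIF:
    """Plasma contrast concentration on the DCE time grid (mM)."""

    cp: np.ndarray
    timestamps: np.ndarray  # s
    form: str = "weinmann"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cp = np.asarray(self.cp, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.cp.shape != self.timestamps.shape:
            raise ValueError("cp and timestamps differ in length")
        if np.any(self.cp < 0) or not np.all(np.isfinite(self.cp)):
            raise ValueError("AIF concentrations must be finite and non-negative")


def population_aif(timestamps_s, injection_time_s: float, params: dict | None = None) -> AIF:
    """Biexponential population AIF, zero before the injection time."""
    p = dict(WEINMANN_DEFAULTS)
    if params:
        p.update(params)
    t = np.asarray(timestamps_s, dtype=float)
    tau_min = (t - injection_time_s) / 60.0
    cp = p["dose"] * (
        p["a1"] * np.exp(-p["m1"] * np.clip(tau_min, 0, None))
        + p["a2"] * np.exp(-p["m2"] * np.clip(tau_min, 0, None))
    )
    cp[tau_min < 0] = 0.0
    return AIF(cp=cp, timestamps=t, form="weinmann", params=p)


# ---------------------------------------------------------------------------
# SPGR signal model and inversion


def spgr_signal(r1: np.ndarray, m0: float | np.ndarray, spgr: SPGRParams) -> np.ndarray:
    """SPGR steady-state signal: M0 sin(a) (1 - E1) / (1 - cos(a) E1)."""
    a = np.deg2rad(spgr.flip_deg)
    e1 = np.exp(-spgr.tr * np.asarray(r1, dtype=float))
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def signal_to_concentration(
    signal_tc: np.ndarray,
    t10: float,
    spgr: SPGRParams,
    relax: RelaxivityModel,
    n_baseline_frames: int,
) -> np.ndarray:
    """Invert one voxel's SPGR signal time course to concentration (mM).

    The equilibrium-magnetization scale is pinned by the pre-injection
    baseline average together with the baseline T1 (T10); R1(t) then follows
    by inverting the signal equation, and
    C(t) = (R1(t) - R1,0) / r1.  Time points whose implied E1 falls outside
    (0, 1) — enhancement too strong for the model — return NaN.
    """
    s = np.asarray(signal_tc, dtype=float)
    if n_baseline_frames < 1:
        raise ValueError("need >= 1 pre-injection baseline frame")
    if not (np.isfinite(t10) and t10 > 0):
        raise ValueError("baseline T1 must be positive and finite")
    a = np.deg2rad(spgr.flip_deg)
    r10 = 1.0 / t10
    e10 = np.exp(-spgr.tr * r10)
    s_base = float(s[:n_baseline_frames].mean())
    if s_base <= 0:
        return np.full_like(s, np.nan)
    # M0 sin(a) pinned so the model reproduces the baseline signal at R10
    msin = s_base * (1.0 - np.cos(a) * e10) / (1.0 - e10)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (msin - s) / (msin - s * np.cos(a))
        conc = np.where(
            (e1 > 0) & (e1 < 1),
            (-np.log(np.clip(e1, 1e-300, None)) / spgr.tr - r10) / relax.r1,
            np.nan,
        )
    return conc


def concentration_map(
    series_4d: np.ndarray,
    t10_map_values: np.ndarray,
    t10_valid: np.ndarray,
    spgr: SPGRParams,
    relax: RelaxivityModel,
    n_baseline_frames: int,
) -> np.ndarray:
    """Voxel-wise signal-to-concentration on a 4D stack; skipped voxels are NaN."""
    series_4d = np.asarray(series_4d, dtype=float)
    out = np.full(series_4d.shape, np.nan)
    for idx in np.ndindex(series_4d.shape[:-1]):
        if not t10_valid[idx]:
            continue
        out[idx] = signal_to_concentration(
            series_4d[idx], float(t10_map_values[idx]), spgr, relax, n_baseline_frames
        )
    return out


# ---------------------------------------------------------------------------
# Extended Tofts model


@dataclass
class ToftsParams:
    ktrans: float         # inverse timestamp units (min^-1 when t is minutes)
    ve: float             # extravascular-extracellular volume fraction
    vp: float             # plasma volume fraction
    residual_norm: float
    valid: bool = True


def _exp_conv(cp: np.ndarray, t: np.ndarray, kep: float) -> np.ndarray:
    """integral_0^t Cp(tau) exp(-kep (t - tau)) dtau for piecewise-linear Cp.

    Evaluated exactly segment-by-segment on the (possibly non-uniform) grid,
    so sparse late frames introduce no quadrature error beyond the linear
    interpolation of Cp itself.
    """
    n = t.size
    out = np.zeros(n)
    acc = 0.0
    for j in range(n - 1):
        dt = t[j + 1] - t[j]
        a, b = cp[j], cp[j + 1]
        x = kep * dt
        decay = np.exp(-x)
        if x < 1e-4:
            # series in x avoids cancellation: g1 -> dt, g2 -> dt^2/2
            g1 = dt * (1.0 - x / 2.0 + x * x / 6.0)
            g2 = dt * dt * (0.5 - x / 6.0 + x * x / 24.0)
        else:
            g1 = (1.0 - decay) / kep
            g2 = dt / kep - (1.0 - decay) / kep**2
        seg = a * g1 + (b - a) / dt * g2
        acc = acc * decay + seg
        out[j + 1] = acc
    return out


def extended_tofts_curve(
    ktrans: float, ve: float, vp: float, aif_cp: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Forward model: Ct = Ktrans * Cp (x) exp(-Ktrans t / ve) + vp * Cp."""
    kep = ktrans / ve if ve > 0 else 0.0
    return ktrans * _exp_conv(aif_cp, t, kep) + vp * aif_cp


# Fixed multi-start list spanning the Ktrans-ve ridge (no RNG).  Values are in
# normalized time units (time grid scaled to [0, 1]), so they cover both the
# paper's 1e-4/min scale and ordinary tumor values once de-normalized.
_TOFTS_STARTS = [
    (1e-3, 0.05, 0.01),
    (0.1, 0.2, 0.05),
    (2.0, 0.5, 0.1),
]


def fit_extended_tofts(ct, aif: AIF, timestamps=None) -> ToftsParams:
    """Least-squares extended-Tofts fit of one tissue concentration curve.

    Time units are taken from ``timestamps`` (default: the AIF grid); the
    fitted Ktrans is in inverse those units, so passing minutes yields
    min^-1.  Internally the grid is normalized to [0, 1], which makes the
    optimizer path independent of the time unit (exact equivariance).
    Bounds: ve, vp in [0, 1]; Ktrans >= 0.  Three fixed starts guard the
    Ktrans/ve ridge; the best residual wins.
    """
    ct = np.asarray(ct, dtype=float)
    t = np.asarray(timestamps if timestamps is not None else aif.timestamps, dtype=float)
    cp = aif.cp
    if not np.all(np.isfinite(cp)):
        raise ValueError("AIF contains non-finite values")
    if ct.shape != t.shape or cp.shape != t.shape:
        raise ValueError("curve, AIF and timestamps must share one grid")
    keep = np.isfinite(ct)
    if keep.sum() < 4:
        return ToftsParams(np.nan, np.nan, np.nan, np.nan, valid=False)

    tmax = float(t[-1] - t[0])
    tn = (t - t[0]) / tmax  # dimensionless grid

    def resid(x):
        model = extended_tofts_curve(x[0], x[1], x[2], cp, tn)
        return (model - ct)[keep]

    best = None
    for start in _TOFTS_STARTS:
        try:
            sol = least_squares(
                resid,
                x0=np.array(start),
                bounds=([0.0, 1e-8, 0.0], [1e4, 1.0, 1.0]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=4000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return ToftsParams(np.nan, np.nan, np.nan, np.nan, valid=False)

    ktrans_n, ve, vp = best.x
    ktrans = float(ktrans_n / tmax)  # back to user time units
    rnorm = float(np.sqrt(2.0 * best.cost))
    valid = bool(ve + vp <= 1.0 + 1e-9)
    return ToftsParams(ktrans=ktrans, ve=float(ve), vp=float(vp),
                       residual_norm=rnorm, valid=valid)


# ---------------------------------------------------------------------------
# Enhancement-curve shape


TYPE_I = "type I persistent"
TYPE_II = "type II plateau"
TYPE_III = "type III washout"
UNCLASSIFIABLE = "unclassifiable"


def classify_enhancement(
    tc,
    timestamps,
    injection_time_s: float = 0.0,
    late_start_s: float = 120.0,
    rel_threshold: float = 0.10,
) -> str:
    """Classify an enhancement curve by its late-phase slope.

    A straight line is fitted to the curve from ``late_start_s`` after
    injection to the end; the fitted change over that window, relative to
    the post-injection peak, decides the class: rising beyond +10 % of peak
    -> type I (persistent), within +/-10 % -> type II (plateau, the pattern
    reported for these tumors: rapid uptake to a steady state by 2 min),
    falling below -10 % -> type III (washout).
    """
    tc = np.asarray(tc, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    post = t >= injection_time_s
    if post.sum() < 3:
        raise ValueError("need >= 3 post-injection frames")
    peak = np.nanmax(np.abs(tc[post]))
    if not np.isfinite(peak) or peak == 0:
        return UNCLASSIFIABLE
    late = t >= injection_time_s + late_start_s
    if late.sum() < 2:
        raise ValueError("late window has < 2 frames; extend the acquisition")
    tl, yl = t[late], tc[late]
    ok = np.isfinite(yl)
    slope = np.polyfit(tl[ok], yl[ok], 1)[0]
    rel_change = slope * (tl[-1] - tl[0]) / peak
    if rel_change > rel_threshold:
        return TYPE_I
    if rel_change < -rel_threshold:
        return TYPE_III
    return TYPE_II
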