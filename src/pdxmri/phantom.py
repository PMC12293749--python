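"""Digital-phantom generators with known ground truth for every modality.

Each ``simulate_*`` function is a pure function of its parameters and a
seed: same call, same bytes.  Independent RNG streams are derived per
modality from the master seed, so adding a modality never perturbs
another's data.  Truth values default to the physiologic ranges reported
for these tumors (ADC 0.6-1.4 x 1e-3 mm^2/s, k_PL 0.04-0.14 s^-1, Ktrans a
few 1e-4 min^-1, doubling times 3.5-11 days).

Noise physics: Rician on magnitude MR channels (DWI, saturation recovery,
hyperpolarized 13C), Gaussian on the high-SNR 1H DCE signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pdxmri.datamodel import GrowthSeries, HPDynamics
from pdxmri.dce import AIF, RelaxivityModel, SPGRParams, extended_tofts_curve, population_aif, spgr_signal

# Per-modality stream indices for SeedSequence-derived generators
_STREAMS = {"dwi": 1, "satrec": 2, "dce": 3, "hp": 4, "growth": 5, "sirm": 6}

#: Emulated 7-b diffusion schedule, s/mm^2 (11-600 range, evenly spaced).
DEFAULT_B_VALUES = np.array([11.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0])

#: Emulated 10-TR saturation-recovery schedule, s (log-spaced 369.5 ms - 5 s).
DEFAULT_TR_LIST = np.geomspace(0.3695, 5.0, 10)

#: Emulated DCE frame schedule, s: every 3 s for 1 min, then 1/min to 8 min.
DEFAULT_DCE_TIMES = np.concatenate([np.arange(0.0, 60.1, 3.0), np.arange(120.0, 480.1, 60.0)])

DEFAULT_HP_TR = 4.2       # s
DEFAULT_HP_FRAMES = 15
DEFAULT_HP_FLIP = 10.0    # degrees
DEFAULT_T1_PYR = 30.0     # s
DEFAULT_T1_LAC = 25.0     # s
DEFAULT_T1_UREA = 20.0    # s


def _rng(seed: int, modality: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[modality]]))


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, size=np.shape(signal))
    im = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.hypot(re, im)


@dataclass
class PhantomDataset:
    """A simulated acquisition plus its generating truth."""

    data: np.ndarray                  # last axis is time / b / TR
    truth: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# Static mapping modalities


def checkerboard_truth(shape=(8, 8, 1), low: float = 0.6e-3, high: float = 1.4e-3) -> np.ndarray:
    """A two-level truth map exercising the full physiologic range."""
    idx = np.indices(shape).sum(axis=0)
    return np.where(idx % 2 == 0, low, high)


def simulate_dwi(
    adc_truth: np.ndarray,
    b_values=DEFAULT_B_VALUES,
    s0: float = 100.0,
    snr: float = np.inf,
    seed: int = 0,
) -> PhantomDataset:
    """Mono-exponential DWI: S = S0 exp(-b ADC) + Rician noise at S0/snr."""
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    if snr <= 0:
        raise ValueError("snr must be positive")
    adc_truth = np.asarray(adc_truth, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    clean = s0 * np.exp(-adc_truth[..., None] * b_values)
    sigma = 0.0 if np.isinf(snr) else s0 / snr
    data = _rician(clean, sigma, _rng(seed, "dwi"))
    return PhantomDataset(
        data=data,
        truth={"adc": adc_truth, "s0": s0, "b_values": b_values, "sigma": sigma},
        seed=seed,
    )


def simulate_saturation_recovery(
    t1_truth: np.ndarray,
    tr_list=DEFAULT_TR_LIST,
    s0: float = 100.0,
    snr: float = np.inf,
    seed: int = 0,
) -> PhantomDataset:
    """Saturation recovery: S = S0 (1 - exp(-TR/T1)) + Rician noise."""
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    t1_truth = np.asarray(t1_truth, dtype=float)
    tr_list = np.asarray(tr_list, dtype=float)
    clean = s0 * (1.0 - np.exp(-tr_list / t1_truth[..., None]))
    sigma = 0.0 if np.isinf(snr) else s0 / snr
    data = _rician(clean, sigma, _rng(seed, "satrec"))
    return PhantomDataset(
        data=data,
        truth={"t1": t1_truth, "s0": s0, "tr_list": tr_list, "sigma": sigma},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# DCE


def simulate_dce(
    ktrans_truth: np.ndarray,   # min^-1
    ve_truth: np.ndarray,
    vp_truth: np.ndarray,
    t10_truth: np.ndarray,      # s
    spgr: SPGRParams | None = None,
    relax: RelaxivityModel | None = None,
    timestamps=DEFAULT_DCE_TIMES,
    n_baseline_frames: int = 3,
    aif_params: dict | None = None,
    m0: float = 1000.0,
    snr: float = np.inf,
    seed: int = 0,
) -> PhantomDataset:
    """Extended-Tofts tissue dynamics rendered through the SPGR signal model.

    Tissue concentration follows the extended Tofts forward model under a
    population biexponential AIF injected at the first post-baseline frame;
    T1(t) = 1/(R10 + r1 C(t)) sets the signal; Gaussian noise at
    baseline-signal/snr is added.
    """
    spgr = spgr or SPGRParams(tr=0.040, flip_deg=40.0, te=0.003)
    relax = relax or RelaxivityModel()
    ktrans_truth = np.asarray(ktrans_truth, dtype=float)
    ve_truth = np.asarray(ve_truth, dtype=float)
    vp_truth = np.asarray(vp_truth, dtype=float)
    t10_truth = np.asarray(t10_truth, dtype=float)
    if np.any(ve_truth + vp_truth > 1):
        raise ValueError("truth has ve + vp > 1")
    t = np.asarray(timestamps, dtype=float)
    inj = float(t[n_baseline_frames])
    aif = population_aif(t, inj, aif_params)
    t_min = t / 60.0

    shape = ktrans_truth.shape
    conc = np.zeros(shape + (t.size,))
    for idx in np.ndindex(shape):
        conc[idx] = extended_tofts_curve(
            float(ktrans_truth[idx]), float(ve_truth[idx]), float(vp_truth[idx]),
            aif.cp, t_min,
        )
    r1t = 1.0 / t10_truth[..., None] + relax.r1 * conc
    clean = spgr_signal(r1t, m0, spgr)
    if np.isinf(snr):
        data = clean
    else:
        base = float(clean[..., :n_baseline_frames].mean())
        data = clean + _rng(seed, "dce").normal(0.0, base / snr, size=clean.shape)
    return PhantomDataset(
        data=data,
        truth={
            "ktrans": ktrans_truth, "ve": ve_truth, "vp": vp_truth,
            "t10": t10_truth, "concentration": conc, "aif_cp": aif.cp,
            "timestamps": t, "injection_time_s": inj,
            "n_baseline_frames": n_baseline_frames, "m0": m0,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hyperpolarized 13C


def gamma_variate(t, amplitude: float, shape_k: float = 3.0, scale_s: float = 4.0):
    """Gamma-variate bolus input rate, peaking at (shape_k-1)*scale_s with height ``amplitude``."""
    t = np.clip(np.asarray(t, dtype=float), 0, None)
    peak = (shape_k - 1.0) * scale_s
    norm = peak ** (shape_k - 1.0) * np.exp(-peak / scale_s) if peak > 0 else 1.0
    return amplitude * t ** (shape_k - 1.0) * np.exp(-t / scale_s) / norm


def simulate_hp(
    kpl_truth: np.ndarray,            # s^-1, 0 outside tumor
    perfusion: np.ndarray | None = None,  # relative urea delivery, 1 = vessel
    delivery: np.ndarray | None = None,   # relative pyruvate delivery; 0 = signal-free
    bolus_amplitude: float = 50.0,
    bolus_shape: float = 3.0,
    bolus_scale_s: float = 4.0,
    t1_pyr: float = DEFAULT_T1_PYR,
    t1_lac: float = DEFAULT_T1_LAC,
    t1_urea: float = DEFAULT_T1_UREA,
    flip_deg: float = DEFAULT_HP_FLIP,
    tr: float = DEFAULT_HP_TR,
    n_frames: int = DEFAULT_HP_FRAMES,
    snr: float = np.inf,
    seed: int = 0,
    substeps: int = 100,
) -> tuple[PhantomDataset, HPDynamics]:
    """Two-site unidirectional exchange with T1 decay and RF losses.

    Longitudinal magnetizations are integrated on a fine grid (TR/substeps)
    between excitations: dP/dt = input - P (1/T1P + kPL),
    dL/dt = kPL P - L/T1L; at every TR both pools lose cos(flip) and the
    transverse observation is Mz sin(flip).  The urea channel sees the same
    bolus scaled by the per-voxel ``perfusion`` map with no conversion.
    Rician noise is added at sigma = peak clean pyruvate / snr.
    """
    if n_frames < 5:
        raise ValueError("need >= 5 frames")
    for nm, v in (("t1_pyr", t1_pyr), ("t1_lac", t1_lac), ("t1_urea", t1_urea), ("tr", tr)):
        if v <= 0:
            raise ValueError(f"{nm} must be positive")
    kpl_truth = np.asarray(kpl_truth, dtype=float)
    shape = kpl_truth.shape
    if perfusion is None:
        perfusion = (kpl_truth > 0).astype(float) * 0.5
    perfusion = np.asarray(perfusion, dtype=float)
    if delivery is None:
        delivery = ((kpl_truth > 0) | (perfusion > 0)).astype(float)
    delivery = np.asarray(delivery, dtype=float)

    a = np.deg2rad(flip_deg)
    sin_a, cos_a = np.sin(a), np.cos(a)
    dt = tr / substeps
    times = np.arange(n_frames) * tr

    pz = np.zeros(shape)
    lz = np.zeros(shape)
    uz = np.zeros(shape)
    pyr = np.zeros(shape + (n_frames,))
    lac = np.zeros(shape + (n_frames,))
    urea = np.zeros(shape + (n_frames,))

    t_now = 0.0
    # bolus begins at t = 0 (first excitation coincides with arrival start)
    for n in range(n_frames):
        pyr[..., n] = pz * sin_a
        lac[..., n] = lz * sin_a
        urea[..., n] = uz * sin_a
        pz = pz * cos_a
        lz = lz * cos_a
        uz = uz * cos_a
        if n == n_frames - 1:
            break
        for s in range(substeps):
            ts = t_now + s * dt
            inflow = float(gamma_variate(ts, bolus_amplitude, bolus_shape, bolus_scale_s))
            dpz = inflow * delivery - pz * (1.0 / t1_pyr + kpl_truth)
            dlz = kpl_truth * pz - lz / t1_lac
            duz = inflow * perfusion - uz / t1_urea
            # midpoint (RK2) step
            pz_h = pz + 0.5 * dt * dpz
            lz_h = lz + 0.5 * dt * dlz
            uz_h = uz + 0.5 * dt * duz
            inflow_h = float(gamma_variate(ts + 0.5 * dt, bolus_amplitude, bolus_shape, bolus_scale_s))
            pz = pz + dt * (inflow_h * delivery - pz_h * (1.0 / t1_pyr + kpl_truth))
            lz = lz + dt * (kpl_truth * pz_h - lz_h / t1_lac)
            uz = uz + dt * (inflow_h * perfusion - uz_h / t1_urea)
        t_now += tr

    sigma = 0.0 if np.isinf(snr) else float(pyr.max() / snr)
    rng = _rng(seed, "hp")
    dyn = HPDynamics(
        pyr=_rician(pyr, sigma, rng),
        lac=_rician(lac, sigma, rng),
        urea=_rician(urea, sigma, rng),
        timestamps=times,
        flip_deg=flip_deg,
        sigma=None,
    )
    auc = np.trapezoid(urea, x=times, axis=-1)
    return PhantomDataset(
        data=np.stack([dyn.pyr, dyn.lac, dyn.urea]),
        truth={
            "kpl": kpl_truth, "perfusion": perfusion, "sigma": sigma,
            "t1_pyr": t1_pyr, "t1_lac": t1_lac, "t1_urea": t1_urea,
            "flip_deg": flip_deg, "tr": tr,
            "clean_pyr": pyr, "clean_lac": lac, "clean_urea": urea,
            "urea_auc_map": auc, "timestamps": times,
        },
        seed=seed,
    ), dyn


def default_hp_phantom(
    kpl_tumor: float = 0.08,
    snr: float = np.inf,
    seed: int = 0,
    grid: int = 8,
):
    """An 8x8 slice: 3x3 tumor block, one vessel voxel, background elsewhere.

    Returns (dataset, dynamics, tumor_roi, vessel_roi, background_roi).
    """
    kpl = np.zeros((grid, grid))
    tumor = np.zeros((grid, grid), dtype=bool)
    tumor[2:5, 2:5] = True
    kpl[tumor] = kpl_tumor
    vessel = np.zeros((grid, grid), dtype=bool)
    vessel[6, 6] = True
    perf = np.zeros((grid, grid))
    perf[tumor] = 0.5
    perf[vessel] = 1.0
    ds, dyn = simulate_hp(kpl, perfusion=perf, snr=snr, seed=seed)
    background = ~(tumor | vessel)
    return ds, dyn, tumor, vessel, background


# ---------------------------------------------------------------------------
# Growth and SIRM


def simulate_growth(
    v0_mm3: float = 50.0,
    td_days: float = 5.0,
    noise_sigma: float = 0.1,
    n_weeks: int = 4,
    seed: int = 0,
) -> GrowthSeries:
    """Weekly exponential growth with lognormal multiplicative noise."""
    if td_days <= 0:
        raise ValueError("doubling time must be positive")
    t = np.arange(n_weeks + 1) * 7.0
    rng = _rng(seed, "growth")
    noise = np.exp(rng.normal(0.0, noise_sigma, size=t.size)) if noise_sigma > 0 else 1.0
    v = v0_mm3 * 2.0 ** (t / td_days) * noise
    return GrowthSeries(times_days=t, volumes_mm3=v)


def simulate_peak_table(
    fe_truth: dict[str, float] | None = None,
    total_area: float = 1000.0,
    noise_cv: float = 0.0,
    tissue_mass_g: float = 0.1,
    extract_volume_ml: float = 1.0,
    reference_conc_mm: float = 1.0,
    seed: int = 0,
):
    """NMR peak table with known fractional enrichment per metabolite.

    satellite = FE * total, central = (1 - FE) * total, each perturbed by
    multiplicative lognormal noise of the stated coefficient of variation.
    """
    import pandas as pd

    if fe_truth is None:
        fe_truth = {"lactate": 0.40, "alanine": 0.25, "glutamate": 0.15}
    rng = _rng(seed, "sirm")
    rows = []
    for met, fe in fe_truth.items():
        if not (0 <= fe <= 1):
            raise ValueError(f"FE truth for {met} outside [0, 1]")
        sat = fe * total_area
        cen = (1.0 - fe) * total_area
        if noise_cv > 0:
            s = np.sqrt(np.log1p(noise_cv**2))
            sat *= np.exp(rng.normal(-s**2 / 2, s))
            cen *= np.exp(rng.normal(-s**2 / 2, s))
        rows.append(
            {
                "metabolite": met,
                "central_area": cen,
                "satellite_area": sat,
                "proton_count": 3,
                "tissue_mass_g": tissue_mass_g,
                "reference_area": total_area,
                "reference_conc_mm": reference_conc_mm,
                "reference_protons": 9,
                "extract_volume_ml": extract_volume_ml,
            }
        )
    table = pd.DataFrame(rows)
    return table, dict(fe_truth)
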