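# Methods

`pdxmri` implements the quantitative arms of a preclinical multi-modal MR
study of patient-derived xenograft (PDX) tumors grown at different
implantation sites: relaxometry, diffusion, dynamic contrast-enhanced (DCE)
pharmacokinetics, hyperpolarized (HP) ¹³C metabolic imaging, tumor growth
kinetics, stable-isotope enrichment arithmetic, and the cohort-level
statistics. Because no animal imaging data ship with the package, every
stage is validated by parameter recovery against a digital phantom whose
generating truth is known exactly.

## Signal models

### Saturation-recovery T1

S(TR) = S₀ (1 − e^(−TR/T₁)), fitted per voxel by nonlinear least squares
(`scipy.optimize.curve_fit`) with analytic initialization: S₀ from the
longest-TR signal and T₁ from a two-point log estimate. The emulated
protocol samples 10 TRs from 369.5 ms to 5 s; the phantom uses a log-spaced
schedule over that range since the intermediate values are
protocol-dependent. Validity window: T₁ ∈ (1 ms, 20 s) **and**
T₁ > TRmin/5 — a T₁ far below the shortest TR is unidentifiable (the curve
is fully recovered at every sample, e.g. a TR-independent constant), so
such fits are masked rather than clipped.

### ADC

Mono-exponential decay S_b/S₀ = e^(−b·ADC) fitted log-linearly
(`numpy.polyfit` on ln S vs b). Log-linear is the primary estimator because
the b-range (11–600 s/mm²) is low enough that noise-floor bias is modest;
the unweighted nonlinear fit is retained as a test oracle and agrees to
1e−8 on noiseless data. Voxels with any non-positive sample are invalid
(no log transform). Maps carry mm²/s; CSV summaries use the conventional
10⁻³ mm²/s scale. At SNR 20 the per-voxel sampling SD of ADC is ≈ 13 %
(error propagation through the 7-point log-linear fit), so recovery
requirements are placed on the estimator's *centering* (median signed
error), not on per-voxel scatter.

### DCE: concentration and extended Tofts

Signal is converted to gadolinium concentration through the spoiled
gradient-echo steady-state equation S ∝ sin α (1 − E₁)/(1 − cos α E₁),
E₁ = e^(−TR·R₁). The equilibrium scale is pinned by the pre-injection
baseline average together with the measured baseline T₁ (T₁₀); inverting
for R₁(t) gives C(t) = (R₁(t) − R₁₀)/r₁ with r₁ = 3.8 mM⁻¹s⁻¹ (Magnevist
at 3 T). Time points whose implied E₁ leaves (0, 1) are masked.

Tissue kinetics use the extended Tofts model
C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^(−k_ep (t−τ)) dτ + v_p C_p(t), k_ep =
K^trans/v_e. The convolution is evaluated segment-exactly for a
piecewise-linear C_p on the non-uniform frame grid (3 s frames for the
first minute, then one per minute to 8 min), with a series expansion of the
segment integrals below k_ep·Δt = 10⁻⁴ to avoid cancellation. The fit
normalizes the time grid to [0, 1] internally, which makes the optimizer
path independent of the time unit (passing minutes yields K^trans in
min⁻¹ exactly 60× the per-second fit). Three fixed starts guard the
K^trans–v_e ridge; bounds are v_e, v_p ∈ [0, 1] with the validity condition
v_e + v_p ≤ 1, and K^trans ≥ 0 with a wide normalized upper bound rather
than a fixed 10 min⁻¹ cap (a unit-specific cap would break the
time-unit equivariance; in practice the bound is never active).

The arterial input function is a population biexponential (Weinmann form,
C_p = D(a₁e^(−m₁t) + a₂e^(−m₂t)), defaults a₁ = 3.99, a₂ = 4.78 kg/L,
m₁ = 0.144, m₂ = 0.0111 min⁻¹, D = 0.1 mmol/kg), configurable or
replaceable by a measured CSV curve. No hematocrit correction is applied:
fits are against the plasma AIF as given. Injection time defaults to the
first post-baseline frame (baseline count configurable, default 3).

Enhancement curves are classified by the linear slope of the late phase
(≥ 2 min post injection): fitted change over the window > +10 % of the
post-injection peak → type I (persistent), within ±10 % → type II
(plateau), < −10 % → type III (washout). Note that under the default
Weinmann AIF a simulated tumor tracks the plasma washout and classifies as
type III; the plateau pattern requires an AIF that approaches steady state,
as in the dedicated closure test.

### Hyperpolarized ¹³C: inputless k_PL

The measured pyruvate time course itself drives lactate production — no
arterial input model. Between excitations n and n+1 the lactate
longitudinal magnetization obeys dL/dt = k_PL P(t) − L/T1_L, with cos α RF
losses at each excitation (α = 10°, TR = 4.2 s, 15 frames, one excitation
per metabolite per frame; measured amplitudes are sin α projections of the
available longitudinal magnetization, so the shared sin α cancels from the
fit). The inter-frame update uses the exact interval solution

L(t₊₁) = L(t) cos α e^(−TR/T1_L) + k_PL ∫ P̃(τ) e^(−(t₊₁−τ)/T1_L) dτ,

with P̃ piecewise-linear between the flip-corrected samples
(P_n cos α → P_{n+1}). Keeping the relaxation kernel inside the pyruvate
integral matters: dropping it (a plain ∫P dτ drive) biases k_PL high by
≈ TR/(2·T1_L) ≈ 8 % at these settings, which a fine-grid ODE oracle
exposes; the kernel-exact form recovers a noiseless k_PL = 0.10 s⁻¹
phantom to better than 0.5 %. The fit window starts at the pyruvate-peak
frame (bolus arrival is not modeled, the standard inputless convention);
lactate is anchored at its measured value there; k_PL ≥ 0 by bounded least
squares. T1 of lactate is fixed at 25 s (config-exposed) — the inputless
formulation requires a fixed relaxation constant and magnitude data cannot
identify it jointly with k_PL.

Only voxels whose peak amplitude reaches SNR ≥ 3 (inclusive) enter
summaries; σ is the standard deviation of a signal-free background region
across all three channels. k_PL is fitted per voxel over voxels where both
pyruvate and lactate pass the rule, then averaged over the tumor ROI
("whole-tumor mean"). Urea perfusion is summarized as the trapezoidal AUC
per voxel, mean-tumor over mean-vessel (dimensionless); no cross-site
urea scale is provided because vessel normalization is site-local.

### Growth and SIRM

Doubling time T_d = ln 2 / slope of the OLS fit of ln V vs t (days).
Non-positive slopes are flagged non-growing (no finite T_d) and excluded
from group means with a logged count. Fractional enrichment from integrated
NMR peak areas: FE = satellite/(satellite + central), undefined (NaN) when
both are zero; optional natural-abundance correction
FE′ = (FE − 0.011c)/(1 − 0.011c) per c carbons, off by default.
Concentrations are proton-normalized ratios to an internal standard,
(total/protons)/(ref/ref protons) × ref conc × extract volume / tissue
mass, in µmol/g.

### Statistics

Pairwise post-hoc comparisons use Welch two-sample t-tests (the study
names only "post hoc tests"), corrected by the two-stage linear step-up
FDR procedure: stage 1 at q′ = q/(1+q) estimates the true-null count m₀,
stage 2 re-runs the step-up at q′·m/m₀ (the Benjamini–Krieger–Yekutieli
definition, matching `statsmodels` `fdr_tsbky` and Prism; an
independently coded reference oracle checks discovery sets in tests).
Repeated-measures power follows the G*Power 3.1 within-between interaction
convention: λ = f²·N·m/(1 − ρ), df = (k−1)(m−1) and (N−k)(m−1), power =
upper tail of the noncentral F beyond the central critical value; with
f = 1.438, N = 6, k = m = 2, ρ = 0.2, α = 0.05 this gives 0.981, and N = 6
is the smallest total reaching power ≥ 0.95. The between-factors
convention (λ = f²·N·m/(1 + (m−1)ρ)) is available by flag but does not
reproduce the 0.98 figure. Cohen's f is treated as an input constant:
its published derivation from the underlying mean and SD does not follow
the standard two-group formula, so the package does not claim to re-derive
it. A vectorized compound-symmetry ANOVA simulator cross-checks the
analytic power to within 0.01 at 10⁵ replicates.

## The phantom: what it emulates, what it does not

Generators are pure functions of (parameters, seed), one RNG stream per
modality derived from the master seed, so datasets are bit-reproducible
and adding a modality never perturbs another. Noise is Rician on magnitude
channels (DWI, saturation recovery, HP ¹³C) and Gaussian on the high-SNR
¹H DCE signal. The HP phantom integrates the two-site exchange ODE at
TR/100 with RK2 and a gamma-variate bolus (shape 3, scale 4 s —
a few-second arrival typical of a murine tail-vein injection); pyruvate
delivery, urea perfusion, and k_PL maps are independently configurable, so
background voxels are genuinely signal-free for noise estimation. Truth
sidecar JSONs carry a SHA-256 of the data linking files to truth.

Defaults sit in the reported physiologic ranges: ADC 0.6–1.4 × 10⁻³ mm²/s,
T1 1.2–2.0 s, k_PL 0.04–0.14 s⁻¹ (default 0.08), doubling times 5–11 days,
FE 0.15–0.40. For noisy DCE recovery the phantom uses tumor-typical
kinetics (K^trans 0.25 min⁻¹, v_e 0.3, v_p 0.05): at the study's reported
10⁻⁴ min⁻¹ K^trans scale the transfer term is far below any realistic
noise floor, so noisy recovery there would test nothing; the 10⁻⁴-scale
values are exercised noiselessly instead.

The phantom does not emulate anatomy, partial-volume effects, motion, B0/B1
inhomogeneity, k-space artifacts, or spectral overlap in the ¹³C data. A
green recovery test therefore establishes correctness of the estimators
under the stated signal and noise models, not robustness to acquisition
artifacts.

## Numerical choices

- Exponential-kernel segment integrals switch to 2nd-order series below
  rate·Δt = 10⁻⁴ (both DCE convolution and HP drive), keeping the
  no-relaxation limits exact to rounding.
- scipy's noncentral-F survival function is bypassed at λ = 0 (it is
  unreliable there); the null power is α by definition.
- Flat-signal ADC voxels are detected exactly (zero peak-to-peak log
  signal) and return ADC = 0 with R² flagged NaN.
- ROI extraction is row-major and deterministic; masks must share grids
  exactly — no resampling anywhere (inputs are required pre-aligned).
- Pipeline CSV schema: one row per (animal, ROI, parameter) with columns
  id, pdx_line, site, parameter, value, units, n_voxels; fitted/rejected
  voxel counts are logged per stage because the SNR rule silently changes
  n otherwise.

## Known limitations

- The inputless k_PL fit is unidirectional (no k_LP back-conversion) and
  assumes shared nominal flip across metabolites.
- The DCE stage fits a single population AIF for all voxels; no per-voxel
  bolus-arrival-time estimation.
- SIRM consumes integrated peak areas only; which protons were integrated
  per metabolite is left to the table producer.
- Urea AUC normalization assumes a user-supplied vessel ROI per animal;
  intrahepatic and intratibial values are not cross-comparable.
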