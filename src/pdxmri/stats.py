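"""Group statistics: ANOVA with two-stage step-up FDR, Pearson correlation,
and repeated-measures power / sample size.

The multiple-comparison correction is the adaptive two-stage linear step-up
procedure of Benjamini, Krieger and Yekutieli (the "q < 0.05, two-stage
step-up" rule of GraphPad Prism): stage 1 runs a linear step-up at
q' = q/(1+q) to estimate the number of true nulls m0, stage 2 re-runs the
step-up at level q' * m / m0.

Power for a two-way (between x within) repeated-measures design follows the
G*Power 3.1 within-between *interaction* convention: noncentrality
lambda = f^2 * N * m / (1 - rho) with numerator df (k-1)(m-1) and
denominator df (N-k)(m-1), where f is Cohen's effect size, N the total
animal count in k equal groups, m the repeated measures and rho the
compound-symmetric correlation among them.  A between-factors convention
(lambda = f^2 * N * m / (1 + (m-1) rho)) is available via ``convention``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Two-stage step-up FDR


def _linear_step_up(pvals: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up; boolean rejection vector."""
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresh = level * np.arange(1, m + 1) / m
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        reject[order[: kmax + 1]] = True
    return reject


def two_stage_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage step-up FDR control; returns (reject, q_values).

    Stage 1 estimates the number of true null hypotheses m0 from a linear
    step-up pass at q' = q/(1+q); stage 2 repeats the step-up at the
    adapted level q' * m/m0.  Rejections are invariant to the input order.
    The returned q-values are the adapted step-up critical ratios
    p_(i) * m0 / i (monotonized), so ``q_values <= q'`` reproduces the
    rejection set.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("p-values must be a non-empty 1D vector")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pvals.size
    q_prime = q / (1.0 + q)
    stage1 = _linear_step_up(pvals, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        m0 = m
        reject = np.zeros(m, dtype=bool)
    elif r1 == m:
        m0 = 0
        reject = np.ones(m, dtype=bool)
    else:
        m0 = m - r1
        reject = _linear_step_up(pvals, q_prime * m / m0)

    # adapted BH q-values (with m0 in place of m), monotonized from the top
    eff_m0 = max(m0, 1)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    qv = ranked * eff_m0 / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    q_values = np.empty(m)
    q_values[order] = np.clip(qv, 0, 1)
    return reject, q_values


# ---------------------------------------------------------------------------
# Group comparisons


@dataclass
class AnovaFdrResult:
    f_statistic: float
    p_anova: float
    comparisons: pd.DataFrame  # group_a, group_b, p, q_adjusted, significant


def anova_fdr(groups: dict[str, np.ndarray], q: float = 0.05) -> AnovaFdrResult:
    """One-way ANOVA plus all pairwise comparisons with two-stage FDR.

    ``groups`` maps group label to the per-animal values.  Pairwise post-hoc
    p-values come from Welch two-sample t-tests (unequal variances) and are
    then adjusted by :func:`two_stage_fdr` at level ``q``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"group '{name}' has < 2 values")
        arrays[name] = v
    f_stat, p_anova = sps.f_oneway(*arrays.values())

    pairs = list(combinations(sorted(arrays), 2))
    pvals = np.array(
        [sps.ttest_ind(arrays[a], arrays[b], equal_var=False).pvalue for a, b in pairs]
    )
    reject, qv = two_stage_fdr(pvals, q=q)
    comp = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p": pvals,
            "q_adjusted": qv,
            "significant": reject,
        }
    )
    return AnovaFdrResult(f_statistic=float(f_stat), p_anova=float(p_anova), comparisons=comp)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def mean_se(values) -> tuple[float, float]:
    """Mean and standard error of the mean, the study's summary convention."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


# ---------------------------------------------------------------------------
# Repeated-measures power


@dataclass
class PowerSpec:
    f: float            # Cohen's effect size
    n_total: int        # total subjects, equal groups
    k_groups: int
    m_measures: int
    rho: float          # correlation among repeated measures
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("effect size f must be >= 0")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def rm_power(spec: PowerSpec, convention: str = "interaction") -> float:
    """Achieved power of the repeated-measures within-between F test.

    ``convention='interaction'`` (default) uses lambda = f^2 N m / (1-rho);
    ``'between'`` uses lambda = f^2 N m / (1 + (m-1) rho) with the
    between-groups df.  Power is the upper-tail mass of the noncentral F
    beyond the central-F critical value at alpha.
    """
    k, m, n = spec.k_groups, spec.m_measures, spec.n_total
    if convention == "interaction":
        df1 = (k - 1) * (m - 1)
        df2 = (n - k) * (m - 1)
        lam = spec.f**2 * n * m / (1.0 - spec.rho)
    elif convention == "between":
        df1 = k - 1
        df2 = n - k
        lam = spec.f**2 * n * m / (1.0 + (m - 1) * spec.rho)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if df1 <= 0 or df2 <= 0:
        raise ValueError(f"non-positive degrees of freedom (df1={df1}, df2={df2})")
    fcrit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0:  # scipy's ncf is unreliable at zero noncentrality
        return float(spec.alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def rm_sample_size(
    f: float,
    k_groups: int,
    m_measures: int,
    rho: float,
    alpha: float = 0.05,
    target_power: float = 0.95,
    n_max: int = 10000,
    convention: str = "interaction",
) -> int:
    """Smallest total N (divisible by k) reaching the target power."""
    if f <= 0:
        raise ValueError("target power unreachable with f = 0")
    if not (alpha < target_power < 1):
        raise ValueError("target power must be in (alpha, 1)")
    n = 2 * k_groups
    while n <= n_max:
        spec = PowerSpec(f=f, n_total=n, k_groups=k_groups, m_measures=m_measures,
                         rho=rho, alpha=alpha)
        if rm_power(spec, convention=convention) >= target_power:
            return n
        n += k_groups
    raise RuntimeError(f"no N <= {n_max} reaches power {target_power}")


def simulate_rm_power(
    spec: PowerSpec, n_reps: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo check of :func:`rm_power` under compound symmetry.

    Simulates k equal groups of N/k subjects with m measures each: cell
    means carry a pure group-by-measure interaction of effect size f; each
    subject adds a random offset of variance rho and residual noise of
    variance 1-rho (total unit variance, correlation rho).  The interaction
    F statistic of the classical mixed-design ANOVA is compared with the
    central-F critical value; the rejection rate estimates power.
    """
    k, m, N = spec.k_groups, spec.m_measures, spec.n_total
    if N % k:
        raise ValueError("n_total must be divisible by k_groups")
    n = N // k
    rng = np.random.default_rng(seed)

    # interaction-only cell means: mu_gj = delta * s_g * w_j, orthogonal
    # contrasts so row/column means vanish; scaled so that
    # sqrt(mean(mu^2)) = f (sigma = 1)
    sg = np.where(np.arange(k) < k / 2, 1.0, -1.0)
    if k % 2:
        sg[k // 2] = 0.0
    wj = np.where(np.arange(m) < m / 2, 1.0, -1.0)
    if m % 2:
        wj[m // 2] = 0.0
    cell = np.outer(sg, wj)
    rms = np.sqrt(np.mean(cell**2))
    cell = cell * (spec.f / rms)

    subj = rng.normal(0.0, np.sqrt(spec.rho), size=(n_reps, k, n, 1))
    eps = rng.normal(0.0, np.sqrt(1.0 - spec.rho), size=(n_reps, k, n, m))
    y = cell[None, :, None, :] + subj + eps

    grand = y.mean(axis=(1, 2, 3), keepdims=True)
    g_mean = y.mean(axis=(2, 3), keepdims=True)          # per group
    j_mean = y.mean(axis=(1, 2), keepdims=True)          # per measure
    gj_mean = y.mean(axis=2, keepdims=True)              # group x measure
    subj_mean = y.mean(axis=3, keepdims=True)            # per subject

    ss_int = n * ((gj_mean - g_mean - j_mean + grand) ** 2).sum(axis=(1, 2, 3))
    ss_err = ((y - gj_mean - subj_mean + g_mean) ** 2).sum(axis=(1, 2, 3))
    df1 = (k - 1) * (m - 1)
    df2 = (N - k) * (m - 1)
    f_stat = (ss_int / df1) / (ss_err / df2)
    fcrit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(np.mean(f_stat > fcrit))
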