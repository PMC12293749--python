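"""Hyperpolarized 13C quantification: noise, SNR rule, k_PL, urea AUC."""

import numpy as np
import pytest
from oracles import ode_oracle_kpl

from pdxmri.datamodel import HPDynamics
from pdxmri.hp13c import (
    NormalizationError,
    estimate_noise,
    fit_kpl_inputless,
    fit_kpl_map,
    snr_mask,
    urea_auc,
)
from pdxmri.phantom import default_hp_phantom, simulate_hp

TIMES15 = np.arange(15) * 4.2


def make_dyn(pyr=None, lac=None, urea=None, shape=(8, 8)):
    zero = np.zeros(shape + (15,))
    return HPDynamics(
        pyr=zero if pyr is None else pyr,
        lac=zero if lac is None else lac,
        urea=zero if urea is None else urea,
        timestamps=TIMES15,
    )


class TestNoise:
    def test_sigma_matches_generator(self):
        rng = np.random.default_rng(5)
        shape = (8, 8)
        bg = np.zeros(shape, dtype=bool)
        bg.flat[:25] = True  # 25 voxels x 15 frames x 3 channels > 1000 samples
        noise = lambda: np.where(bg[..., None], rng.normal(0, 1.0, shape + (15,)), 0.0)
        dyn = make_dyn(pyr=noise(), lac=noise(), urea=noise())
        sigma = estimate_noise(dyn, bg)
        assert sigma == pytest.approx(1.0, abs=0.05)

    def test_constant_background_is_degenerate(self):
        dyn = make_dyn(pyr=np.full((8, 8, 15), 2.0), lac=np.full((8, 8, 15), 2.0),
                       urea=np.full((8, 8, 15), 2.0))
        bg = np.ones((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="zero spread"):
            estimate_noise(dyn, bg)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        arrs = [rng.normal(0, 1, (8, 8, 15)) for _ in range(3)]
        bg = np.ones((8, 8), dtype=bool)
        s1 = estimate_noise(make_dyn(*arrs), bg)
        s2 = estimate_noise(make_dyn(*(2 * a for a in arrs)), bg)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_too_few_samples(self):
        dyn = make_dyn()
        with pytest.raises(ValueError, match="8 voxel-time"):
            estimate_noise(dyn, np.zeros((8, 8), dtype=bool))


class TestSNRMask:
    def test_boundary_inclusive_at_exactly_3(self):
        ch = np.zeros((2, 1, 15))
        ch[0, 0, 5] = 3.0   # peak exactly 3 sigma
        ch[1, 0, 5] = 2.99
        mask = snr_mask(ch, sigma=1.0)
        assert mask[0, 0] and not mask[1, 0]

    def test_count_matches_construction(self):
        rng = np.random.default_rng(8)
        ch = np.abs(rng.normal(0, 0.1, (8, 8, 15)))
        chosen = rng.choice(64, size=10, replace=False)
        for c in chosen:
            ch[np.unravel_index(c, (8, 8)) + (7,)] = 10.0
        assert snr_mask(ch, sigma=1.0).sum() == 10

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            snr_mask(np.ones((2, 2, 5)), sigma=0.0)


class TestKPLFit:
    def test_zero_lactate_gives_zero_kpl(self):
        pyr = np.exp(-np.arange(15) / 5.0) * 100
        res = fit_kpl_inputless(pyr, np.zeros(15))
        assert res.valid and res.kpl == 0.0

    def test_zero_pyruvate_invalid(self):
        res = fit_kpl_inputless(np.zeros(15), np.ones(15))
        assert not res.valid

    @pytest.mark.parametrize("kpl_true", [0.04, 0.08, 0.10, 0.14])
    def test_noiseless_closure(self, kpl_true):
        _, dyn = simulate_hp(np.array([[kpl_true]]))
        res = fit_kpl_inputless(dyn.pyr[0, 0], dyn.lac[0, 0])
        assert res.kpl == pytest.approx(kpl_true, abs=0.001 * (kpl_true / 0.10))

    def test_scale_invariance(self):
        _, dyn = simulate_hp(np.array([[0.08]]))
        a = fit_kpl_inputless(dyn.pyr[0, 0], dyn.lac[0, 0]).kpl
        b = fit_kpl_inputless(dyn.pyr[0, 0] * 1e3, dyn.lac[0, 0] * 1e3).kpl
        assert b == pytest.approx(a, rel=1e-6)

    def test_no_relaxation_limit_matches_cumulative_slope(self):
        # T1L -> inf, flip -> 0: lactate is the running integral of kPL*P
        kpl_true = 0.06
        t = TIMES15
        pyr = 100 * np.exp(-t / 20.0)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (pyr[1:] + pyr[:-1]) * np.diff(t))])
        lac = kpl_true * cum
        res = fit_kpl_inputless(pyr, lac, flip_deg=1e-6, tr=4.2, t1_lac=1e12)
        assert res.kpl == pytest.approx(kpl_true, rel=0.01)

    def test_noisy_snr10_vs_ode_oracle(self):
        # 200 Rician-noise voxels at k_PL = 0.08: the discrete fit must stay
        # within 10% (median) of the fine-grid ODE oracle and of the truth
        kpl_true = 0.08
        truth = np.full((20, 10), kpl_true)
        _, dyn = simulate_hp(truth, snr=10.0, seed=21)
        fits = np.array([
            fit_kpl_inputless(dyn.pyr[idx], dyn.lac[idx]).kpl
            for idx in np.ndindex(20, 10)
        ])
        oracle = ode_oracle_kpl(dyn.pyr.reshape(200, 15), dyn.lac.reshape(200, 15))
        assert np.median(np.abs(fits - kpl_true) / kpl_true) < 0.10
        assert np.median(np.abs(fits - oracle) / kpl_true) < 0.10

    def test_tumor_mean_is_mean_of_voxel_fits(self):
        ds, dyn, tumor, vessel, background = default_hp_phantom(kpl_tumor=0.08, snr=50, seed=3)
        sigma = estimate_noise(dyn, background)
        res = fit_kpl_map(dyn, tumor, sigma)
        vals = res.kpl_map[res.valid]
        assert res.n_voxels_used == vals.size
        assert res.tumor_mean_kpl == pytest.approx(vals.mean(), rel=1e-12)
        assert res.tumor_mean_kpl == pytest.approx(0.08, rel=0.10)


class TestUreaAUC:
    def test_self_normalization(self):
        tc = np.linspace(0, 5, 15)
        urea = np.tile(tc, (2, 1, 1))
        dyn = make_dyn(urea=urea, shape=(2, 1))
        tumor = np.array([[True], [False]])
        vessel = np.array([[False], [True]])
        res = urea_auc(dyn, tumor, vessel)
        assert res.urea_auc == pytest.approx(1.0, rel=1e-12)

    def test_linearity(self):
        tc = np.linspace(1, 5, 15)
        urea = np.stack([0.5 * tc, tc])[:, None, :]
        dyn = make_dyn(urea=urea, shape=(2, 1))
        res = urea_auc(dyn, np.array([[True], [False]]), np.array([[False], [True]]))
        assert res.urea_auc == pytest.approx(0.5, rel=1e-12)

    def test_hand_computed_trapezoid_ratio(self):
        rng = np.random.default_rng(12)
        urea = rng.random((4, 2, 15))
        dyn = make_dyn(urea=urea, shape=(4, 2))
        tumor = np.zeros((4, 2), bool); tumor[:2] = True
        vessel = np.zeros((4, 2), bool); vessel[3, 1] = True
        # oracle: explicit trapezoid sums per voxel
        def trap(v):
            return sum(0.5 * (v[i] + v[i + 1]) * 4.2 for i in range(14))
        tumor_aucs = [trap(urea[i, j]) for i in range(2) for j in range(2)]
        expected = np.mean(tumor_aucs) / trap(urea[3, 1])
        res = urea_auc(dyn, tumor, vessel)
        assert res.urea_auc == pytest.approx(expected, abs=1e-10)

    def test_global_scaling_invariance(self):
        _, dyn, tumor, vessel, bg = default_hp_phantom(snr=np.inf)
        r1 = urea_auc(dyn, tumor, vessel).urea_auc
        dyn2 = HPDynamics(pyr=dyn.pyr, lac=dyn.lac, urea=dyn.urea * 7.0,
                          timestamps=dyn.timestamps)
        assert urea_auc(dyn2, tumor, vessel).urea_auc == pytest.approx(r1, rel=1e-12)

    def test_empty_vessel_after_snr_mask(self):
        dyn = make_dyn(urea=np.full((2, 1, 15), 0.1), shape=(2, 1))
        with pytest.raises(NormalizationError, match="vessel"):
            urea_auc(dyn, np.array([[True], [False]]), np.array([[False], [True]]),
                     sigma=1.0)
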