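"""Fitter unit tests: exact linear inversion for the tensor, powder
averaging, self-consistent nonlinear recovery, identifiability ordering,
and determinism."""

import numpy as np
import pytest

from hippodiff import model_fitting as mf
from hippodiff import signal_models as sm


def _voxels(n, gen, scheme, rng):
    """Simulate n single-voxel signals from per-voxel parameter draws."""
    sig = np.zeros((n, 1, 1, scheme.n_volumes))
    truth = []
    for i in range(n):
        p, s = gen(rng)
        truth.append(p)
        sig[i, 0, 0] = s
    return sig, truth, np.ones((n, 1, 1), dtype=bool)


class TestFitDti:
    def test_noiseless_exact_recovery(self, scheme, rng):
        def gen(rng):
            A = rng.normal(size=(3, 3)) * 0.3
            D = A @ A.T / 3.0 + 0.3 * np.eye(3)
            return D, sm.dti_signal(sm.TensorParams(D=D, S0=1.2), scheme)
        sig, truth, mask = _voxels(25, gen, scheme, rng)
        res = mf.fit_dti(sig, scheme, mask)
        for i, D in enumerate(truth):
            assert np.abs(res.maps["D"][i, 0, 0] - D).max() <= 1e-8
            assert res.maps["S0"][i, 0, 0] == pytest.approx(1.2, rel=1e-8)

    def test_only_low_b_shells_used(self, scheme, rng):
        """Corrupting the b >= 2.4 shells does not change the fit."""
        D = sm.tensor_from_eigen([1.2, 0.6, 0.4], e1=(0, 0, 1))
        s = sm.dti_signal(sm.TensorParams(D=D), scheme)
        sig = np.zeros((1, 1, 1, scheme.n_volumes))
        sig[0, 0, 0] = s
        corrupted = sig.copy()
        corrupted[..., scheme.bvals_per_volume >= 2.4] = 99.0
        mask = np.ones((1, 1, 1), dtype=bool)
        a = mf.fit_dti(sig, scheme, mask)
        b = mf.fit_dti(corrupted, scheme, mask)
        assert np.allclose(a.maps["D"], b.maps["D"])

    def test_b0_only_scheme_rejected(self):
        b0 = sm.AcquisitionScheme(bvalues=(0.0,), n_dirs_per_shell=(10,),
                                  directions=np.zeros((10, 3)))
        with pytest.raises(ValueError):
            mf.fit_dti(np.ones((1, 1, 1, 10)), b0,
                       np.ones((1, 1, 1), dtype=bool))

    def test_noise_floor_fa_bias_positive(self, scheme, rng):
        """Isotropic ground truth at snr = 50: mean fitted FA is biased
        positive (the well-known eigenvalue repulsion noise floor)."""
        D = 0.8 * np.eye(3)
        clean = sm.dti_signal(sm.TensorParams(D=D), scheme)
        n = 1000
        re = clean[None, :] + rng.normal(0, 0.02, (n, clean.size))
        im = rng.normal(0, 0.02, (n, clean.size))
        sig = np.hypot(re, im)[:, None, None, :]
        res = mf.fit_dti(sig, scheme, np.ones((n, 1, 1), dtype=bool))
        fa = res.maps["FA"][:, 0, 0]
        assert np.nanmean(fa) > 0.01

    def test_negative_eigenvalue_clamped_and_flagged(self, scheme, rng):
        """Heavy noise can push an eigenvalue negative; the fitter clamps
        it to zero and sets the flag."""
        D = sm.tensor_from_eigen([0.3, 0.01, 0.01])
        clean = sm.dti_signal(sm.TensorParams(D=D), scheme)
        n = 200
        sig = np.abs(clean[None, :]
                     + rng.normal(0, 0.1, (n, clean.size)))
        sig = sig[:, None, None, :]
        res = mf.fit_dti(sig, scheme, np.ones((n, 1, 1), dtype=bool))
        flagged = res.diagnostics["eigenvalue_clamped"][:, 0, 0]
        eigs = np.linalg.eigvalsh(res.maps["D"][:, 0, 0][flagged])
        assert flagged.any()
        assert eigs.min() >= -1e-12


class TestPowderAverage:
    def test_isotropic_signal_mean_equals_any_direction(self, scheme):
        p = sm.TensorParams(D=0.9 * np.eye(3))
        sig = sm.dti_signal(p, scheme)[None, None, None, :]
        bsh, mean, sd = mf.powder_average(sig, scheme)
        for s, b in enumerate(bsh):
            idx = scheme.shell_indices(s)
            assert mean[0, s] == pytest.approx(sig[0, 0, 0, idx[0]],
                                               rel=1e-12)
            assert sd[0, s] == pytest.approx(0.0, abs=1e-12)

    def test_stick_mean_matches_analytic_powder(self, scheme):
        """60 near-uniform directions at b = 6: the direction mean is
        within 1% of the analytic powder-averaged stick."""
        mu = np.array([0.2, -0.6, 0.77])
        mu /= np.linalg.norm(mu)
        D = sm.tensor_from_eigen([1.7, 0, 0], e1=mu)
        sig = sm.dti_signal(sm.TensorParams(D=D), scheme)[None, None, None]
        bsh, mean, _ = mf.powder_average(sig, scheme)
        s6 = np.nonzero(bsh == 6.0)[0][0]
        expected = sm.stick_powder_signal(np.array([6.0]), 1.7)[0]
        assert mean[0, s6] == pytest.approx(expected, rel=0.01)

    def test_duplicate_directions_leave_mean_unchanged(self):
        dirs = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 0, 0]])
        sch = sm.AcquisitionScheme(bvalues=(0.0, 1.0),
                                   n_dirs_per_shell=(1, 3),
                                   directions=np.vstack([[0, 0, 0], dirs]))
        sig = np.array([[[[1.0, 0.5, 0.5, 0.8]]]])
        _, mean, _ = mf.powder_average(sig, sch, min_dirs=3)
        assert mean[0, 1] == pytest.approx((0.5 + 0.5 + 0.8) / 3)

    def test_small_shell_refused(self):
        sch = sm.AcquisitionScheme(bvalues=(0.0, 1.0),
                                   n_dirs_per_shell=(1, 2),
                                   directions=np.array([[0, 0, 0],
                                                        [0, 0, 1.0],
                                                        [1.0, 0, 0]]))
        with pytest.raises(ValueError):
            mf.powder_average(np.ones((1, 1, 1, 3)), sch)


def _study_sandi_draw(rng):
    """Parameter draws matching the synthetic study conditions."""
    age_c = rng.uniform(-5.5, 5.5)
    fn = np.clip(0.23 + 0.006 * age_c + rng.normal(0, 0.02), 0.05, 0.9)
    fec = np.clip(0.35 - 0.006 * age_c + rng.normal(0, 0.02), 0.05, 0.9)
    return sm.SANDIParams(
        f_ec=fec, f_in=np.clip(fn / (1 - fec), 0.05, 0.95),
        r_s=np.clip(7.0 - 0.05 * age_c + rng.normal(0, 0.35), 1.5, 11.5),
        d_in=1.7,
        d_ec=np.clip(1.0 - 0.012 * age_c + rng.normal(0, 0.06), 0.2, 2.9))


class TestFitSandi:
    def test_noiseless_example_voxel_recovery(self, scheme):
        """The worked example: (f_ec=0.4, f_in=0.35, r_s=7, d_in=1.7,
        d_ec=1.0) recovered within 2% relative error."""
        p = sm.SANDIParams(f_ec=0.4, f_in=0.35, r_s=7.0, d_in=1.7,
                           d_ec=1.0)
        sig = np.zeros((1, 1, 1, scheme.n_volumes))
        sig[0, 0, 0] = sm.sandi_powder_signal(p, scheme.bvals_per_volume,
                                              scheme.delta, scheme.Delta)
        res = mf.fit_sandi(sig, scheme, np.ones((1, 1, 1), dtype=bool),
                           seed=0)
        for name in ("f_ec", "f_in", "r_s", "d_in", "d_ec"):
            assert res.maps[name][0, 0, 0] == pytest.approx(
                getattr(p, name), rel=0.02)

    def test_soma_radius_ordering(self, scheme):
        """Two voxels differing only in radius (5 vs 10 um) produce
        strictly ordered fitted radii."""
        sig = np.zeros((2, 1, 1, scheme.n_volumes))
        for i, r in enumerate((5.0, 10.0)):
            p = sm.SANDIParams(f_ec=0.35, f_in=0.3, r_s=r, d_in=1.7,
                               d_ec=1.0)
            sig[i, 0, 0] = sm.sandi_powder_signal(
                p, scheme.bvals_per_volume, scheme.delta, scheme.Delta)
        res = mf.fit_sandi(sig, scheme, np.ones((2, 1, 1), dtype=bool))
        assert res.maps["Rsoma"][0, 0, 0] < res.maps["Rsoma"][1, 0, 0]

    def test_derived_fraction_conservation(self, scheme, rng):
        def gen(rng):
            p = _study_sandi_draw(rng)
            return p, sm.sandi_powder_signal(p, scheme.bvals_per_volume,
                                             scheme.delta, scheme.Delta)
        sig, _, mask = _voxels(10, gen, scheme, rng)
        res = mf.fit_sandi(sig, scheme, mask, n_starts=4, prescreen=32,
                           polish=False)
        total = (res.maps["f_neurite"] + res.maps["f_soma"]
                 + res.maps["f_extracellular"])[mask]
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_too_few_shells_rejected(self):
        sch = sm.default_scheme().subscheme(2.4)
        n_vol = sch.n_volumes
        with pytest.raises(ValueError):
            mf.fit_sandi(np.ones((1, 1, 1, n_vol)), sch,
                         np.ones((1, 1, 1), dtype=bool))

    def test_deterministic(self, scheme, rng):
        def gen(rng):
            p = _study_sandi_draw(rng)
            return p, sm.sandi_powder_signal(p, scheme.bvals_per_volume,
                                             scheme.delta, scheme.Delta)
        sig, _, mask = _voxels(6, gen, scheme, rng)
        a = mf.fit_sandi(sig, scheme, mask, seed=3)
        b = mf.fit_sandi(sig, scheme, mask, seed=3)
        for name in a.maps:
            assert np.array_equal(a.maps[name], b.maps[name],
                                  equal_nan=True)

    def test_map_prior_shrinks_variance(self, scheme, rng):
        """The MAP option reduces estimator spread on noisy replicates of
        one voxel (same estimand, regularized)."""
        p = sm.SANDIParams(f_ec=0.35, f_in=0.35, r_s=7.0, d_in=1.7,
                           d_ec=1.0)
        clean = sm.sandi_powder_signal(p, scheme.bvals_per_volume,
                                       scheme.delta, scheme.Delta)
        n = 150
        re = clean[None, :] + rng.normal(0, 0.02, (n, clean.size))
        im = rng.normal(0, 0.02, (n, clean.size))
        sig = np.hypot(re, im)[:, None, None, :]
        mask = np.ones((n, 1, 1), dtype=bool)
        plain = mf.fit_sandi(sig, scheme, mask, n_starts=4, prescreen=64,
                             polish=False)
        mapped = mf.fit_sandi(sig, scheme, mask, n_starts=4, prescreen=64,
                              polish=False,
                              prior_weight=(0.01, 0.01, 0.02, 0.05, 0.01))
        sd_plain = np.nanstd(plain.maps["f_neurite"][mask])
        sd_map = np.nanstd(mapped.maps["f_neurite"][mask])
        assert sd_map < sd_plain


class TestFitNoddi:
    def test_noiseless_example_voxel_recovery(self, scheme):
        """(f_iso=0.1, f_in=0.5, kappa=2) with known orientation is
        recovered within 1e-3 each."""
        mu = np.array([0.4, 0.2, 0.89])
        mu /= np.linalg.norm(mu)
        p = sm.NODDIParams(f_iso=0.1, f_in=0.5, kappa=2.0, mu=mu)
        sig = sm.noddi_signal(p, scheme)[None, None, None]
        mus = mu[None, None, None]
        res = mf.fit_noddi(sig, scheme, np.ones((1, 1, 1), dtype=bool),
                           mu_init=np.broadcast_to(mus, (1, 1, 1, 3)))
        assert res.maps["f_iso"][0, 0, 0] == pytest.approx(0.1, abs=1e-3)
        assert res.maps["f_neurite_noddi"][0, 0, 0] == pytest.approx(
            0.5, abs=1e-3)
        assert res.maps["kappa"][0, 0, 0] == pytest.approx(2.0, rel=1e-3)

    def test_neurite_fraction_ordering(self, scheme):
        """Ground-truth f_in 0.05 vs 0.95 orders the fitted neurite
        fraction correctly in every noiseless voxel."""
        mu = np.array([0.0, 0.0, 1.0])
        sig = np.zeros((2, 1, 1, scheme.n_volumes))
        for i, f in enumerate((0.05, 0.95)):
            p = sm.NODDIParams(f_iso=0.05, f_in=f, kappa=2.0, mu=mu)
            sig[i, 0, 0] = sm.noddi_signal(p, scheme)
        mus = np.broadcast_to(mu, (2, 1, 1, 3))
        res = mf.fit_noddi(sig, scheme, np.ones((2, 1, 1), dtype=bool),
                           mu_init=mus)
        assert res.maps["f_neurite_noddi"][0, 0, 0] < \
            res.maps["f_neurite_noddi"][1, 0, 0]

    def test_orientation_defaults_to_tensor_eigenvector(self, scheme):
        """Without a supplied orientation the fitter derives it from the
        low-b tensor fit; recovery stays accurate for a coherent voxel."""
        mu = np.array([1.0, 1.0, 0.2])
        mu /= np.linalg.norm(mu)
        p = sm.NODDIParams(f_iso=0.05, f_in=0.55, kappa=8.0, mu=mu)
        sig = sm.noddi_signal(p, scheme)[None, None, None]
        res = mf.fit_noddi(sig, scheme, np.ones((1, 1, 1), dtype=bool))
        assert res.maps["f_neurite_noddi"][0, 0, 0] == pytest.approx(
            0.55, abs=0.02)

    def test_odi_map_consistent_with_kappa(self, scheme):
        mu = np.array([0.0, 0.0, 1.0])
        p = sm.NODDIParams(f_iso=0.0, f_in=0.4, kappa=1.0, mu=mu)
        sig = sm.noddi_signal(p, scheme)[None, None, None]
        res = mf.fit_noddi(sig, scheme, np.ones((1, 1, 1), dtype=bool),
                           mu_init=np.broadcast_to(mu, (1, 1, 1, 3)))
        k = res.maps["kappa"][0, 0, 0]
        assert res.maps["ODI"][0, 0, 0] == pytest.approx(
            sm.watson_odi(k), rel=1e-12)
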