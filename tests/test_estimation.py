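"""Laplace likelihood machinery, empirical-Bayes estimates, diagnostics."""

import copy

import numpy as np
import pytest
from scipy import integrate

from copropk.estimation import (
    CpiModel,
    RifModel,
    RsvModel,
    fit_fixed_effects,
    laplace_inner,
    likelihood_ratio_test,
    marginal_neg2ll,
    profile_likelihood,
)
from copropk.trial import simulate_trial


def toy_predict(theta, n_obs):
    def predict(B3):
        # sum over the (possibly empty) random-effect axis
        return theta * np.exp(B3.sum(-1, keepdims=True)) * np.ones((1, 1, n_obs))
    return predict


def exact_marginal_neg2ll(y, theta, omega2, sp, sa):
    """Adaptive-quadrature oracle for the one-random-effect toy model."""
    def integrand(b):
        f = theta * np.exp(b)
        v = sp**2 * f**2 + sa**2
        ll = -0.5 * np.sum((y - f) ** 2 / v + np.log(2 * np.pi * v))
        lp = -0.5 * (b**2 / omega2 + np.log(2 * np.pi * omega2))
        return np.exp(ll + lp)
    val, _ = integrate.quad(integrand, -6, 6, limit=300)
    return -2.0 * np.log(val)


class TestLaplaceEngine:
    @pytest.mark.parametrize("sp,sa", [(0.0, 1.0), (0.15, 1e-3)])
    def test_matches_quadrature_oracle(self, sp, sa):
        theta, omega2, n_obs = 10.0, 0.09, 8
        rng = np.random.default_rng(5)
        etas = rng.normal(0, np.sqrt(omega2), 3)
        f = theta * np.exp(etas)[:, None]
        Y = f * (1 + rng.normal(0, sp, (3, n_obs))) + rng.normal(0, sa, (3, n_obs))
        res = laplace_inner(toy_predict(theta, n_obs), Y, sp, sa, np.array([omega2]))
        exact = np.array([exact_marginal_neg2ll(y, theta, omega2, sp, sa) for y in Y])
        assert np.max(np.abs(res.per_subject - exact)) < 0.5

    def test_zero_random_effects_collapse_to_fixed_likelihood(self):
        theta, n_obs, sa = 5.0, 6, 0.7
        rng = np.random.default_rng(2)
        Y = theta + rng.normal(0, sa, (4, n_obs))
        res = laplace_inner(toy_predict(theta, n_obs), Y, 0.0, sa, np.zeros(0))
        direct = np.sum((Y - theta) ** 2 / sa**2 + np.log(2 * np.pi * sa**2), axis=1)
        assert np.allclose(res.per_subject, direct)

    def test_no_observations_gives_prior_mode(self):
        res = laplace_inner(toy_predict(1.0, 0), np.zeros((2, 0)), 0.0, 1.0,
                            np.array([0.25]))
        assert np.allclose(res.modes, 0.0)

    def test_shrinkage_to_zero_as_prior_tightens(self):
        theta, n_obs = 10.0, 5
        Y = np.full((1, n_obs), 14.0)  # data prefer eta = log(1.4)
        loose = laplace_inner(toy_predict(theta, n_obs), Y, 0.0, 1.0, np.array([1.0]))
        tight = laplace_inner(toy_predict(theta, n_obs), Y, 0.0, 1.0, np.array([1e-8]))
        assert abs(loose.modes[0, 0] - np.log(1.4)) < 0.01
        assert abs(tight.modes[0, 0]) < 1e-4


class TestEmpiricalBayes:
    def test_recovers_effects_from_rich_noise_free_data(self, design, models):
        # near-noise-free data: the MAP random effects equal the generating
        # effects for every component that enters the likelihood
        rif, cpi, _ = models
        cpi_small = copy.deepcopy(cpi)
        cpi_small.err.streams["cpi_plasma"] = (1e-4, 1e-6)
        cpi_small.err.streams["cpi_urine"] = (1e-4, 1e-6)
        df, truth = simulate_trial(design, rif, cpi_small, None, seed=9,
                                   residual_noise=False, return_truth=True)
        dt = 0.02  # same grid as the generator: no discretization mismatch
        t_cpi = np.arange(-7.0, 24.0 + dt / 2, dt)
        tg = truth["t_grid"]
        prof = {}
        for occ in ("OCC1", "OCC3"):
            c = truth["profiles"][(occ, "rif")]
            idx = np.clip(np.searchsorted(tg, t_cpi), 0, tg.size - 1)
            prof[occ] = np.where(t_cpi[None, :] < 0, 0.0, c[:, idx])
        model = CpiModel(df, cpi_small, rif_profiles=prof, dt=dt)
        theta = {n: getattr(cpi.fixed, n) for n in model.theta_names}
        modes = model.empirical_bayes(theta)
        # only the identifiable combinations are compared: for parameters
        # with both IIV and IOV the data pin eta + kappa_occ, not the split
        comp = {c: j for j, c in enumerate(model.b_components)}
        eta_t = truth["eta"]["cpi"]
        kap_t = truth["kappa"]["cpi"]
        for name in ("CLR", "Ki"):
            j = comp[("eta", name, None)]
            assert np.max(np.abs(modes[:, j] - eta_t[name])) < 5e-3, name
        # DDI occasions have dynamics that separate synthesis from biliary
        # clearance; the sums eta + kappa_occ are pinned there
        for name in ("ksyn", "CLb"):
            je = comp[("eta", name, None)]
            for io, occ in ((0, "OCC1"), (2, "OCC3")):
                jk = comp[("kappa", name, occ)]
                est = modes[:, je] + modes[:, jk]
                true_sum = eta_t[name] + kap_t[name][:, io]
                assert np.max(np.abs(est - true_sum)) < 5e-3, (name, occ)
        # the steady-state-only occasion identifies just the baseline level
        f = cpi.fixed
        s_k = modes[:, comp[("eta", "ksyn", None)]] + modes[:, comp[("kappa", "ksyn", "OCC2")]]
        s_b = modes[:, comp[("eta", "CLb", None)]] + modes[:, comp[("kappa", "CLb", "OCC2")]]
        e_r = modes[:, comp[("eta", "CLR", None)]]
        css_hat = f.ksyn * np.exp(s_k) / (f.CLb * np.exp(s_b) + f.CLR * np.exp(e_r))
        s_k_t = eta_t["ksyn"] + kap_t["ksyn"][:, 1]
        s_b_t = eta_t["CLb"] + kap_t["CLb"][:, 1]
        css_t = f.ksyn * np.exp(s_k_t) / (f.CLb * np.exp(s_b_t) + f.CLR * np.exp(eta_t["CLR"]))
        assert np.max(np.abs(css_hat / css_t - 1.0)) < 5e-3


class TestFitting:
    def test_perturbed_parameters_increase_ofv(self, design, models, trial_df):
        rif, cpi, _ = models
        dt = 0.1
        m_rif = RifModel(trial_df, copy.deepcopy(rif), dt=dt)
        th_rif = {n: getattr(rif.fixed, n) for n in m_rif.theta_names}
        t_cpi = np.arange(-7.0, 24.0 + dt / 2, dt)
        pos = t_cpi >= -1e-9
        prof_pos = m_rif.ebe_profiles(th_rif, t_cpi[pos])
        prof = {}
        for occ, c in prof_pos.items():
            full = np.zeros((c.shape[0], t_cpi.size))
            full[:, pos] = c
            prof[occ] = full
        model = CpiModel(trial_df, copy.deepcopy(cpi), rif_profiles=prof, dt=dt)
        theta = {n: getattr(cpi.fixed, n) for n in model.theta_names}
        base = model.neg2ll(theta, warm=False).ofv
        for name, factor in (("ksyn", 1.3), ("CLb", 0.7), ("CLR", 1.5), ("Ki", 0.5)):
            pert = dict(theta)
            pert[name] = theta[name] * factor
            assert model.neg2ll(pert).ofv > base, name

    def test_fit_improves_on_perturbed_start_and_recovers(self, design, models):
        rif, cpi, _ = models
        df, truth = simulate_trial(design, rif, cpi, None, seed=41,
                                   return_truth=True)
        dt = 0.1
        t_cpi = np.arange(-7.0, 24.0 + dt / 2, dt)
        tg = truth["t_grid"]
        prof = {}
        for occ in ("OCC1", "OCC3"):
            c = truth["profiles"][(occ, "rif")]
            idx = np.clip(np.searchsorted(tg, t_cpi), 0, tg.size - 1)
            prof[occ] = np.where(t_cpi[None, :] < 0, 0.0, c[:, idx])
        model = CpiModel(df, copy.deepcopy(cpi), rif_profiles=prof, dt=dt)
        theta0 = {n: getattr(cpi.fixed, n) for n in model.theta_names}
        start = {k: v * f for (k, v), f in
                 zip(theta0.items(), (1.3, 0.8, 1.2, 1.0, 0.8, 1.4))}
        fit = fit_fixed_effects(model, theta0=start, xtol=3e-3, ftol=5e-3, maxfev=180)
        start_ofv = model.neg2ll(start, warm=False).ofv
        assert fit.ofv < start_ofv
        for name in ("ksyn", "CLb", "CLR", "Ki"):
            assert abs(fit.estimates[name] / theta0[name] - 1) < 0.30, name

    def test_marginal_neg2ll_convenience(self, trial_df, models):
        rif, _, _ = models
        ofv = marginal_neg2ll(trial_df, copy.deepcopy(rif), compound="rif")
        assert np.isfinite(ofv)

    def test_rsv_truth_beats_perturbation(self, trial_df, models, rif_grid_profile):
        rif, _, rsv = models
        t, cg = rif_grid_profile
        dt = 0.1
        tg = np.arange(0.0, 24.0 + dt / 2, dt)
        # typical perpetrator exposure for every subject (smoke-level check)
        prof = {"OCC3": np.tile(np.interp(tg, t, cg), (12, 1))}
        model = RsvModel(trial_df, copy.deepcopy(rsv), rif_profiles=prof, dt=dt)
        theta = {n: getattr(rsv.fixed, n) for n in model.theta_names}
        base = model.neg2ll(theta, warm=False).ofv
        pert = dict(theta, CLb=theta["CLb"] * 2.0)
        assert model.neg2ll(pert).ofv > base

    def test_likelihood_ratio_test(self):
        assert likelihood_ratio_test(100.0, 103.84, df=1) == pytest.approx(0.05, abs=1e-3)
        assert likelihood_ratio_test(100.0, 100.0, df=1) == 1.0


class TestProfileLikelihood:
    def test_minimum_at_fitted_estimate(self, design, models):
        rif, cpi, _ = models
        df, truth = simulate_trial(design, rif, cpi, None, seed=51, return_truth=True)
        dt = 0.1
        t_cpi = np.arange(-7.0, 24.0 + dt / 2, dt)
        tg = truth["t_grid"]
        prof = {}
        for occ in ("OCC1", "OCC3"):
            c = truth["profiles"][(occ, "rif")]
            idx = np.clip(np.searchsorted(tg, t_cpi), 0, tg.size - 1)
            prof[occ] = np.where(t_cpi[None, :] < 0, 0.0, c[:, idx])
        model = CpiModel(df, copy.deepcopy(cpi), rif_profiles=prof, dt=dt)
        fit = fit_fixed_effects(model, xtol=3e-3, ftol=5e-3, maxfev=150)
        vhat = fit.estimates["V_rif"]
        grid = vhat * np.array([0.6, 0.8, 1.0, 1.25, 1.6])
        profl = profile_likelihood(model, fit.theta, "V_rif", grid,
                                   xtol=3e-3, ftol=5e-3)
        assert profl["delta_ofv"].iloc[2] <= 1.0  # minimum at/near the estimate
        assert profl["delta_ofv"].iloc[0] > profl["delta_ofv"].iloc[2]
        assert profl["delta_ofv"].iloc[-1] > profl["delta_ofv"].iloc[2]


class TestDiagnostics:
    def test_vpc_bands_and_calibration(self, design, models, trial_df):
        from copropk.diagnostics import vpc

        rif, cpi, _ = models
        bundle = vpc(trial_df, design, rif, cpi, None, n_replicates=200,
                     seed=13, streams=("cpi_plasma",), dt=0.05)
        bands = bundle.vpc_bands
        assert (bands["p2.5"] <= bands["p50"]).all()
        assert (bands["p50"] <= bands["p97.5"]).all()
        # self-VPC: the observed medians fall inside the 95% band of
        # simulated medians for the vast majority of time bins
        inside = ((bands["obs_median"] >= bands["median_lo"])
                  & (bands["obs_median"] <= bands["median_hi"]))
        assert inside.mean() >= 0.8

    def test_vpc_zero_variance_bands_collapse(self, design, zero_var_models):
        from copropk.diagnostics import vpc
        from copropk.population import PopulationModel, ResidualErrorSpec

        rif0, cpi0, _ = zero_var_models
        cpi_nf = PopulationModel(
            fixed=cpi0.fixed, re=cpi0.re,
            err=ResidualErrorSpec({"cpi_plasma": (1e-12, 1e-12),
                                   "cpi_urine": (1e-12, 1e-12)}))
        rif_nf = PopulationModel(
            fixed=rif0.fixed, re=rif0.re,
            err=ResidualErrorSpec({"rif_plasma": (1e-12, 1e-12)}))
        bundle = vpc(None, design, rif_nf, cpi_nf, None, n_replicates=20,
                     seed=1, streams=("cpi_plasma",), dt=0.05)
        width = bundle.vpc_bands["p97.5"] - bundle.vpc_bands["p2.5"]
        assert np.max(width) < 1e-9

    def test_band_width_grows_with_residual_error(self, design, models):
        from copropk.diagnostics import vpc
        from copropk.population import PopulationModel, ResidualErrorSpec

        rif, cpi, _ = models
        widths = []
        for sp in (0.1, 0.3):
            cpi_mod = PopulationModel(
                fixed=cpi.fixed, re=cpi.re,
                err=ResidualErrorSpec({"cpi_plasma": (sp, 0.001),
                                       "cpi_urine": cpi.err.streams["cpi_urine"]}))
            b = vpc(None, design, rif, cpi_mod, None, n_replicates=60,
                    seed=2, streams=("cpi_plasma",), dt=0.05)
            widths.append((b.vpc_bands["p97.5"] - b.vpc_bands["p2.5"]).mean())
        assert widths[1] > widths[0]

    def test_residual_table_columns(self, trial_df, models):
        from copropk.diagnostics import residual_table

        rif, _, _ = models
        model = RifModel(trial_df, copy.deepcopy(rif), dt=0.1)
        theta = {n: getattr(rif.fixed, n) for n in model.theta_names}
        tab = residual_table(model, theta)
        assert set(tab.columns) >= {"DV", "PRED", "IPRED", "IWRES", "CWRES"}
        assert len(tab) == model.y.size
        # individual predictions track the data better than population ones
        assert np.abs(tab["IWRES"]).median() < 2.0
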