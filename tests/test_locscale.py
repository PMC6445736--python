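import numpy as np
import pandas as pd
import pytest

from bpvar import (AnalysisDataset, LongitudinalData, McmcConfig, ModelSpec,
                   SimConfig, SurvivalData, fit_locscale, naive_estimates,
                   simulate_dataset, subject_effects)
from bpvar.mcmc import PosteriorDraws


def _dataset_from_arrays(ids, times, values, surv_time=30.0):
    long = LongitudinalData(pd.DataFrame({"id": ids, "time": times, "value": values}))
    uids = pd.unique(pd.Series(ids))
    surv = SurvivalData(pd.DataFrame({"id": uids, "time": surv_time, "status": 0}))
    return AnalysisDataset(long, surv)


FIX_POP = dict(beta=[120.0], mu_sigma=2.0, tau0=15.0, tau_sigma=0.5, rho=0.5)


class TestSubjectPosteriorOracle:
    def test_matches_2d_quadrature(self):
        """Subject-level conditional posterior vs brute-force grid integration.

        One subject with two measurements, population parameters fixed; the
        sampler is run on many identical independent replicas, which gives
        independent draws from the same two-dimensional posterior.
        """
        y = np.array([115.0, 131.0])
        nrep = 800
        ds = _dataset_from_arrays(np.repeat(np.arange(nrep), 2),
                                  np.tile([0.0, 6.0], nrep),
                                  np.tile(y, nrep))
        draws = fit_locscale(ds, "lmm2",
                             McmcConfig(chains=2, burn_in=500, n_keep=1500, seed=3),
                             fix_population=FIX_POP)
        b = draws.stacked("b").ravel()
        s = draws.stacked("sigma").ravel()

        bg = np.linspace(60, 180, 601)
        lg = np.linspace(-0.5, 4.5, 601)
        B, L = np.meshgrid(bg, lg, indexing="ij")
        zb, zl = (B - 120) / 15.0, (L - 2.0) / 0.5
        rho = 0.5
        logp = -(zb ** 2 - 2 * rho * zb * zl + zl ** 2) / (2 * (1 - rho ** 2))
        sig = np.exp(L)
        logp += sum(-np.log(sig) - (yy - B) ** 2 / (2 * sig ** 2) for yy in y)
        post = np.exp(logp - logp.max())
        post /= post.sum()

        e_b = (post * B).sum()
        e_s = (post * np.exp(L)).sum()
        assert b.mean() == pytest.approx(e_b, abs=0.05)
        assert s.mean() == pytest.approx(e_s, abs=0.05)

        edges_b = np.linspace(80, 170, 31)
        edges_l = np.linspace(0.5, 4.0, 31)
        hist, _, _ = np.histogram2d(b, np.log(s), bins=[edges_b, edges_l])
        hist /= hist.sum()
        ib = np.searchsorted(edges_b, B) - 1
        il = np.searchsorted(edges_l, L) - 1
        ok = (ib >= 0) & (ib < 30) & (il >= 0) & (il < 30)
        q = np.zeros((30, 30))
        np.add.at(q, (ib[ok], il[ok]), post[ok])
        q /= q.sum()
        tv = 0.5 * np.abs(hist - q).sum()
        assert tv < 0.01

    def test_degenerate_chain_effects_equal_draw(self):
        draws = PosteriorDraws(
            params={"b": np.full((1, 10, 3), 7.0), "sigma": np.full((1, 10, 3), 2.5)},
            subject_ids=np.array([1, 2, 3]), config=McmcConfig(chains=1))
        eff = subject_effects(draws)
        np.testing.assert_allclose(eff.df["bp_hat"], 7.0)
        np.testing.assert_allclose(eff.df["sd_hat"], 2.5)

    def test_missing_subject_draws_rejected(self):
        draws = PosteriorDraws(params={"mu_sigma": np.zeros((1, 10))},
                               subject_ids=np.array([]), config=McmcConfig(chains=1))
        with pytest.raises(ValueError, match="per-subject"):
            subject_effects(draws)


class TestDegenerateHeteroscedasticity:
    def test_tau_sigma_zero_data(self):
        # all subjects share sigma = e^2: the scale-spread posterior must
        # collapse and the subject SDs concentrate near the common value
        ds, _ = simulate_dataset(SimConfig(n_subjects=400, tau_sigma=0.0, rho=0.0,
                                           seed=13))
        draws = fit_locscale(ds, "lmm1",
                             McmcConfig(chains=1, burn_in=600, n_keep=600, seed=2))
        assert draws.mean("tau_sigma") < 0.1
        sd_hat = subject_effects(draws).df["sd_hat"]
        assert np.abs(np.log(sd_hat) - 2.0).mean() < 0.1


class TestParameterRecovery:
    def test_scenario1_population_parameters(self, scenario1_dataset):
        ds, _ = scenario1_dataset
        draws = fit_locscale(ds, "lmm2",
                             McmcConfig(chains=1, burn_in=800, n_keep=800, seed=4))
        truth = {"mu_sigma": 2.0, "tau_sigma": 0.5, "tau0": 15.0, "rho": 0.5}
        for name, val in truth.items():
            post_mean, post_sd = draws.mean(name), draws.sd(name)
            assert abs(post_mean - val) < 3 * post_sd, name
        assert abs(draws.mean("beta")[0] - 120.0) < 3 * draws.sd("beta")[0]

    def test_slope_model_recovers_time_trend(self, rng):
        # slopes identifiable: per-subject slope SE ~ sigma/sqrt(40) ~ 0.16,
        # well below the population slope SD of 0.5
        n, m = 300, 5
        t = np.tile(np.array([0.0, 2.0, 4.0, 6.0, 8.0]), n)
        b0 = rng.normal(120, 10, n)
        b1 = rng.normal(1.0, 0.5, n)
        sig = np.exp(rng.normal(0.0, 0.25, n))
        y = (np.repeat(b0, m) + np.repeat(b1, m) * t
             + rng.normal(size=n * m) * np.repeat(sig, m))
        ds = _dataset_from_arrays(np.repeat(np.arange(n), m), t, y)
        draws = fit_locscale(ds, "lmm3",
                             McmcConfig(chains=1, burn_in=1500, n_keep=1000, seed=6))
        assert abs(draws.mean("beta_t") - 1.0) < 3 * max(draws.sd("beta_t"), 0.02)
        assert draws.mean("tau1") == pytest.approx(0.5, abs=0.12)
        assert draws.mean("mu_sigma") == pytest.approx(0.0, abs=0.12)
        eff = subject_effects(draws)
        assert np.corrcoef(eff.df["slope_hat"], b1)[0, 1] > 0.85


class TestShrinkage:
    def test_sd_hat_shrinks_toward_population(self, scenario1_dataset):
        ds, _ = scenario1_dataset
        draws = fit_locscale(ds, "lmm2",
                             McmcConfig(chains=1, burn_in=600, n_keep=600, seed=5))
        eff = subject_effects(draws)
        nav = naive_estimates(ds.longitudinal, ddof=1).df.set_index("id")
        merged = eff.df.set_index("id").join(nav, how="inner")
        assert merged["sd_hat"].var() < merged["sd"].var()
        # most subjects sit between the population centre and their own SD
        centre = np.exp(draws.mean("mu_sigma"))
        lo = np.minimum(centre, merged["sd"])
        hi = np.maximum(centre, merged["sd"])
        frac_between = ((merged["sd_hat"] >= lo) & (merged["sd_hat"] <= hi)).mean()
        assert frac_between > 0.5

    def test_more_measurements_less_shrinkage(self):
        rel_dist = {}
        for n_visits in (4, 10):
            ds, _ = simulate_dataset(SimConfig(n_subjects=400, n_visits=n_visits,
                                               seed=50 + n_visits))
            draws = fit_locscale(ds, "lmm2",
                                 McmcConfig(chains=1, burn_in=500, n_keep=500,
                                            seed=n_visits))
            eff = subject_effects(draws).df.set_index("id")
            nav = naive_estimates(ds.longitudinal, ddof=1).df.set_index("id")
            j = eff.join(nav, how="inner")
            rel_dist[n_visits] = float(np.mean(np.abs(j["sd_hat"] - j["sd"]) / j["sd"]))
        assert rel_dist[10] < rel_dist[4]


class TestSpecificationRobustness:
    def test_lmm1_lmm2_agree_on_uncorrelated_data(self):
        ds, _ = simulate_dataset(SimConfig(n_subjects=500, rho=0.0, seed=23))
        mc = McmcConfig(chains=1, burn_in=600, n_keep=600, seed=9)
        d1 = fit_locscale(ds, "lmm1", mc)
        d2 = fit_locscale(ds, "lmm2", mc)
        for name in ("mu_sigma", "tau_sigma"):
            lo1, hi1 = d1.quantile(name, [0.025, 0.975])
            lo2, hi2 = d2.quantile(name, [0.025, 0.975])
            assert max(lo1, lo2) < min(hi1, hi2), name  # central intervals overlap

    def test_subject_order_invariance(self):
        ds, _ = simulate_dataset(SimConfig(n_subjects=300, seed=44))
        perm_df = ds.longitudinal.df.copy()
        perm_df["id"] = -perm_df["id"]  # reverses subject iteration order
        ds_perm = AnalysisDataset(
            LongitudinalData(perm_df),
            SurvivalData(ds.survival.df.assign(id=-ds.survival.df["id"])))
        mc = McmcConfig(chains=1, burn_in=600, n_keep=800, seed=10)
        d1 = fit_locscale(ds, "lmm2", mc)
        d2 = fit_locscale(ds_perm, "lmm2", mc)
        for name in ("mu_sigma", "tau_sigma", "tau0", "rho"):
            tol = 0.5 * (d1.sd(name) + d2.sd(name))
            assert abs(d1.mean(name) - d2.mean(name)) < tol, name


class TestModelSpec:
    def test_standard_names(self):
        assert ModelSpec.from_name("lmm1") == ModelSpec(has_slope=False, correlated=False)
        assert ModelSpec.from_name("LMM4") == ModelSpec(has_slope=True, correlated=True)
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec.from_name("lmm9")

    def test_shared_slope_requires_slope(self):
        with pytest.raises(ValueError, match="slope"):
            ModelSpec(has_slope=False, shared_effects=("level", "sd", "slope"))
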