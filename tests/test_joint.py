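import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import norm

from bpvar import (AnalysisDataset, HazardParams, LongitudinalData, McmcConfig,
                   SimConfig, SurvivalData, cumulative_hazard, fit_joint,
                   fit_locscale, hazard_cutpoints, joint_loglik,
                   simulate_dataset)


class TestCutpoints:
    def test_interior_quantiles(self):
        ev = np.arange(1.0, 16.0)  # 1..15
        cp = hazard_cutpoints(ev, 3)
        expected = np.quantile(ev, [1 / 3, 2 / 3])
        np.testing.assert_allclose(cp, [0.0, *expected, 15.0])

    def test_single_interval_constant_baseline(self):
        cp = hazard_cutpoints(np.array([2.0, 5.0, 9.0]), 1)
        np.testing.assert_allclose(cp, [0.0, 9.0])

    def test_too_few_events(self):
        with pytest.raises(ValueError, match="smaller number of intervals"):
            hazard_cutpoints(np.array([1.0, 2.0]), 5)

    def test_t_max_override(self):
        cp = hazard_cutpoints(np.array([1.0, 2.0, 3.0, 4.0]), 2, t_max=20.0)
        assert cp[-1] == 20.0


class TestCumulativeHazard:
    def test_zero_at_origin(self):
        hp = HazardParams(cutpoints=np.array([0.0, 1.0, 2.0]), h0=np.array([0.3, 0.7]))
        assert cumulative_hazard(0.0, 0.0, hp) == 0.0

    def test_single_interval_exponential(self):
        hp = HazardParams(cutpoints=np.array([0.0, 5.0]), h0=np.array([0.4]))
        eta = 0.3
        for t in (0.5, 3.0, 12.0):  # including beyond the last cutpoint
            assert cumulative_hazard(t, eta, hp) == pytest.approx(
                0.4 * t * np.exp(eta), rel=1e-12)

    def test_matches_numerical_quadrature(self, rng):
        cuts = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 9.5, 6)), [10.0]])
        h0 = rng.uniform(0.05, 1.5, 7)
        hp = HazardParams(cutpoints=cuts, h0=h0)

        def hazard(t):
            idx = min(np.searchsorted(cuts, t, side="left") - 1, len(h0) - 1)
            return h0[max(idx, 0)]

        eta = -0.4
        for t in (0.3, 2.7, 6.1, 9.99, 10.0):
            num, _ = integrate.quad(hazard, 0, t, points=cuts[cuts < t], limit=200)
            assert cumulative_hazard(t, eta, hp) == pytest.approx(
                num * np.exp(eta), abs=1e-10, rel=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError):
            HazardParams(cutpoints=np.array([0.0, 2.0, 1.0]), h0=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            HazardParams(cutpoints=np.array([0.0, 1.0]), h0=np.array([-1.0]))


class TestJointLoglik:
    def test_hand_assembled_tiny_dataset(self, rng):
        # 5 subjects, 2 visits: sum of normal log-densities plus
        # piecewise-exponential survival terms, assembled by hand
        n = 5
        ids = np.repeat(np.arange(n), 2)
        times = np.tile([0.0, 2.0], n)
        level = rng.normal(120, 10, n)
        sigma = rng.uniform(4, 12, n)
        y = level[ids] + rng.normal(size=2 * n) * sigma[ids]
        t_star = np.array([1.5, 4.0, 6.0, 8.0, 10.0])
        delta = np.array([1, 0, 1, 1, 0])
        ds = AnalysisDataset(
            LongitudinalData(pd.DataFrame({"id": ids, "time": times, "value": y})),
            SurvivalData(pd.DataFrame({"id": np.arange(n), "time": t_star,
                                       "status": delta})))
        cuts = np.array([0.0, 3.0, 7.0, 10.0])
        h0 = np.array([0.02, 0.05, 0.03])
        hp = HazardParams(cutpoints=cuts, h0=h0, alpha_level=0.02, alpha_sd=0.05)

        expected = 0.0
        for i in range(n):
            for j in range(2):
                expected += norm.logpdf(y[2 * i + j], level[i], sigma[i])
            eta = 0.02 * level[i] + 0.05 * sigma[i]
            big_h = sum(h * max(0.0, min(t_star[i], hi) - lo)
                        for h, lo, hi in zip(h0, cuts[:-1], cuts[1:]))
            if delta[i]:
                k = np.searchsorted(cuts, t_star[i], side="left") - 1
                expected += np.log(h0[k]) + eta
            expected -= np.exp(eta) * big_h
        assert joint_loglik(ds, level, sigma, hp) == pytest.approx(expected, rel=1e-12)


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_dataset(SimConfig(n_subjects=400, seed=99))


class TestFitJoint:
    def test_zero_association_factorises(self, small_cohort):
        # with the association coefficients pinned at 0 the likelihood
        # factorises and the longitudinal posterior matches the mixed model
        ds, _ = small_cohort
        mc = McmcConfig(chains=1, burn_in=600, n_keep=600, seed=11)
        dj = fit_joint(ds, "jm2", n_intervals=5, mcmc=mc,
                       fix_population={"alpha_level": 0.0, "alpha_sd": 0.0})
        dl = fit_locscale(ds, "lmm2", mc)
        for name in ("mu_sigma", "tau_sigma", "tau0", "rho"):
            tol = 0.6 * (dj.sd(name) + dl.sd(name))
            assert abs(dj.mean(name) - dl.mean(name)) < tol, name

    @staticmethod
    def _per_draw_surv(draws, ds, k, fn, stride=8):
        """Average a per-draw survival functional over thinned draws."""
        cuts = hazard_cutpoints(
            ds.survival.df.loc[ds.survival.df.status == 1, "time"].to_numpy(),
            k, t_max=float(ds.survival.df.time.max()))
        t_star = ds.survival.df["time"].to_numpy()
        out = []
        h0s = draws.stacked("h0")
        als = draws.stacked("alpha_level")
        asd = draws.stacked("alpha_sd")
        bs = draws.stacked("b")
        sgs = draws.stacked("sigma")
        for i in range(0, len(als), stride):
            hp = HazardParams(cutpoints=cuts, h0=h0s[i],
                              alpha_level=float(als[i]), alpha_sd=float(asd[i]))
            eta = als[i] * bs[i] + asd[i] * sgs[i]
            out.append(fn(hp, eta, t_star))
        return float(np.mean(out))

    def test_recovers_associations_and_calibrates(self, small_cohort):
        ds, eff = small_cohort
        draws = fit_joint(ds, "jm2", n_intervals=5,
                          mcmc=McmcConfig(chains=1, burn_in=1500, n_keep=800,
                                          thin=2, seed=12))
        # truth 0.02 / 0.05; N=400 so intervals are wide
        lo, hi = draws.quantile("alpha_sd", [0.005, 0.995])
        assert lo < 0.05 < hi
        lo0, hi0 = draws.quantile("alpha_level", [0.005, 0.995])
        assert lo0 < 0.02 < hi0

        # martingale calibration: the posterior-averaged sum of cumulative
        # hazards at the observed follow-up times estimates the event count
        expected_events = self._per_draw_surv(
            draws, ds, 5,
            lambda hp, eta, t: cumulative_hazard(t, eta, hp).sum())
        assert expected_events == pytest.approx(ds.survival.n_events, rel=0.15)

    def test_more_intervals_fit_at_least_as_well(self, small_cohort):
        # Weibull-generated data: a 5-interval baseline tracks the
        # increasing hazard better than a single exponential interval
        ds, _ = small_cohort
        mc = McmcConfig(chains=1, burn_in=800, n_keep=600, seed=13)

        def surv_ll(hp, eta, t_star):
            delta = ds.survival.df["status"].to_numpy()
            idx = np.minimum(np.searchsorted(hp.cutpoints, t_star, side="left") - 1,
                             len(hp.h0) - 1)
            big_h = cumulative_hazard(t_star, eta, hp)
            return float(np.sum(delta * (np.log(hp.h0[idx]) + eta) - big_h))

        lls = {k: self._per_draw_surv(fit_joint(ds, "jm2", n_intervals=k, mcmc=mc),
                                      ds, k, surv_ll)
               for k in (1, 5)}
        assert lls[5] >= lls[1]

    def test_too_many_intervals_rejected(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError, match="intervals"):
            fit_joint(ds, "jm2", n_intervals=10_000,
                      mcmc=McmcConfig(chains=1, burn_in=10, n_keep=10, seed=1))
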