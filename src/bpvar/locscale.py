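"""Bayesian location-scale mixed models with subject-specific residual SDs.

The longitudinal model is

    Y_ij = beta' X_i (+ beta_t t_ij) + b0_i (+ b1_i t_ij) + eps_ij,
    eps_ij ~ N(0, sigma_i^2),

with a log-normal law for the residual SD, ``log sigma_i ~ N(mu_sigma,
tau_sigma^2)``, and the random effects and ``log sigma_i`` jointly
multivariate normal.  Four standard specifications are provided:

* ``lmm1`` -- random intercept, no intercept/log-SD correlation;
* ``lmm2`` -- random intercept, correlation ``rho`` free;
* ``lmm3`` -- random intercept and slope, intercept-slope correlation free,
  random effects independent of the log-SD;
* ``lmm4`` -- random intercept and slope, fully unstructured correlation.

Internally the intercept (and slope) are *hierarchically centred*: the
subject-level state carries the subject's usual level directly (population
mean ``beta' X_i``) rather than a zero-mean deviation, which decorrelates
the fixed effects from the random effects and is what makes the Gibbs
updates mix well.

Sampling is Metropolis-within-Gibbs: the usual level (and slope) have
conjugate Gaussian full conditionals given ``sigma_i``; ``log sigma_i``
and the population SD/correlation parameters use adaptive random-walk
steps; the population means are a joint conjugate Gaussian block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AnalysisDataset
from .mcmc import AdaptiveScale, McmcConfig, PosteriorDraws, gelman_rubin, spawn_rngs

logger = logging.getLogger("bpvar")

__all__ = ["ModelSpec", "LocScaleParams", "SubjectEffects",
           "fit_locscale", "subject_effects"]

_STANDARD_SPECS = {
    "lmm1": dict(has_slope=False, correlated=False),
    "lmm2": dict(has_slope=False, correlated=True),
    "lmm3": dict(has_slope=True, correlated=False),
    "lmm4": dict(has_slope=True, correlated=True),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which location-scale model to fit and how it links to a hazard.

    ``correlated`` frees the correlation(s) between random effects and the
    log residual SD.  ``shared_effects`` names the subject-level quantities
    entering a joint model's hazard: any of ``"level"``, ``"sd"``,
    ``"slope"`` (the residual SD enters on its natural mmHg scale).
    """

    has_slope: bool = False
    correlated: bool = False
    fixed_covariates: tuple[str, ...] = ()
    shared_effects: tuple[str, ...] = ("level", "sd")

    def __post_init__(self) -> None:
        bad = set(self.shared_effects) - {"level", "sd", "slope"}
        if bad:
            raise ValueError(f"unknown shared effects {sorted(bad)}")
        if "slope" in self.shared_effects and not self.has_slope:
            raise ValueError("shared slope requires has_slope=True")

    @classmethod
    def from_name(cls, name: str, **kw) -> "ModelSpec":
        try:
            base = _STANDARD_SPECS[name.lower()]
        except KeyError:
            raise ValueError(f"unknown model {name!r}; expected one of {sorted(_STANDARD_SPECS)}")
        return cls(**base, **kw)


@dataclass(frozen=True)
class LocScaleParams:
    """Population parameters of a location-scale model (for simulation
    truth, initial values, or fixing parameters in a fit)."""

    beta: np.ndarray = field(default_factory=lambda: np.array([120.0]))
    beta_t: float = 0.0
    mu_sigma: float = 2.0
    tau0: float = 15.0
    tau1: float = 0.0
    tau_sigma: float = 0.5
    rho: float = 0.0     # level-logSD (intercept-only models)
    rho01: float = 0.0   # level-slope
    rho0s: float = 0.0   # level-logSD (slope models)
    rho1s: float = 0.0   # slope-logSD


@dataclass(frozen=True)
class SubjectEffects:
    """Posterior-mean subject-level quantities: usual level ``bp_hat``,
    residual SD ``sd_hat`` and, when modelled, slope ``slope_hat``."""

    df: pd.DataFrame


def _as_pop_matrix(state: dict, has_slope: bool) -> np.ndarray:
    """Assemble the population covariance of (level, [slope,] log sigma)."""
    t0, ts = state["tau0"], state["tau_sigma"]
    if not has_slope:
        r = state["rho"]
        return np.array([[t0 ** 2, r * t0 * ts],
                         [r * t0 * ts, ts ** 2]])
    t1 = state["tau1"]
    r01, r0s, r1s = state["rho01"], state["rho0s"], state["rho1s"]
    return np.array([
        [t0 ** 2, r01 * t0 * t1, r0s * t0 * ts],
        [r01 * t0 * t1, t1 ** 2, r1s * t1 * ts],
        [r0s * t0 * ts, r1s * t1 * ts, ts ** 2],
    ])


def _is_pd(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


class LocScaleSampler:
    """Metropolis-within-Gibbs sampler for the location-scale mixed model.

    Subclasses (the joint model) hook into the subject-level updates via
    :meth:`_survival_loglik` and extend the sweep via :meth:`_update_extra`.
    """

    def __init__(self, data: AnalysisDataset, spec: ModelSpec, mcmc: McmcConfig,
                 fix_population: dict | None = None):
        self.spec = spec
        self.mcmc = mcmc
        self.priors = mcmc.priors
        self.fix = dict(fix_population or {})

        ids, codes, t, y = data.longitudinal.arrays()
        if len(ids) == 0:
            raise ValueError("no longitudinal measurements")
        self.ids = ids
        self.n_subj = len(ids)
        # per-subject sufficient statistics (fixed throughout sampling)
        self.n_i = np.bincount(codes, minlength=self.n_subj).astype(float)
        self.sy = np.bincount(codes, weights=y, minlength=self.n_subj)
        self.syy = np.bincount(codes, weights=y * y, minlength=self.n_subj)
        self.st = np.bincount(codes, weights=t, minlength=self.n_subj)
        self.stt = np.bincount(codes, weights=t * t, minlength=self.n_subj)
        self.sty = np.bincount(codes, weights=t * y, minlength=self.n_subj)

        # fixed-effect design: intercept plus named baseline covariates
        if spec.fixed_covariates:
            if data.covariates is None:
                raise ValueError("spec names fixed covariates but dataset has none")
            cov = data.covariates.df.set_index("id").loc[ids, list(spec.fixed_covariates)]
            self.x = np.column_stack([np.ones(self.n_subj), cov.to_numpy(float)])
        else:
            self.x = np.ones((self.n_subj, 1))
        self.p = self.x.shape[1]

        # which covariance parameters are active under this spec
        if spec.has_slope:
            self.cov_names = ["tau0", "tau1", "tau_sigma", "rho01"]
            if spec.correlated:
                self.cov_names += ["rho0s", "rho1s"]
        else:
            self.cov_names = ["tau0", "tau_sigma"]
            if spec.correlated:
                self.cov_names += ["rho"]
        self.cov_names = [c for c in self.cov_names if c not in self.fix]

        self.scale_ell = AdaptiveScale(self.n_subj, initial=0.5, target=0.35)
        self.scale_cov = AdaptiveScale(len(self.cov_names), initial=0.05, target=0.35)

    # -- hooks for the joint model -------------------------------------
    def _survival_loglik(self, level, slope, sigma):
        """Per-subject survival log-likelihood contribution (0 for the
        longitudinal-only model)."""
        return 0.0

    def _update_extra(self, state, rng, adapt):
        pass

    def _extra_draw_names(self) -> dict:
        return {}

    # -- initialisation ------------------------------------------------
    def initial_state(self, rng) -> dict:
        n = np.maximum(self.n_i, 1.0)
        mean_i = self.sy / n
        with np.errstate(invalid="ignore", divide="ignore"):
            var_i = np.maximum(self.syy / n - mean_i ** 2, 0.0)
        sd_i = np.sqrt(var_i)
        ell0 = np.log(np.where((self.n_i >= 2) & (sd_i > 0), sd_i, np.nan))
        ell_fill = np.nanmean(ell0) if np.isfinite(np.nanmean(ell0)) else 0.0
        ell0 = np.where(np.isfinite(ell0), ell0, ell_fill)

        beta0, *_ = np.linalg.lstsq(self.x, mean_i, rcond=None)
        state = {
            "level": mean_i.copy(),
            "slope": np.zeros(self.n_subj) if self.spec.has_slope else None,
            "ell": ell0 + 0.05 * rng.standard_normal(self.n_subj),
            "beta": beta0,
            "beta_t": 0.0,
            "mu_sigma": float(np.mean(ell0)),
            "tau0": max(float(np.std(mean_i)), 0.5),
            "tau1": 0.5,
            "tau_sigma": max(float(np.std(ell0)), 0.1),
            "rho": 0.0, "rho01": 0.0, "rho0s": 0.0, "rho1s": 0.0,
        }
        for k, v in self.fix.items():
            state[k] = np.asarray(v, dtype=float) if k == "beta" else float(v)
        # mild overdispersion across chains
        state["mu_sigma"] += 0.05 * rng.standard_normal() if "mu_sigma" not in self.fix else 0.0
        return state

    # -- conditional pieces --------------------------------------------
    def _prior_cond_level(self, state):
        """Mean and variance of level_i | (slope_i,) ell_i under the
        population law (vectorised over subjects)."""
        xb = self.x @ state["beta"]
        sig = _as_pop_matrix(state, self.spec.has_slope)
        if not self.spec.has_slope:
            v_ll = sig[1, 1]
            if v_ll <= 0:
                return xb, np.full(self.n_subj, sig[0, 0])
            k = sig[0, 1] / v_ll
            mean = xb + k * (state["ell"] - state["mu_sigma"])
            var = sig[0, 0] - k * sig[0, 1]
            return mean, np.full(self.n_subj, max(var, 1e-12))
        # condition level on (slope, ell)
        s22 = sig[1:, 1:]
        s12 = sig[0, 1:]
        sol = np.linalg.solve(s22, s12)
        resid = np.column_stack([state["slope"] - state["beta_t"],
                                 state["ell"] - state["mu_sigma"]])
        mean = xb + resid @ sol
        var = sig[0, 0] - s12 @ sol
        return mean, np.full(self.n_subj, max(var, 1e-12))

    def _prior_cond_slope(self, state):
        sig = _as_pop_matrix(state, True)
        s22 = np.array([[sig[0, 0], sig[0, 2]], [sig[2, 0], sig[2, 2]]])
        s12 = np.array([sig[1, 0], sig[1, 2]])
        sol = np.linalg.solve(s22, s12)
        resid = np.column_stack([state["level"] - self.x @ state["beta"],
                                 state["ell"] - state["mu_sigma"]])
        mean = state["beta_t"] + resid @ sol
        var = sig[1, 1] - s12 @ sol
        return mean, np.full(self.n_subj, max(var, 1e-12))

    def _prior_cond_ell(self, state):
        sig = _as_pop_matrix(state, self.spec.has_slope)
        if not self.spec.has_slope:
            v = sig[0, 0]
            k = sig[0, 1] / v
            mean = state["mu_sigma"] + k * (state["level"] - self.x @ state["beta"])
            var = sig[1, 1] - k * sig[0, 1]
        else:
            s22 = sig[:2, :2]
            s12 = sig[2, :2]
            sol = np.linalg.solve(s22, s12)
            resid = np.column_stack([state["level"] - self.x @ state["beta"],
                                     state["slope"] - state["beta_t"]])
            mean = state["mu_sigma"] + resid @ sol
            var = sig[2, 2] - s12 @ sol
        return mean, max(var, 1e-12)

    def _sse(self, level, slope):
        if slope is None:
            return self.syy - 2 * level * self.sy + self.n_i * level ** 2
        return (self.syy - 2 * level * self.sy - 2 * slope * self.sty
                + self.n_i * level ** 2 + 2 * level * slope * self.st
                + slope ** 2 * self.stt)

    # -- updates --------------------------------------------------------
    def _gibbs_level_proposal(self, state, rng):
        """Draw from the Gaussian full conditional of level_i given the
        longitudinal data and the population prior (exact for the LMM)."""
        pm, pv = self._prior_cond_level(state)
        inv_s2 = np.exp(-2.0 * state["ell"])
        if state["slope"] is None:
            lik_prec = self.n_i * inv_s2
            lik_mean_num = self.sy * inv_s2
        else:
            lik_prec = self.n_i * inv_s2
            lik_mean_num = (self.sy - state["slope"] * self.st) * inv_s2
        prec = 1.0 / pv + lik_prec
        mean = (pm / pv + lik_mean_num) / prec
        return mean + rng.standard_normal(self.n_subj) / np.sqrt(prec)

    def _update_level(self, state, rng):
        state["level"] = self._gibbs_level_proposal(state, rng)

    def _gibbs_slope_proposal(self, state, rng):
        pm, pv = self._prior_cond_slope(state)
        inv_s2 = np.exp(-2.0 * state["ell"])
        lik_prec = self.stt * inv_s2
        lik_mean_num = (self.sty - state["level"] * self.st) * inv_s2
        prec = 1.0 / pv + lik_prec
        mean = (pm / pv + lik_mean_num) / prec
        return mean + rng.standard_normal(self.n_subj) / np.sqrt(prec)

    def _update_slope(self, state, rng):
        state["slope"] = self._gibbs_slope_proposal(state, rng)

    def _update_ell(self, state, rng, adapt):
        cur = state["ell"]
        cm, cv = self._prior_cond_ell(state)
        sse = self._sse(state["level"], state["slope"])
        sigma_cur = np.exp(cur)

        def logpost(ell, sigma):
            lp = (-self.n_i * ell - 0.5 * sse * np.exp(-2.0 * ell)
                  - (ell - cm) ** 2 / (2.0 * cv))
            return lp + self._survival_loglik(state["level"], state["slope"], sigma)

        prop = np.clip(cur + self.scale_ell.scale * rng.standard_normal(self.n_subj), -40.0, 40.0)
        with np.errstate(over="ignore"):
            lp_cur = logpost(cur, sigma_cur)
            lp_prop = logpost(prop, np.exp(prop))
        acc = np.log(rng.uniform(size=self.n_subj)) < lp_prop - lp_cur
        state["ell"] = np.where(acc, prop, cur)
        if adapt:
            self.scale_ell.update(acc)

    def _update_means(self, state, rng):
        """Joint conjugate Gaussian block for (beta, beta_t, mu_sigma)."""
        has_slope = self.spec.has_slope
        sig = _as_pop_matrix(state, has_slope)
        lam = np.linalg.inv(sig)
        k = sig.shape[0]
        p = self.p
        dim = p + (2 if has_slope else 1)

        # z_i = (level, [slope,] ell); m_i = (X beta, [beta_t,] mu_sigma)
        z = [state["level"]] + ([state["slope"]] if has_slope else []) + [state["ell"]]
        xtx = self.x.T @ self.x
        sx = self.x.sum(axis=0)

        prec = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        prec[:p, :p] = lam[0, 0] * xtx
        for a in range(1, k):
            prec[:p, p + a - 1] = lam[0, a] * sx
            prec[p + a - 1, :p] = lam[0, a] * sx
        for a in range(1, k):
            for b in range(1, k):
                prec[p + a - 1, p + b - 1] = lam[a, b] * self.n_subj
        for a in range(k):
            rhs[:p] += lam[0, a] * (self.x.T @ z[a])
            for b in range(1, k):
                rhs[p + b - 1] += lam[b, a] * z[a].sum()

        prec += np.eye(dim) / self.priors.loc_sd ** 2

        theta_names = (["beta"] * p + (["beta_t"] if has_slope else []) + ["mu_sigma"])
        fixed_mask = np.array([nm in self.fix for nm in theta_names])
        theta_cur = np.concatenate([
            np.atleast_1d(state["beta"]).astype(float),
            [state["beta_t"]] if has_slope else [],
            [state["mu_sigma"]],
        ])
        free = ~fixed_mask
        if free.any():
            pf = prec[np.ix_(free, free)]
            r = rhs[free] - prec[np.ix_(free, fixed_mask)] @ theta_cur[fixed_mask]
            chol = np.linalg.cholesky(pf)
            mean = np.linalg.solve(pf, r)
            zdraw = rng.standard_normal(free.sum())
            theta_cur[free] = mean + np.linalg.solve(chol.T, zdraw)
        state["beta"] = theta_cur[:p]
        if has_slope:
            state["beta_t"] = float(theta_cur[p])
        state["mu_sigma"] = float(theta_cur[-1])

    def _pop_loglik(self, state):
        sig = _as_pop_matrix(state, self.spec.has_slope)
        if not _is_pd(sig):
            return -np.inf
        resid = [state["level"] - self.x @ state["beta"]]
        if self.spec.has_slope:
            resid.append(state["slope"] - state["beta_t"])
        resid.append(state["ell"] - state["mu_sigma"])
        r = np.column_stack(resid)
        s = r.T @ r
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            return -np.inf
        return -0.5 * self.n_subj * logdet - 0.5 * np.trace(np.linalg.solve(sig, s))

    def _update_covariance(self, state, rng, adapt):
        pr = self.priors
        ll_cur = self._pop_loglik(state)
        accs = np.zeros(len(self.cov_names))
        for j, name in enumerate(self.cov_names):
            cur = state[name]
            prop = cur + self.scale_cov.scale[j] * rng.standard_normal()
            if name.startswith("tau"):
                if not (1e-6 < prop < pr.sd_upper):
                    continue
            else:
                if not (pr.corr_lower < prop < pr.corr_upper):
                    continue
            state[name] = prop
            ll_prop = self._pop_loglik(state)
            if np.log(rng.uniform()) < ll_prop - ll_cur:
                ll_cur = ll_prop
                accs[j] = 1.0
            else:
                state[name] = cur
        if adapt:
            self.scale_cov.update(accs)

    def iterate(self, state, rng, adapt: bool):
        self._update_level(state, rng)
        if self.spec.has_slope:
            self._update_slope(state, rng)
        self._update_ell(state, rng, adapt)
        self._update_means(state, rng)
        if self.cov_names:
            self._update_covariance(state, rng, adapt)
        self._update_extra(state, rng, adapt)

    # -- driver ---------------------------------------------------------
    def scalar_draw_names(self) -> list[str]:
        names = ["mu_sigma", "tau0", "tau_sigma"]
        if self.spec.has_slope:
            names += ["beta_t", "tau1", "rho01"]
            if self.spec.correlated:
                names += ["rho0s", "rho1s"]
        elif self.spec.correlated:
            names += ["rho"]
        return names

    def run(self) -> PosteriorDraws:
        mc = self.mcmc
        rngs = spawn_rngs(mc.seed, mc.chains)
        scalars = self.scalar_draw_names()
        extra = self._extra_draw_names()  # name -> trailing shape tuple
        keep = mc.n_keep
        out: dict[str, np.ndarray] = {}
        for nm in scalars:
            out[nm] = np.empty((mc.chains, keep))
        out["beta"] = np.empty((mc.chains, keep, self.p))
        out["b"] = np.empty((mc.chains, keep, self.n_subj))
        out["sigma"] = np.empty((mc.chains, keep, self.n_subj))
        if self.spec.has_slope:
            out["slope"] = np.empty((mc.chains, keep, self.n_subj))
        for nm, shape in extra.items():
            out[nm] = np.empty((mc.chains, keep, *shape))

        for c, rng in enumerate(rngs):
            # fresh adaptation per chain
            self.scale_ell = AdaptiveScale(self.n_subj, initial=0.5, target=0.35)
            self.scale_cov = AdaptiveScale(len(self.cov_names), initial=0.05, target=0.35)
            self._reset_extra_adaptation()
            state = self.initial_state(rng)
            for _ in range(mc.burn_in):
                self.iterate(state, rng, adapt=True)
            for i in range(keep):
                for _ in range(mc.thin):
                    self.iterate(state, rng, adapt=False)
                for nm in scalars:
                    out[nm][c, i] = state[nm]
                out["beta"][c, i] = state["beta"]
                out["b"][c, i] = state["level"]
                out["sigma"][c, i] = np.exp(state["ell"])
                if self.spec.has_slope:
                    out["slope"][c, i] = state["slope"]
                self._record_extra(out, c, i, state)

        draws = PosteriorDraws(params=out, subject_ids=self.ids, config=mc)
        if mc.chains >= 2:
            bad = {nm: gelman_rubin(draws, nm) for nm in scalars}
            bad = {k: v for k, v in bad.items() if v > mc.rhat_threshold}
            if bad:
                warnings.warn(
                    "convergence diagnostic above threshold "
                    f"{mc.rhat_threshold}: " +
                    ", ".join(f"{k}: R-hat={v:.3f}" for k, v in bad.items()),
                    RuntimeWarning, stacklevel=2)
        return draws

    def _reset_extra_adaptation(self):
        pass

    def _record_extra(self, out, chain, i, state):
        pass


def fit_locscale(data: AnalysisDataset, spec: ModelSpec | str,
                 mcmc: McmcConfig | None = None,
                 fix_population: dict | None = None) -> PosteriorDraws:
    """Fit a location-scale mixed model by MCMC.

    ``fix_population`` maps population-parameter names (``"beta"``,
    ``"beta_t"``, ``"mu_sigma"``, ``"tau0"``, ``"tau1"``, ``"tau_sigma"``,
    ``"rho"``, ``"rho01"``, ``"rho0s"``, ``"rho1s"``) to values held fixed
    during sampling -- useful for oracle checks and empirical-Bayes style
    subject-level inference.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_name(spec)
    mcmc = mcmc or McmcConfig()
    return LocScaleSampler(data, spec, mcmc, fix_population).run()


def subject_effects(draws: PosteriorDraws) -> SubjectEffects:
    """Posterior-mean usual level and residual SD per subject.

    Because they are posterior means under the hierarchical prior, the
    per-subject residual SDs are shrunk toward the population centre
    relative to the naive per-subject SDs, with stronger shrinkage for
    subjects with fewer measurements.
    """
    if "b" not in draws.params or "sigma" not in draws.params:
        raise ValueError("draws contain no per-subject parameters")
    df = pd.DataFrame({
        "id": draws.subject_ids,
        "bp_hat": draws.mean("b"),
        "sd_hat": draws.mean("sigma"),
    })
    if "slope" in draws.params:
        df["slope_hat"] = draws.mean("slope")
    return SubjectEffects(df=df)
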