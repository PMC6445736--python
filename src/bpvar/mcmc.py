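"""Shared MCMC plumbing: configuration, draws container, diagnostics.

The samplers in :mod:`bpvar.locscale` and :mod:`bpvar.joint` are
Metropolis-within-Gibbs schemes built from conjugate updates where the
full conditional is available in closed form and adaptive random-walk
Metropolis steps elsewhere.  Adaptation (Robbins-Monro tuning of proposal
scales toward a target acceptance rate) runs during burn-in only, so the
retained chain is a draw from a fixed Markov kernel.

Convergence is monitored with the Brooks-Gelman corrected potential scale
reduction factor

    R-hat^2 = Vhat / W,   Vhat = (n-1)/n * W + (m+1)/(m n) * B,

where ``W`` is the mean within-chain variance, ``B/n`` the variance of the
chain means, ``m`` the number of chains and ``n`` the retained length; the
statistic is floored at 1 so that identical chains give exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["McmcConfig", "PriorConfig", "PosteriorDraws", "gelman_rubin",
           "AdaptiveScale", "spawn_rngs"]


@dataclass(frozen=True)
class PriorConfig:
    """Diffuse default priors: U[0, sd_upper] on SDs, U[-1, 1] on
    correlations, N(0, loc_sd^2) on location parameters (including log
    baseline-hazard levels)."""

    sd_upper: float = 100.0
    loc_sd: float = 100.0
    corr_lower: float = -1.0
    corr_upper: float = 1.0


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults follow the reference analysis: burn-in 1000 for mixed models
    (use 2000 for joint models), 1000 retained draws; joint models are
    typically thinned by 4 because the association parameters mix slowly.
    ``chains=2`` is the minimum for the Brooks-Gelman diagnostic.
    """

    chains: int = 2
    burn_in: int = 1000
    n_keep: int = 1000
    thin: int = 1
    seed: int | None = None
    priors: PriorConfig = field(default_factory=PriorConfig)
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_keep < 1 or self.thin < 1 or self.chains < 1:
            raise ValueError("require burn_in >= 0, n_keep >= 1, thin >= 1, chains >= 1")


@dataclass
class PosteriorDraws:
    """Named posterior draws, stacked per chain.

    ``params[name]`` has shape ``(chains, n_keep)`` for population
    parameters and ``(chains, n_keep, n_subjects)`` for per-subject
    quantities (``"b"``, ``"sigma"``, optionally ``"slope"``).
    """

    params: dict[str, np.ndarray]
    subject_ids: np.ndarray
    config: McmcConfig

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def mean(self, name: str):
        return self.stacked(name).mean(axis=0)

    def sd(self, name: str):
        return self.stacked(name).std(axis=0, ddof=1)

    def quantile(self, name: str, q):
        return np.quantile(self.stacked(name), q, axis=0)

    def rhat(self, name: str) -> float:
        return gelman_rubin(self, name)

    def summary(self, names: list[str] | None = None) -> pd.DataFrame:
        """Posterior mean, SD, central 95% interval and R-hat per scalar
        parameter."""
        if names is None:
            names = [k for k, v in self.params.items() if v.ndim == 2]
        rows = {}
        for k in names:
            s = self.stacked(k)
            rows[k] = {
                "mean": s.mean(), "sd": s.std(ddof=1),
                "q2.5": np.quantile(s, 0.025), "q97.5": np.quantile(s, 0.975),
                "rhat": gelman_rubin(self, k) if self.n_chains >= 2 else np.nan,
            }
        return pd.DataFrame(rows).T


def gelman_rubin(draws: "PosteriorDraws | np.ndarray", param: str | None = None) -> float:
    """Brooks-Gelman corrected potential scale reduction factor.

    Accepts either a :class:`PosteriorDraws` plus parameter name or a raw
    ``(chains, draws)`` array.  Requires at least two chains of equal
    length.  Returns a value >= 1; identical chains give exactly 1.
    """
    if isinstance(draws, PosteriorDraws):
        if param is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        x = draws.params[param]
        if x.ndim != 2:
            raise ValueError(f"{param!r} is not a scalar parameter; R-hat needs (chains, draws)")
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    if n < 2:
        raise ValueError("chains too short for a variance estimate")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = chain_means.var(ddof=1)
    if w == 0:
        return 1.0
    v_hat = (n - 1) / n * w + (m + 1) / m * b_over_n
    return float(np.sqrt(max(1.0, v_hat / w)))


class AdaptiveScale:
    """Robbins-Monro adaptation of random-walk proposal scales.

    Holds a vector of log proposal scales; :meth:`update` nudges them so the
    realised acceptance rate approaches ``target``.  Call ``update`` during
    burn-in only (adaptation must be frozen afterwards for the chain to be
    Markov).
    """

    def __init__(self, n: int, initial: float | np.ndarray = 0.5,
                 target: float = 0.35):
        self.log_scale = np.full(n, 0.0) + np.log(np.asarray(initial, dtype=float))
        self.target = target
        self._t = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted: np.ndarray) -> None:
        self._t += 1
        step = 1.0 / self._t ** 0.6
        self.log_scale += step * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_scale, -12.0, 12.0, out=self.log_scale)


def spawn_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
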