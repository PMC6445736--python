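"""Replicated simulation harness: bias, RMSE and coverage per method.

For each replicate a cohort is simulated, each requested method produces an
estimate of the two association parameters -- the usual-level log hazard
ratio (truth ``alpha0``) and the variability log hazard ratio (truth
``alpha_sigma``) -- together with a 95% interval (Wald for the Cox-based
methods, central posterior for the joint models), and the harness
aggregates the replicate mean, SD (n-1 divisor), RMSE (plain mean of
squared errors) and coverage.

Methods: ``true`` (Cox on the latent per-subject truth -- the best
achievable benchmark), ``naive``, ``lmm1``/``lmm2`` (two-stage with the
location-scale mixed model), ``jm1``/``jm2`` (joint models).  Replicates
are seed-deterministic regardless of execution order; replicates where a
fit fails are dropped for that method and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import ConvergenceError, cox_newton, fit_cox
from .joint import fit_joint
from .locscale import fit_locscale, subject_effects
from .mcmc import McmcConfig
from .naive import naive_estimates
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger("bpvar")

__all__ = ["SimStudyResult", "run_simstudy", "format_table", "parse_table"]

METHOD_LABELS = {"true": "True values", "naive": "Naive", "lmm1": "LMM1",
                 "lmm2": "LMM2", "jm1": "JM1", "jm2": "JM2"}


@dataclass(frozen=True)
class SimStudyResult:
    """Aggregated metrics (``table``) plus per-replicate estimates
    (``estimates``) of both log hazard ratios."""

    table: pd.DataFrame
    estimates: pd.DataFrame
    truth: tuple[float, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _wald_rows(fit, level_col: str, sd_col: str) -> dict:
    i0 = fit.names.index(level_col)
    i1 = fit.names.index(sd_col)
    return {
        "est_level": fit.coef[i0], "lo_level": fit.ci_lower[i0], "hi_level": fit.ci_upper[i0],
        "est_sd": fit.coef[i1], "lo_sd": fit.ci_lower[i1], "hi_sd": fit.ci_upper[i1],
    }


def _run_method(method: str, dataset, effects, mcmc: McmcConfig,
                n_intervals: int) -> dict:
    if method == "true":
        fit = cox_newton(np.column_stack([effects.b0, effects.sigma]),
                         dataset.survival.df["time"].to_numpy(),
                         dataset.survival.df["status"].to_numpy(),
                         names=("level", "variability"))
        return _wald_rows(fit, "level", "variability")
    if method == "naive":
        # sample SD (n-1): the convention of the stock statistical software
        # the naive two-stage results are benchmarked against
        est = naive_estimates(dataset.longitudinal, ddof=1)
        u = est.df.rename(columns={"mean": "level", "sd": "variability"})[
            ["id", "level", "variability"]]
        return _wald_rows(fit_cox(u, dataset.survival), "level", "variability")
    if method in ("lmm1", "lmm2"):
        draws = fit_locscale(dataset, method, mcmc)
        eff = subject_effects(draws)
        u = eff.df.rename(columns={"bp_hat": "level", "sd_hat": "variability"})[
            ["id", "level", "variability"]]
        return _wald_rows(fit_cox(u, dataset.survival), "level", "variability")
    if method in ("jm1", "jm2"):
        draws = fit_joint(dataset, method, n_intervals=n_intervals, mcmc=mcmc)
        out = {}
        for short, name in (("level", "alpha_level"), ("sd", "alpha_sd")):
            out[f"est_{short}"] = float(draws.mean(name))
            lo, hi = draws.quantile(name, [0.025, 0.975])
            out[f"lo_{short}"], out[f"hi_{short}"] = float(lo), float(hi)
        return out
    raise ValueError(f"unknown method {method!r}; expected one of {sorted(METHOD_LABELS)}")


def run_simstudy(cfg: SimConfig, methods: list[str], reps: int,
                 mcmc: McmcConfig | None = None, master_seed: int = 0,
                 n_intervals: int = 15) -> SimStudyResult:
    """Run ``reps`` simulation replicates and aggregate the metrics."""
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    if not methods:
        raise ValueError("no methods requested")
    for m in methods:
        if m not in METHOD_LABELS:
            raise ValueError(f"unknown method {m!r}")
    base_mcmc = mcmc or McmcConfig(chains=1)

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(reps)
    rows = []
    for r, child in enumerate(children):
        data_rng = np.random.default_rng(child)
        dataset, effects = simulate_dataset(cfg, data_rng)
        mcmc_seed = int(child.generate_state(1)[0] % 2**31)
        rep_mcmc = McmcConfig(chains=base_mcmc.chains, burn_in=base_mcmc.burn_in,
                              n_keep=base_mcmc.n_keep, thin=base_mcmc.thin,
                              seed=mcmc_seed, priors=base_mcmc.priors,
                              rhat_threshold=base_mcmc.rhat_threshold)
        for m in methods:
            jm_mcmc = rep_mcmc
            if m in ("jm1", "jm2") and mcmc is None:
                jm_mcmc = McmcConfig(chains=1, burn_in=2000, thin=4, seed=mcmc_seed)
            try:
                res = _run_method(m, dataset, effects, jm_mcmc, n_intervals)
            except (ValueError, ConvergenceError, np.linalg.LinAlgError) as exc:
                logger.warning("replicate %d, method %s failed: %s", r, m, exc)
                res = {k: np.nan for k in ("est_level", "lo_level", "hi_level",
                                           "est_sd", "lo_sd", "hi_sd")}
            rows.append({"rep": r, "method": m, **res})
    est = pd.DataFrame(rows)

    truth = {"level": cfg.alpha0, "sd": cfg.alpha_sigma}
    agg_rows = []
    for m in methods:
        sub = est[est["method"] == m]
        for param in ("level", "sd"):
            vals = sub[f"est_{param}"]
            ok = vals.notna()
            if not ok.any():
                raise RuntimeError(f"all replicates failed for method {m!r}")
            v = vals[ok].to_numpy()
            lo, hi = sub.loc[ok, f"lo_{param}"].to_numpy(), sub.loc[ok, f"hi_{param}"].to_numpy()
            tr = truth[param]
            agg_rows.append({
                "method": m, "parameter": param, "true": tr,
                "mean": v.mean(), "sd": v.std(ddof=1),
                "rmse": float(np.sqrt(np.mean((v - tr) ** 2))),
                "coverage": float(np.mean((lo <= tr) & (tr <= hi))),
                "n_replicates": int(ok.sum()), "n_failed": int((~ok).sum()),
            })
    return SimStudyResult(table=pd.DataFrame(agg_rows), estimates=est,
                          truth=(cfg.alpha0, cfg.alpha_sigma))


def format_table(result: SimStudyResult) -> str:
    """Aligned text table: one row per method, the usual-level block then
    the variability block, each ``True  Mean (SD)  RMSE  Coverage``."""
    tab = result.table
    if tab.empty:
        raise ValueError("empty result")
    lines = [f"{'':<14}{'Usual Level logHR':<46}{'Variability logHR':<46}",
             f"{'Method':<14}" + 2 * f"{'True':<8}{'Mean (SD)':<20}{'RMSE':<8}{'Coverage':<10}"]
    for m in tab["method"].unique():
        row = f"{METHOD_LABELS[m]:<14}"
        for param in ("level", "sd"):
            r = tab[(tab["method"] == m) & (tab["parameter"] == param)].iloc[0]
            mean_sd = "{:.4f} ({:.4f})".format(r["mean"], r["sd"])
            row += "{:<8.4g}{:<20}{:<8.4f}{:<10.4f}".format(
                r["true"], mean_sd, r["rmse"], r["coverage"])
        lines.append(row.rstrip())
    return "\n".join(lines) + "\n"


def parse_table(text: str) -> pd.DataFrame:
    """Parse :func:`format_table` output back into the aggregate frame
    (values at 4-decimal precision); inverse of the text rendering."""
    lines = [ln for ln in text.strip().splitlines()[2:] if ln.strip()]
    label_to_key = {v: k for k, v in METHOD_LABELS.items()}
    rows = []
    for ln in lines:
        toks = ln.replace("(", "").replace(")", "").split()
        nums = [float(t) for t in toks[-10:]]
        name = " ".join(toks[:-10])
        for j, param in enumerate(("level", "sd")):
            t, mean, sd, rmse, cov = nums[5 * j: 5 * j + 5]
            rows.append({"method": label_to_key[name], "parameter": param,
                         "true": t, "mean": mean, "sd": sd, "rmse": rmse,
                         "coverage": cov})
    return pd.DataFrame(rows)
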