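"""Semiparametric Cox proportional-hazards regression (stage two).

Maximum partial-likelihood estimation by Newton-Raphson with step-halving,
Efron's correction for tied event times, and standard errors from the
inverse observed information.  Covariates are standardised internally for
numerical conditioning and the fit is mapped back to the original scale
(the partial likelihood is exactly invariant to centering, and scaling a
covariate by ``c`` scales its coefficient by ``1/c``).

The module also provides the two-stage procedure: estimate each subject's
usual level and residual SD in stage one (naive formulas or a
location-scale mixed model) and enter the estimates as fixed covariates in
the Cox model, ignoring their estimation uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AnalysisDataset, SurvivalData

__all__ = ["CoxFit", "ConvergenceError", "fit_cox", "cox_newton", "two_stage_fit"]

_Z975 = 1.96  # Wald multiplier, matching the 95% intervals reported


class ConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails to converge (e.g. monotone
    likelihood under perfect separation)."""


@dataclass(frozen=True)
class CoxFit:
    """Fitted Cox model: log hazard ratios with Wald inference."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    n_subjects: int
    n_events: int
    loglik: float
    n_iter: int

    @property
    def ci_lower(self) -> np.ndarray:
        return self.coef - _Z975 * self.se

    @property
    def ci_upper(self) -> np.ndarray:
        return self.coef + _Z975 * self.se

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "z": z,
            "hr": np.exp(self.coef),
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
        }, index=list(self.names))


def _efron_quantities(beta, x, time, status):
    """Log partial likelihood, score and information (Efron ties).

    ``x, time, status`` must be sorted by descending time with censored
    records preceding events at tied times.
    """
    n, p = x.shape
    eta = x @ beta
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = np.einsum("i,ij,ik->ijk", w, x, x)
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    ev = status == 1
    ev_times = time[ev]
    if len(np.unique(ev_times)) == len(ev_times):
        # no tied *event* times: Efron and Breslow coincide and the risk
        # sums are plain reversed cumsums (censored records sort before
        # events at tied times, so they stay in the event's risk set)
        pos = np.flatnonzero(ev)
        R = cw[pos]
        mu = cwx[pos] / R[:, None]
        loglik = float(np.sum(eta[pos] - np.log(R)))
        score = np.sum(x[pos] - mu, axis=0)
        info = np.sum(cwxx[pos] / R[:, None, None]
                      - np.einsum("ij,ik->ijk", mu, mu), axis=0)
        return loglik, score, info

    loglik, score, info = 0.0, np.zeros(p), np.zeros((p, p))
    # group boundaries over tied times
    starts = np.flatnonzero(np.r_[True, np.diff(time) != 0])
    ends = np.r_[starts[1:], n] - 1
    for a, b in zip(starts, ends):
        g_ev = np.flatnonzero(ev[a:b + 1]) + a
        d = len(g_ev)
        if d == 0:
            continue
        R, Rx, Rxx = cw[b], cwx[b], cwxx[b]
        D = w[g_ev].sum()
        Dx = wx[g_ev].sum(axis=0)
        Dxx = wxx[g_ev].sum(axis=0)
        frac = (np.arange(d) / d)[:, None]
        denom = R - frac[:, 0] * D                      # (d,)
        num_x = Rx[None, :] - frac * Dx[None, :]        # (d, p)
        num_xx = Rxx[None] - frac[:, :, None] * Dxx[None]
        m = num_x / denom[:, None]
        loglik += float(eta[g_ev].sum() - np.log(denom).sum())
        score += x[g_ev].sum(axis=0) - m.sum(axis=0)
        info += np.sum(num_xx / denom[:, None, None]
                       - np.einsum("ij,ik->ijk", m, m), axis=0)
    return loglik, score, info


def cox_newton(x: np.ndarray, time: np.ndarray, status: np.ndarray,
               names: tuple[str, ...] | None = None,
               tol: float = 1e-9, max_iter: int = 50) -> CoxFit:
    """Fit a Cox model from plain arrays (one row per subject)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    n, p = x.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    n_events = int(status.sum())
    if n_events == 0:
        raise ValueError("no events: the partial likelihood is undefined")

    scale = x.std(axis=0)
    if np.any(scale == 0):
        j = int(np.argmin(scale))
        raise ValueError(f"covariate {names[j]!r} is constant: rank-deficient design")
    center = x.mean(axis=0)
    xs = (x - center) / scale

    # descending time; censored before events at tied times so tied censored
    # subjects stay in the risk set of the event
    order = np.lexsort((status, -time))
    xs_o, t_o, s_o = xs[order], time[order], status[order]

    beta = np.zeros(p)
    loglik, score, info = _efron_quantities(beta, xs_o, t_o, s_o)
    if np.linalg.cond(info) > 1e10:
        raise ValueError("collinear covariates: information matrix is singular")
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError("collinear covariates: information matrix is singular") from exc
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new, sc_new, info_new = _efron_quantities(cand, xs_o, t_o, s_o)
            if ll_new >= loglik - 1e-12:
                break
            step = step / 2
        beta, loglik, score, info = cand, ll_new, sc_new, info_new
        if np.abs(beta).max() > 10:
            # on the standardised scale a log hazard ratio of 10 per SD only
            # arises when the likelihood is monotone (perfect separation)
            raise ConvergenceError(
                f"monotone likelihood: coefficient diverging (|coef|={np.abs(beta).max():.3g} "
                "per covariate SD); a covariate perfectly separates events")
        if np.linalg.norm(score) < tol:
            break
    else:
        raise ConvergenceError(
            f"Newton iteration did not converge in {max_iter} steps "
            f"(||score||={np.linalg.norm(score):.3g}, max|coef|={np.abs(beta).max():.3g}); "
            "possible monotone likelihood / perfect separation"
        )

    vcov_s = np.linalg.inv(info)
    coef = beta / scale
    vcov = vcov_s / np.outer(scale, scale)
    se = np.sqrt(np.diag(vcov))
    return CoxFit(names=tuple(names), coef=coef, se=se, vcov=vcov,
                  n_subjects=n, n_events=n_events, loglik=loglik, n_iter=n_iter)


def fit_cox(covariates: pd.DataFrame, survival: SurvivalData,
            columns: tuple[str, ...] | None = None) -> CoxFit:
    """Fit a Cox model joining per-subject covariates to survival records.

    ``covariates`` needs an ``id`` column; remaining (or ``columns``-selected)
    columns enter the linear predictor.  Subjects missing from either table
    are dropped (inner join), so stage-one exclusions propagate naturally.
    """
    if "id" not in covariates.columns:
        raise ValueError("covariates need an 'id' column")
    cols = tuple(c for c in covariates.columns if c != "id") if columns is None else tuple(columns)
    if not cols:
        raise ValueError("no covariate columns")
    merged = covariates[["id", *cols]].merge(survival.df, on="id", how="inner")
    if merged[list(cols)].isna().any().any():
        raise ValueError("missing covariate values after merge")
    return cox_newton(merged[list(cols)].to_numpy(float),
                      merged["time"].to_numpy(float),
                      merged["status"].to_numpy(int), names=cols)


def two_stage_fit(data: AnalysisDataset, stage1: str | object = "naive",
                  mcmc=None, min_measurements: int = 2,
                  adjust_for: tuple[str, ...] = ()) -> CoxFit:
    """Two-stage association fit: subject-level estimates, then Cox.

    ``stage1`` is ``"naive"`` or a :class:`~bpvar.locscale.ModelSpec`
    (the strings ``"lmm1"``/``"lmm2"``/``"lmm3"``/``"lmm4"`` select the
    standard specifications).  Stage-one estimates of the usual level and
    residual SD are treated as fixed covariates in stage two; their
    estimation uncertainty is not propagated into the Cox standard errors.
    ``adjust_for`` names baseline covariate columns added to the model.
    """
    from .locscale import ModelSpec, fit_locscale, subject_effects
    from .naive import naive_estimates

    if isinstance(stage1, str) and stage1 == "naive":
        est = naive_estimates(data.longitudinal, min_measurements=min_measurements)
        u = est.df.rename(columns={"mean": "level", "sd": "variability"})[
            ["id", "level", "variability"]]
    else:
        spec = ModelSpec.from_name(stage1) if isinstance(stage1, str) else stage1
        draws = fit_locscale(data, spec, mcmc)
        eff = subject_effects(draws)
        u = eff.df.rename(columns={"bp_hat": "level", "sd_hat": "variability"})[
            ["id", "level", "variability"]]
    if adjust_for:
        if data.covariates is None:
            raise ValueError("adjust_for given but dataset has no covariate table")
        u = u.merge(data.covariates.df[["id", *adjust_for]], on="id", how="inner")
    return fit_cox(u, data.survival)
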