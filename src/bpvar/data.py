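"""Core data containers and follow-up bookkeeping.

Three tabular containers cover the inputs of every model in the package:

* :class:`LongitudinalData` -- repeated biomarker measurements ``(id, time,
  value)`` in long format, time in years since baseline;
* :class:`SurvivalData` -- one row per subject with follow-up time and an
  event indicator;
* :class:`CovariateTable` -- per-subject baseline covariates.

:class:`AnalysisDataset` bundles the three and optionally records a
separation time ``t_sep`` splitting follow-up into a measurement window and
a survival window (see :func:`separate_followup`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("bpvar")

__all__ = [
    "DataFormatError",
    "LongitudinalData",
    "SurvivalData",
    "CovariateTable",
    "AnalysisDataset",
    "read_long_csv",
    "read_survival_csv",
    "read_covariates_csv",
    "separate_followup",
]


class DataFormatError(ValueError):
    """Raised when an input table violates the expected format."""


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataFormatError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def _require_numeric(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = parsed.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataFormatError(f"{what}: non-numeric value {df[c].iloc[row]!r} in column {c!r} at data row {row}")
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise DataFormatError(f"{what}: missing value in column {c!r} at data row {row}")
        df[c] = parsed.astype(float)
    return df


@dataclass(frozen=True)
class LongitudinalData:
    """Long-format repeated measurements, sorted by subject then time.

    ``df`` has columns ``id, time, value``; per subject the times are
    strictly increasing (duplicate ``(id, time)`` pairs are rejected).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, ("id", "time", "value"), "longitudinal data")
        df = _require_numeric(self.df[["id", "time", "value"]].assign(id=self.df["id"]),
                              ("time", "value"), "longitudinal data")
        if df["id"].isna().any():
            raise DataFormatError("longitudinal data: missing subject id")
        dup = df.duplicated(subset=["id", "time"])
        if dup.any():
            r = df.loc[dup].iloc[0]
            raise DataFormatError(
                f"longitudinal data: duplicate (id, time) pair (id={r['id']!r}, time={r['time']!r})"
            )
        df = df.sort_values(["id", "time"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "df", df)

    @property
    def subjects(self) -> np.ndarray:
        return self.df["id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.df["id"].nunique()

    def counts(self) -> pd.Series:
        """Number of measurements per subject (n_i), indexed by id."""
        return self.df.groupby("id", sort=False).size()

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (subject ids in order, integer codes per row, times, values)."""
        codes, uniques = pd.factorize(self.df["id"], sort=False)
        return (np.asarray(uniques),
                codes.astype(np.int64),
                self.df["time"].to_numpy(float),
                self.df["value"].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class SurvivalData:
    """Per-subject follow-up time (years, > 0) and event indicator (0/1)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, ("id", "time", "status"), "survival data")
        df = _require_numeric(self.df[["id", "time", "status"]].assign(id=self.df["id"]),
                              ("time", "status"), "survival data")
        if df["id"].duplicated().any():
            r = df.loc[df["id"].duplicated()].iloc[0]
            raise DataFormatError(f"survival data: duplicate subject id {r['id']!r}")
        if (df["time"] <= 0).any():
            raise DataFormatError("survival data: follow-up times must be positive")
        if not df["status"].isin([0.0, 1.0]).all():
            raise DataFormatError("survival data: status must be 0 or 1")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "df", df)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def n_events(self) -> int:
        return int(self.df["status"].sum())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class CovariateTable:
    """One row per subject: ``id`` plus real-valued covariate columns."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.df, ("id",), "covariate table")
        if self.df["id"].duplicated().any():
            raise DataFormatError("covariate table: duplicate subject id")
        if self.df.columns.duplicated().any():
            raise DataFormatError("covariate table: duplicate column name")
        cols = tuple(c for c in self.df.columns if c != "id")
        df = _require_numeric(self.df, cols, "covariate table").reset_index(drop=True)
        object.__setattr__(self, "df", df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class AnalysisDataset:
    """Longitudinal + survival (+ optional covariate) data for one analysis.

    When ``t_sep`` is set, the longitudinal window is ``[0, t_sep)`` and the
    survival clock has been reset to start at ``t_sep`` (times are *since*
    the separation point).
    """

    longitudinal: LongitudinalData
    survival: SurvivalData
    covariates: CovariateTable | None = None
    t_sep: float | None = None

    def __post_init__(self) -> None:
        long_ids = set(self.longitudinal.df["id"])
        surv_ids = set(self.survival.df["id"])
        orphan = long_ids - surv_ids
        if orphan:
            raise DataFormatError(
                f"{len(orphan)} subject(s) have measurements but no survival record, e.g. {sorted(orphan)[:3]}"
            )


def read_long_csv(path: str | Path) -> LongitudinalData:
    """Read long-format measurements from CSV with header ``id,time,value``."""
    return LongitudinalData(pd.read_csv(path))


def read_survival_csv(path: str | Path) -> SurvivalData:
    """Read per-subject survival records from CSV with header ``id,time,status``."""
    return SurvivalData(pd.read_csv(path))


def read_covariates_csv(path: str | Path) -> CovariateTable:
    """Read a per-subject covariate table from CSV (``id`` plus named columns)."""
    return CovariateTable(pd.read_csv(path))


def separate_followup(data: AnalysisDataset, t_sep: float) -> AnalysisDataset:
    """Split follow-up at ``t_sep`` into measurement and survival windows.

    Longitudinal records at ``t >= t_sep`` are dropped (half-open window
    ``[0, t_sep)``), subjects whose follow-up ends at or before ``t_sep``
    (event or censoring) are removed entirely, and the survival times of the
    remaining subjects are re-expressed as time since ``t_sep``.  The result
    is a standard survival analysis conditional on being at risk at
    ``t_sep``.  Idempotent: reapplying with the same ``t_sep`` is a no-op.
    """
    if t_sep <= 0:
        raise ValueError(f"t_sep must be positive, got {t_sep}")
    if data.t_sep is not None:
        # Times are already relative to the previous separation point; a
        # second application with the same t_sep must not shift them again.
        if data.t_sep == t_sep:
            return data
        raise ValueError(f"dataset already separated at t_sep={data.t_sep}")

    surv = data.survival.df
    keep = surv["time"] > t_sep
    if not keep.any():
        raise ValueError(f"no survival follow-up remains after t_sep={t_sep}")
    n_drop_subj = int((~keep).sum())
    kept_ids = set(surv.loc[keep, "id"])

    long_df = data.longitudinal.df
    in_window = (long_df["time"] < t_sep) & long_df["id"].isin(kept_ids)
    n_drop_meas = int(len(long_df) - in_window.sum())
    new_long = LongitudinalData(long_df.loc[in_window].reset_index(drop=True))

    new_surv_df = surv.loc[keep].copy()
    new_surv_df["time"] = new_surv_df["time"] - t_sep
    new_surv = SurvivalData(new_surv_df.reset_index(drop=True))

    new_cov = None
    if data.covariates is not None:
        cov = data.covariates.df
        new_cov = CovariateTable(cov.loc[cov["id"].isin(kept_ids)].reset_index(drop=True))

    logger.info(
        "separate_followup(t_sep=%g): dropped %d subject(s) with follow-up ending before t_sep "
        "and %d measurement(s) at or after t_sep; %d subject(s) remain",
        t_sep, n_drop_subj, n_drop_meas, len(new_surv_df),
    )
    return AnalysisDataset(new_long, new_surv, new_cov, t_sep=t_sep)
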