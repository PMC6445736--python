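"""Naive per-subject estimators of usual level and visit-to-visit variability.

These are the estimators in routine use in the cardiovascular literature:
each subject's usual level is the plain mean of their repeated measurements
and their variability is the SD of those measurements.  Both use only
within-subject information, so with few visits the SD is a noisy estimate
of the subject's true residual SD — the source of the regression-dilution
bias the model-based estimators in this package are designed to remove.

The SD denominator is ``n_i`` by default (the population form, as commonly
printed); ``ddof=1`` switches to the sample SD.  The coefficient of
variation (SD/mean) and the average real variability (mean absolute change
between successive visits) are also computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LongitudinalData

logger = logging.getLogger("bpvar")

__all__ = ["NaiveEstimates", "naive_estimates"]


@dataclass(frozen=True)
class NaiveEstimates:
    """Per-subject summary statistics of the measurement stream.

    ``df`` has one row per retained subject with columns
    ``id, mean, sd, cv, arv, n_used``; ``excluded`` lists the ids dropped
    for having fewer than ``min_measurements`` measurements.
    """

    df: pd.DataFrame
    excluded: np.ndarray
    min_measurements: int
    ddof: int


def naive_estimates(data: LongitudinalData, min_measurements: int = 2,
                    ddof: int = 0) -> NaiveEstimates:
    """Compute per-subject mean, SD, CV and ARV of the measurement stream.

    Parameters
    ----------
    data
        Long-format measurements, time-sorted per subject.
    min_measurements
        Subjects with fewer measurements are excluded (and reported in the
        result); at least 2 so the SD is defined.
    ddof
        Delta degrees of freedom for the SD: 0 gives the ``n_i`` denominator
        (default), 1 the sample SD.

    The ARV averages ``|Y_ij - Y_i,j-1|`` over successive time-ordered
    visits, with denominator ``n_i - 1``.
    """
    if min_measurements < 2:
        raise ValueError("min_measurements must be >= 2 (SD undefined below that)")
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")

    df = data.df
    if len(df) == 0:
        raise ValueError("no measurements: all subjects excluded")
    ids, codes, _, y = data.arrays()
    n = np.bincount(codes, minlength=len(ids)).astype(float)
    mean = np.bincount(codes, weights=y, minlength=len(ids)) / n
    sq = np.bincount(codes, weights=y * y, minlength=len(ids)) - n * mean ** 2
    sq = np.maximum(sq, 0.0)  # guard rounding on constant series
    denom = n - ddof
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(np.where(denom > 0, sq / np.where(denom > 0, denom, 1.0), np.nan))
        cv = np.where(mean != 0, sd / mean, np.nan)
    # mean absolute change between successive visits (rows are time-sorted
    # within subject; pairs spanning a subject boundary are masked out)
    within = codes[1:] == codes[:-1]
    absdiff = np.abs(np.diff(y))
    arv_sum = np.bincount(codes[1:][within], weights=absdiff[within], minlength=len(ids))
    with np.errstate(invalid="ignore", divide="ignore"):
        arv = np.where(n > 1, arv_sum / np.maximum(n - 1, 1), np.nan)

    out = pd.DataFrame({
        "id": ids, "mean": mean, "sd": sd, "cv": cv, "arv": arv,
        "n_used": n.astype(int),
    })

    keep = out["n_used"] >= min_measurements
    excluded = out.loc[~keep, "id"].to_numpy()
    if len(excluded):
        logger.info("naive_estimates: excluded %d subject(s) with fewer than %d measurements",
                    len(excluded), min_measurements)
    out = out.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("all subjects excluded: no subject has "
                         f">= {min_measurements} measurements")
    return NaiveEstimates(df=out, excluded=excluded,
                          min_measurements=min_measurements, ddof=ddof)
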