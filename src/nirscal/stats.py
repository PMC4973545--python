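"""Summary and model-evaluation statistics for NIRS calibration.

Conventions (all SDs use denominator n−1):

* SEC  = sqrt(SSE / (n − p − 1)) on calibration residuals with p factors
* SECV, SEP = sqrt(SSE / n), the uncorrected RMS of held-out residuals
* RSQ_cal = 1 − SSE/SST; cross-validation and validation R² are squared
  Pearson correlations between reference and predicted values
* RPD = SD of the reference values divided by SECV (cross-validation)
  or SEP (validation); values above 2.5 are conventionally taken as fit
  for routine quantitative use
* SEL  = sqrt(Σ(a−b)² / 2m) over m duplicate laboratory determinations;
  RSEL = SEL/mean × 100
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "EvalStats",
    "LabPrecision",
    "SummaryStats",
    "summary_stats",
    "sec",
    "secv_sep",
    "rsq",
    "rpd",
    "sel",
    "lab_precision",
]


@dataclasses.dataclass
class SummaryStats:
    n: int
    min: float
    max: float
    mean: float
    sd: float
    cv: float  # percent


@dataclasses.dataclass
class EvalStats:
    """Evaluation statistics for one constituent/model."""

    n: int
    mean: float
    sd: float
    sec: float | None = None
    secv: float | None = None
    sep: float | None = None
    rsq_cal: float | None = None
    r2_cv: float | None = None
    rsq_v: float | None = None
    rpd_cv: float | None = None
    rpd_v: float | None = None
    bias: float | None = None


@dataclasses.dataclass
class LabPrecision:
    constituent: str
    sel: float
    rsel: float  # percent of the constituent mean
    n_pairs: int


def summary_stats(v: np.ndarray) -> SummaryStats:
    """Min/max/mean/SD/CV% of a value vector (SD with denominator n−1)."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("summary statistics need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return SummaryStats(
        n=v.size, min=float(v.min()), max=float(v.max()),
        mean=mean, sd=sd, cv=sd / mean * 100.0,
    )


def sec(residuals: np.ndarray, p: int) -> float:
    """Standard error of calibration with p model factors."""
    e = np.asarray(residuals, dtype=float).ravel()
    n = e.size
    if n <= p + 1:
        raise ValueError(f"SEC undefined: n={n} <= p+1={p + 1}")
    return float(np.sqrt((e @ e) / (n - p - 1)))


def secv_sep(held_out_residuals: np.ndarray) -> float:
    """SECV/SEP: root-mean-square of held-out residuals (no correction)."""
    e = np.asarray(held_out_residuals, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("no residuals")
    return float(np.sqrt((e @ e) / e.size))


def rsq(y: np.ndarray, y_hat: np.ndarray, mode: str = "calibration") -> float:
    """Coefficient of determination.

    ``calibration`` mode is 1 − SSE/SST; ``correlation`` mode (used for
    cross-validation and validation) is the squared Pearson correlation.
    The two coincide for least-squares fitted predictions.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("y and y_hat differ in length")
    if y.size < 3:
        raise ValueError("R^2 needs at least 3 samples")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("R^2 undefined for zero-variance y")
    if mode == "calibration":
        sse = float(((y - y_hat) ** 2).sum())
        return 1.0 - sse / sst
    if mode == "correlation":
        if np.std(y_hat) == 0.0:
            return 0.0
        r = float(np.corrcoef(y, y_hat)[0, 1])
        return r * r
    raise ValueError(f"unknown mode {mode!r}")


def rpd(sd: float, se: float) -> float:
    """Ratio of reference SD to a standard error (SECV or SEP)."""
    if se <= 0:
        raise ValueError("RPD undefined for non-positive standard error")
    return sd / se


def sel(duplicate_pairs: np.ndarray) -> float:
    """Standard error of laboratory from duplicate determinations."""
    pairs = np.atleast_2d(np.asarray(duplicate_pairs, dtype=float))
    if pairs.size == 0:
        raise ValueError("no duplicate pairs")
    if pairs.shape[1] != 2:
        raise ValueError("duplicate pairs must be (m, 2)")
    d = pairs[:, 0] - pairs[:, 1]
    return float(np.sqrt((d @ d) / (2 * pairs.shape[0])))


def lab_precision(constituent: str, duplicate_pairs: np.ndarray, mean: float) -> LabPrecision:
    """SEL and RSEL (% of mean) for one constituent."""
    pairs = np.atleast_2d(np.asarray(duplicate_pairs, dtype=float))
    s = sel(pairs)
    if mean == 0:
        raise ValueError("RSEL undefined for zero mean")
    return LabPrecision(constituent, s, s / mean * 100.0, pairs.shape[0])
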