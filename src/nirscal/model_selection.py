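"""Cross-validated factor selection, outlier elimination and grid search.

The calibration procedure mirrors standard chemometrics-software practice:

1. the calibration set is split into ``n_groups`` (default 6) seeded
   random cross-validation groups; the factor count minimising SECV is
   selected (ties go to the smaller count);
2. the model refitted at that factor count is screened for spectral
   outliers (global H: Mahalanobis distance in score space divided by the
   number of factors, flagged at GH >= 10) and fit outliers (T: absolute
   residual over SEC, flagged at T > 2.5);
3. flagged samples are removed and the procedure repeated, with at most
   two elimination passes.

MSC-family scatter references are refitted inside every cross-validation
training fold so no information leaks from held-out samples through the
reference spectrum.

``grid_search`` runs this calibration for every pre-treatment in a grid
and ranks candidates by SECV (ties: higher cross-validation R², then fewer
factors).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .mpls import MPLSModel, mpls_fit
from .pretreatment import PretreatmentSpec, apply_pretreatment, build_grid
from .spectra_io import SpectraSet
from .stats import EvalStats, rpd, rsq, sec, secv_sep

__all__ = [
    "CVResult",
    "CalibrationResult",
    "GridSearchResult",
    "cross_validate",
    "global_h",
    "t_outliers",
    "calibrate",
    "grid_search",
    "validate",
    "DEFAULT_GH_THRESHOLD",
    "DEFAULT_T_THRESHOLD",
]

DEFAULT_GH_THRESHOLD = 10.0
DEFAULT_T_THRESHOLD = 2.5


def default_max_factors(n: int) -> int:
    """Search bound on PLS factors: min(15, n // 6)."""
    return max(1, min(15, n // 6))


@dataclasses.dataclass
class CVResult:
    """Cross-validation curve and pooled held-out predictions."""

    secv: np.ndarray  # (max_factors,), secv[p-1] = SECV with p factors
    opt_factors: int
    predictions: np.ndarray  # (n, max_factors) pooled held-out predictions
    groups: np.ndarray  # (n,) group label per sample

    def r2_cv(self, y: np.ndarray, n_factors: int | None = None) -> float:
        p = self.opt_factors if n_factors is None else n_factors
        return rsq(y, self.predictions[:, p - 1], mode="correlation")


def _partition(n: int, n_groups: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    groups = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(perm, n_groups)):
        groups[chunk] = g
    return groups


def cross_validate(
    s: SpectraSet,
    y: np.ndarray,
    spec: PretreatmentSpec,
    max_factors: int,
    n_groups: int = 6,
    seed: int = 0,
    standardize_residuals: bool = True,
) -> CVResult:
    """Grouped cross-validation of one pre-treatment.

    Pre-treatment fitting (MSC reference spectra, WMSC weights) is redone
    inside each training fold.  SECV(p) pools the held-out residuals of all
    groups: sqrt(sum(e^2)/n).  ``n_groups == n`` gives leave-one-out.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = s.n_samples
    if y.shape[0] != n:
        raise ValueError("y length does not match the spectra")
    if not 2 <= n_groups <= n:
        raise ValueError(f"n_groups must be in [2, {n}], got {n_groups}")
    groups = _partition(n, n_groups, seed)

    preds = np.empty((n, max_factors))
    for g in range(n_groups):
        test = groups == g
        train = ~test
        fold_spec = spec.fresh()
        s_train = apply_pretreatment(s.subset(train), fold_spec, fit=True)
        s_test = apply_pretreatment(s.subset(test), fold_spec, fit=False)
        cap = min(max_factors, int(train.sum()) - 2)
        model = mpls_fit(
            s_train.absorbance,
            y[train],
            max_factors=cap,
            standardize_residuals=standardize_residuals,
        )
        preds[test] = model.predict_path(s_test.absorbance, n_factors=max_factors)

    residuals = preds - y[:, None]
    secv = np.sqrt((residuals**2).mean(axis=0))
    opt = int(np.argmin(secv)) + 1  # argmin takes the first (smallest p) on ties
    return CVResult(secv=secv, opt_factors=opt, predictions=preds, groups=groups)


def global_h(m: MPLSModel, X: np.ndarray) -> np.ndarray:
    """Global H (GH) score of each spectrum under a fitted model.

    GH_i = D²_i / p where D² is the squared Mahalanobis distance of sample
    i's p-dimensional score vector under the mean and covariance of the
    calibration scores; the calibration-set average is therefore ~1, and
    GH >= 10 marks a spectral outlier.
    """
    T_cal = m.scores
    p = T_cal.shape[1]
    T = m.transform(X)
    mu = T_cal.mean(axis=0)
    cov = np.atleast_2d(np.cov(T_cal.T, ddof=1))
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        ridge = 1e-10 * max(np.trace(cov) / p, 1.0)
        warnings.warn("singular score covariance; ridge-stabilised", stacklevel=2)
        chol = np.linalg.cholesky(cov + ridge * np.eye(p))
    d = np.linalg.solve(chol, (T - mu).T)
    return (d * d).sum(axis=0) / p


def t_outliers(
    m: MPLSModel, X: np.ndarray, y: np.ndarray, threshold: float = DEFAULT_T_THRESHOLD
) -> np.ndarray:
    """Flag samples whose reference value does not fit the model.

    T_i = |y_i − ŷ_i| / SEC; flags T strictly greater than the threshold.
    If all residuals are zero (SEC = 0) nothing is flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    residuals = y - m.predict(X)
    s = sec(residuals, m.n_factors)
    if s == 0.0:
        return np.zeros(y.shape[0], dtype=bool)
    return np.abs(residuals) / s > threshold


@dataclasses.dataclass
class CalibrationResult:
    """Outcome of calibrating one pre-treatment on one constituent."""

    pretreatment: PretreatmentSpec  # fitted (carries MSC reference if any)
    model: MPLSModel
    n_used: int
    kept_ids: list[str]
    removed: list[dict]  # one entry per removed sample: pass, id, reason, value
    passes: int  # elimination passes actually executed (<= max_passes)
    secv_curve: np.ndarray
    opt_factors: int
    stats: EvalStats
    seed: int


def _fit_once(
    s: SpectraSet,
    y: np.ndarray,
    spec: PretreatmentSpec,
    max_factors: int,
    n_groups: int,
    seed: int,
    standardize_residuals: bool,
):
    fitted_spec = spec.fresh()
    cv = cross_validate(
        s, y, spec, max_factors, n_groups=n_groups, seed=seed,
        standardize_residuals=standardize_residuals,
    )
    treated = apply_pretreatment(s, fitted_spec, fit=True)
    model = mpls_fit(
        treated.absorbance,
        y,
        max_factors=cv.opt_factors,
        standardize_residuals=standardize_residuals,
        wavelengths=treated.wavelengths,
    )
    return fitted_spec, cv, treated, model


def calibrate(
    s: SpectraSet,
    y: np.ndarray,
    spec: PretreatmentSpec,
    max_factors: int | None = None,
    n_groups: int = 6,
    gh_threshold: float = DEFAULT_GH_THRESHOLD,
    t_threshold: float = DEFAULT_T_THRESHOLD,
    max_passes: int = 2,
    seed: int = 0,
    standardize_residuals: bool = True,
) -> CalibrationResult:
    """Full calibration of one pre-treatment with outlier elimination.

    Loop (at most ``max_passes`` elimination passes): pre-treat, select the
    factor count by cross-validation, fit, flag GH and T outliers jointly;
    if any are flagged and the pass budget is not exhausted, remove them
    and repeat.  Aborts if more than half of the samples would be removed.
    """
    y = np.asarray(y, dtype=float).ravel()
    n0 = s.n_samples
    if n0 < 20:
        raise ValueError(f"calibration needs >= 20 samples, got {n0}")
    if y.shape[0] != n0:
        raise ValueError("y length does not match the spectra")
    if max_factors is None:
        max_factors = default_max_factors(n0)

    keep = np.arange(n0)
    removed: list[dict] = []
    passes = 0
    while True:
        s_cur = s.subset(keep)
        y_cur = y[keep]
        fitted_spec, cv, treated, model = _fit_once(
            s_cur, y_cur, spec, max_factors, n_groups, seed, standardize_residuals
        )
        gh = global_h(model, treated.absorbance)
        t_flags = t_outliers(model, treated.absorbance, y_cur, t_threshold)
        h_flags = gh >= gh_threshold
        flags = h_flags | t_flags
        if not flags.any() or passes >= max_passes:
            break
        passes += 1
        for i in np.flatnonzero(flags):
            reason = "H" if h_flags[i] else "T"
            if h_flags[i] and t_flags[i]:
                reason = "H+T"
            removed.append(
                {
                    "pass": passes,
                    "sample_id": s_cur.sample_ids[i],
                    "reason": reason,
                    "gh": float(gh[i]),
                }
            )
        keep = keep[~flags]
        if keep.size < 0.5 * n0:
            raise RuntimeError(
                f"outlier elimination removed more than half the samples "
                f"({n0 - keep.size}/{n0}); calibration aborted"
            )

    fitted = model.predict(treated.absorbance)
    residuals = y_cur - fitted
    sd = float(y_cur.std(ddof=1))
    secv = float(cv.secv[cv.opt_factors - 1])
    stats = EvalStats(
        n=keep.size,
        mean=float(y_cur.mean()),
        sd=sd,
        sec=sec(residuals, model.n_factors),
        secv=secv,
        rsq_cal=rsq(y_cur, fitted, mode="calibration"),
        r2_cv=cv.r2_cv(y_cur),
        rpd_cv=rpd(sd, secv),
    )
    return CalibrationResult(
        pretreatment=fitted_spec,
        model=model,
        n_used=int(keep.size),
        kept_ids=list(s_cur.sample_ids),
        removed=removed,
        passes=passes,
        secv_curve=cv.secv,
        opt_factors=cv.opt_factors,
        stats=stats,
        seed=seed,
    )


@dataclasses.dataclass
class GridSearchResult:
    best: CalibrationResult
    leaderboard: pd.DataFrame  # one row per grid cell, ranked
    results: list[CalibrationResult | None]  # in grid order; None where failed


def grid_search(
    s: SpectraSet,
    y: np.ndarray,
    grid: Sequence[PretreatmentSpec] | None = None,
    seed: int = 0,
    **calibrate_kwargs,
) -> GridSearchResult:
    """Calibrate every pre-treatment in the grid and rank by SECV.

    Ranking: ascending SECV, ties broken by higher cross-validation R²,
    then by fewer factors.  The leaderboard mirrors the usual calibration
    report (derivative code, scatter method, factors, n, mean, SD, SEC,
    RSQ_cal, SECV, R²cv, RPD_cv).
    """
    if grid is None:
        grid = build_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("empty pre-treatment grid")

    rows = []
    results: list[CalibrationResult | None] = []
    errors: list[str] = []
    for cell, spec in enumerate(grid):
        try:
            res = calibrate(s, y, spec, seed=seed, **calibrate_kwargs)
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            results.append(None)
            errors.append(f"{spec.label}: {exc}")
            rows.append(
                {"cell": cell, "derivative": spec.code, "scatter": spec.scatter_method,
                 "error": str(exc)}
            )
            continue
        results.append(res)
        st = res.stats
        rows.append(
            {
                "cell": cell,
                "derivative": spec.code,
                "scatter": spec.scatter_method,
                "factors": res.opt_factors,
                "n": res.n_used,
                "mean": st.mean,
                "sd": st.sd,
                "sec": st.sec,
                "rsq_cal": st.rsq_cal,
                "secv": st.secv,
                "r2_cv": st.r2_cv,
                "rpd_cv": st.rpd_cv,
            }
        )
    if all(r is None for r in results):
        raise RuntimeError("all grid cells failed:\n" + "\n".join(errors))

    board = pd.DataFrame(rows)
    ok = board[board.get("secv").notna()] if "secv" in board else board
    order = ok.sort_values(
        by=["secv", "r2_cv", "factors"], ascending=[True, False, True], kind="mergesort"
    ).index
    board = pd.concat([board.loc[order], board.drop(index=order)]).reset_index(drop=True)
    best = results[int(board.iloc[0]["cell"])]
    assert best is not None
    return GridSearchResult(best=best, leaderboard=board, results=results)


def validate(result: CalibrationResult, s_val: SpectraSet, y_val: np.ndarray) -> EvalStats:
    """Apply a fitted calibration to an independent validation set.

    The stored pre-treatment (including any MSC reference learned on the
    calibration set) is replayed without refitting.  Returns SEP, the
    squared validation correlation RSQ_v, RPD_v = SD(y_val)/SEP and bias.
    """
    y_val = np.asarray(y_val, dtype=float).ravel()
    if s_val.n_samples == 0 or y_val.size == 0:
        raise ValueError("empty validation set")
    if y_val.shape[0] != s_val.n_samples:
        raise ValueError("y length does not match the validation spectra")
    treated = apply_pretreatment(s_val, result.pretreatment, fit=False)
    y_hat = result.model.predict(treated.absorbance)
    residuals = y_val - y_hat
    sep = secv_sep(residuals)
    sd = float(y_val.std(ddof=1))
    return EvalStats(
        n=y_val.size,
        mean=float(y_val.mean()),
        sd=sd,
        sep=sep,
        rsq_v=rsq(y_val, y_hat, mode="correlation"),
        rpd_v=rpd(sd, sep),
        bias=float((y_hat - y_val).mean()),
    )
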