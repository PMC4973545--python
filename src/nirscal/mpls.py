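"""Modified partial least squares (MPLS) regression, single response.

MPLS is NIPALS PLS1 with one change: after each factor is extracted, the
X-residual columns and the y-residuals are rescaled by their current
standard deviations before the next factor is sought.  Later factors are
therefore extracted from standardized residual space, which downweights
wavelengths already well explained.  With ``standardize_residuals=False``
the algorithm reduces exactly to plain NIPALS PLS1, which doubles as an
oracle mode for cross-checking.

The per-factor scalings are recorded so prediction replays the identical
chain; predictions remain affine in the input spectrum, and an explicit
coefficient vector can be recovered (``coefficients``).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["MPLSModel", "mpls_fit", "mpls_predict"]

_EPS_SD = 1e-12


@dataclasses.dataclass
class MPLSModel:
    """Fitted MPLS model.

    Arrays are indexed by factor ``k`` (axis 0).  ``x_scales[k]`` holds the
    per-column SDs applied to the X residuals *after* extracting factor
    ``k``; ``y_scale_cum[k]`` is the product of y-residual SDs applied
    *before* factor ``k`` (1 for plain PLS), which maps that factor's
    regression coefficient back to original y units.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, W), unit norm in the residual space of factor k
    loadings: np.ndarray  # (p, W)
    q: np.ndarray  # (p,) inner regression coefficients (scaled space)
    x_scales: np.ndarray  # (p, W)
    y_scale_cum: np.ndarray  # (p,)
    scores: np.ndarray  # (n, p) calibration scores
    n_factors: int
    standardize_residuals: bool
    wavelengths: np.ndarray | None = None

    # -- prediction -------------------------------------------------------

    def _check_grid(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.x_mean.shape[0]}"
            )
        return X

    def transform(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        """Score matrix (n, p) of new spectra under the fitted chain."""
        X = self._check_grid(X)
        p = self.n_factors if n_factors is None else min(n_factors, self.n_factors)
        Xc = X - self.x_mean
        T = np.empty((X.shape[0], p))
        for k in range(p):
            t = Xc @ self.weights[k]
            T[:, k] = t
            Xc = (Xc - np.outer(t, self.loadings[k])) / self.x_scales[k]
        return T

    def predict_path(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        """Predictions for every factor count 1..p as an (n, p) matrix.

        If more factors are requested than the model extracted (early stop
        on exhausted residuals), the last column is repeated.
        """
        X = self._check_grid(X)
        p_req = self.n_factors if n_factors is None else n_factors
        p = min(p_req, self.n_factors)
        T = self.transform(X, p)
        increments = T * (self.q[:p] * self.y_scale_cum[:p])
        path = self.y_mean + np.cumsum(increments, axis=1)
        if p_req > p:
            pad = np.repeat(path[:, -1:], p_req - p, axis=1)
            path = np.concatenate([path, pad], axis=1)
        return path

    def predict(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        return self.predict_path(X, n_factors)[:, -1]

    def coefficients(self, n_factors: int | None = None) -> tuple[np.ndarray, float]:
        """Equivalent (coefficient vector, intercept) in original units.

        The scaling/deflation chain is affine in the input spectrum, so the
        model collapses to ``y = intercept + x @ b``; computed by back-
        propagating each factor's weight through the preceding deflations.
        """
        p = self.n_factors if n_factors is None else min(n_factors, self.n_factors)
        b = np.zeros_like(self.x_mean)
        for k in range(p):
            v = self.weights[k].copy()
            for j in range(k - 1, -1, -1):
                v = v / self.x_scales[j]
                v -= self.weights[j] * (self.loadings[j] @ v)
            b += self.q[k] * self.y_scale_cum[k] * v
        return b, float(self.y_mean - self.x_mean @ b)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "format": "nirscal-mpls/1",
            "n_factors": int(self.n_factors),
            "standardize_residuals": bool(self.standardize_residuals),
            "y_mean": float(self.y_mean),
        }
        for name in ("x_mean", "weights", "loadings", "q", "x_scales", "y_scale_cum", "scores"):
            d[name] = getattr(self, name).tolist()
        if self.wavelengths is not None:
            d["wavelengths"] = self.wavelengths.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MPLSModel":
        if d.get("format") != "nirscal-mpls/1":
            raise ValueError(f"unknown model format {d.get('format')!r}")
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            q=np.asarray(d["q"], dtype=float),
            x_scales=np.asarray(d["x_scales"], dtype=float),
            y_scale_cum=np.asarray(d["y_scale_cum"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            n_factors=int(d["n_factors"]),
            standardize_residuals=bool(d["standardize_residuals"]),
            wavelengths=None if "wavelengths" not in d else np.asarray(d["wavelengths"]),
        )


def mpls_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int,
    standardize_residuals: bool = True,
    wavelengths: np.ndarray | None = None,
) -> MPLSModel:
    """Fit an MPLS (or, with standardization off, plain PLS1) model.

    Extraction stops early when the y residual no longer projects on X
    (weight norm below machine tolerance), so ``n_factors`` on the returned
    model may be smaller than ``max_factors``.  Deterministic for fixed
    input.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, W = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have different numbers of samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    if max_factors >= n - 1:
        raise ValueError(f"max_factors={max_factors} too large for n={n} samples")
    if np.std(y) < _EPS_SD:
        raise ValueError("y has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    f = y - y_mean

    weights, loadings, qs, x_scales, y_cum, scores = [], [], [], [], [], []
    c = 1.0  # cumulative y-residual scaling before the current factor
    ref_norm = np.linalg.norm(Xc.T @ f)
    for _ in range(max_factors):
        w = Xc.T @ f
        nrm = np.linalg.norm(w)
        if nrm <= 1e-12 * max(ref_norm, 1.0):
            break
        w /= nrm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            break
        qk = float(t @ f) / tt
        pk = (Xc.T @ t) / tt
        Xc = Xc - np.outer(t, pk)
        f = f - qk * t

        weights.append(w)
        loadings.append(pk)
        qs.append(qk)
        y_cum.append(c)
        scores.append(t)

        if standardize_residuals:
            sx = Xc.std(axis=0, ddof=1)
            sx = np.where(sx < _EPS_SD, 1.0, sx)
            Xc = Xc / sx
            sy = float(f.std(ddof=1))
            if sy < _EPS_SD:
                sy = 1.0
            f = f / sy
            c *= sy
        else:
            sx = np.ones(W)
        x_scales.append(sx)

    if not weights:
        raise ValueError("no factor could be extracted (X carries no y signal)")

    return MPLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=np.vstack(weights),
        loadings=np.vstack(loadings),
        q=np.asarray(qs),
        x_scales=np.vstack(x_scales),
        y_scale_cum=np.asarray(y_cum),
        scores=np.column_stack(scores),
        n_factors=len(qs),
        standardize_residuals=standardize_residuals,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
    )


def mpls_predict(m: MPLSModel, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
    """Predict the response for pre-treated spectra (functional alias)."""
    return m.predict(X, n_factors)
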