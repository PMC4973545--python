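"""Spectral pre-treatment: scatter correction and gap-segment derivatives.

A pre-treatment is the composition of a scatter-correction method and a
derivative "math treatment" coded ``d,g,s1,s2``: derivative order *d* (0-2),
gap *g* between the differenced points, and two moving-average segment
lengths *s1*, *s2* (points; ``s2 = 1`` means no second smoothing).  The raw
treatment is ``0,0,1,1``.  Scatter correction is applied before the
derivative.

Scatter-correction family
-------------------------
``None``
    Identity.
``SNV``
    Standard normal variate: each spectrum is z-scored (row mean 0, sample
    SD 1), removing additive offsets and multiplicative amplitude.
``Detrend``
    Subtracts a per-spectrum least-squares quadratic in wavelength,
    removing curved baseline drift.
``SNVD``
    SNV followed by Detrend.
``SMSC`` / ``WMSC`` / ``IMSC``
    Multiplicative scatter correction against a reference (mean) spectrum
    learned on the calibration set: each spectrum is regressed on the
    reference (ordinary, inverse-variance weighted, or with the roles of
    spectrum and reference swapped) and mapped back to the reference scale.

The standard screening grid crosses the 7 scatter methods with 11 math
treatments, giving 77 candidate pre-treatments.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .spectra_io import SpectraSet

__all__ = [
    "PretreatmentSpec",
    "ScatterReference",
    "SCATTER_METHODS",
    "MATH_TREATMENTS",
    "parse_treatment_code",
    "scatter_correct",
    "gap_segment_derivative",
    "apply_pretreatment",
    "build_grid",
    "reduced_grid",
]

SCATTER_METHODS = ("None", "SNVD", "SNV", "Detrend", "SMSC", "WMSC", "IMSC")

#: the 11 derivative codes of the standard screening grid
MATH_TREATMENTS = (
    "0,0,1,1",
    "1,4,4,1",
    "2,4,4,1",
    "1,8,8,1",
    "2,8,8,1",
    "1,10,10,1",
    "2,10,10,1",
    "1,12,12,1",
    "2,12,12,1",
    "1,16,16,1",
    "2,16,16,1",
)

_MSC_METHODS = ("SMSC", "WMSC", "IMSC")


@dataclasses.dataclass
class ScatterReference:
    """Reference learned on a calibration set for MSC-family corrections."""

    mean_spectrum: np.ndarray
    weights: np.ndarray | None = None  # inverse-variance weights (WMSC)


@dataclasses.dataclass
class PretreatmentSpec:
    """One scatter-correction + derivative combination.

    ``reference`` is populated when an MSC-family method is fitted on a
    calibration set and is reused verbatim at prediction time.
    """

    derivative_order: int
    gap: int
    segment1: int
    segment2: int
    scatter_method: str = "None"
    reference: ScatterReference | None = None

    def __post_init__(self) -> None:
        d, g, s1, s2 = self.derivative_order, self.gap, self.segment1, self.segment2
        if d not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {d}")
        if min(g, s1, s2) < 0:
            raise ValueError("derivative code numbers must be non-negative")
        if d >= 1 and g < 1:
            raise ValueError(f"derivative order {d} requires gap >= 1")
        if s1 < 1 or s2 < 1:
            raise ValueError("segment lengths must be >= 1")
        if self.scatter_method not in SCATTER_METHODS:
            raise ValueError(f"unknown scatter method {self.scatter_method!r}")

    @property
    def code(self) -> str:
        return f"{self.derivative_order},{self.gap},{self.segment1},{self.segment2}"

    @property
    def label(self) -> str:
        return f"{self.code}+{self.scatter_method}"

    @property
    def is_raw(self) -> bool:
        return (self.derivative_order, self.gap, self.segment1, self.segment2) == (0, 0, 1, 1)

    def fresh(self) -> "PretreatmentSpec":
        """Unfitted copy (drops any learned scatter reference)."""
        return dataclasses.replace(self, reference=None)


def parse_treatment_code(code: str, scatter_method: str = "None") -> PretreatmentSpec:
    """Parse a ``d,g,s1,s2`` derivative code into a PretreatmentSpec."""
    parts = code.split(",")
    if len(parts) != 4:
        raise ValueError(f"treatment code must have four numbers, got {code!r}")
    try:
        d, g, s1, s2 = (int(p.strip()) for p in parts)
    except ValueError:
        raise ValueError(f"non-integer field in treatment code {code!r}") from None
    return PretreatmentSpec(d, g, s1, s2, scatter_method=scatter_method)


def build_grid() -> list[PretreatmentSpec]:
    """The 77-combination screening grid: 7 scatter methods x 11 codes."""
    return [
        parse_treatment_code(code, scatter_method=method)
        for method, code in itertools.product(SCATTER_METHODS, MATH_TREATMENTS)
    ]


def reduced_grid() -> list[PretreatmentSpec]:
    """A 20-cell screening subset (4 scatter methods x 5 codes).

    Keeps the raw, first- and second-derivative codes that span the gap
    range, crossed with no correction, SNV, SNVD and SMSC.  Useful when a
    full 77-cell search is not warranted.
    """
    methods = ("None", "SNV", "SNVD", "SMSC")
    codes = ("0,0,1,1", "1,4,4,1", "2,4,4,1", "2,8,8,1", "2,10,10,1")
    return [
        parse_treatment_code(code, scatter_method=method)
        for method, code in itertools.product(methods, codes)
    ]


# ---------------------------------------------------------------------------
# scatter correction


def _snv(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() < 1e-300)
    if bad.size:
        raise ValueError(f"SNV undefined for constant spectrum at row(s) {bad.tolist()}")
    return (X - mean) / sd

def _detrend(X: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    # quadratic baseline removal; scaled wavelength keeps the fit conditioned
    z = (wavelengths - wavelengths.mean()) / (wavelengths.std() or 1.0)
    design = np.column_stack([np.ones_like(z), z, z * z])
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    return X - (design @ coef).T


def _msc_regress(X: np.ndarray, ref: np.ndarray, weights: np.ndarray | None):
    """Weighted LS slope/intercept of each row on the reference spectrum."""
    w = np.ones_like(ref) if weights is None else weights
    wsum = w.sum()
    ref_mean = (w * ref).sum() / wsum
    row_mean = (X * w).sum(axis=1) / wsum
    ref_c = ref - ref_mean
    denom = (w * ref_c * ref_c).sum()
    slope = ((X - row_mean[:, None]) * (w * ref_c)).sum(axis=1) / denom
    intercept = row_mean - slope * ref_mean
    return slope, intercept


def scatter_correct(
    X: np.ndarray,
    method: str,
    wavelengths: np.ndarray | None = None,
    reference: ScatterReference | None = None,
    fit: bool = False,
) -> tuple[np.ndarray, ScatterReference | None]:
    """Apply one scatter-correction method to an absorbance matrix.

    MSC-family methods need a fitted ``reference``; pass ``fit=True`` to
    learn it from ``X`` (the calibration set).  Returns the corrected matrix
    and the reference (``None`` for reference-free methods).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if method == "None":
        return X.copy(), None
    if method == "SNV":
        return _snv(X), None
    if method in ("Detrend", "SNVD"):
        if wavelengths is None:
            raise ValueError(f"{method} requires the wavelength grid")
        Y = _snv(X) if method == "SNVD" else X
        return _detrend(Y, np.asarray(wavelengths, dtype=float)), None
    if method not in _MSC_METHODS:
        raise ValueError(f"unknown scatter method {method!r}")

    if fit:
        weights = None
        if method == "WMSC":
            var = X.var(axis=0, ddof=1)
            weights = 1.0 / np.maximum(var, 1e-12 * max(var.max(), 1e-30))
        reference = ScatterReference(X.mean(axis=0), weights)
    if reference is None:
        raise ValueError(f"{method} requires a fitted reference (or fit=True)")
    ref = reference.mean_spectrum
    if ref.shape[0] != X.shape[1]:
        raise ValueError("scatter reference does not match the spectral grid")

    if method in ("SMSC", "WMSC"):
        weights = reference.weights if method == "WMSC" else None
        slope, intercept = _msc_regress(X, ref, weights)
        bad = np.flatnonzero(np.abs(slope) < 1e-12)
        if bad.size:
            raise ValueError(f"MSC slope ~ 0 at row(s) {bad.tolist()}")
        return (X - intercept[:, None]) / slope[:, None], reference
    # IMSC: regress the reference on each spectrum, return the fitted values
    row_mean = X.mean(axis=1)
    Xc = X - row_mean[:, None]
    denom = (Xc * Xc).sum(axis=1)
    bad = np.flatnonzero(denom < 1e-300)
    if bad.size:
        raise ValueError(f"IMSC undefined for constant spectrum at row(s) {bad.tolist()}")
    slope = (Xc * (ref - ref.mean())).sum(axis=1) / denom
    bad = np.flatnonzero(np.abs(slope) < 1e-12)
    if bad.size:
        raise ValueError(f"IMSC slope ~ 0 at row(s) {bad.tolist()}")
    intercept = ref.mean() - slope * row_mean
    return intercept[:, None] + slope[:, None] * X, reference


# ---------------------------------------------------------------------------
# gap-segment derivative


def _moving_average(X: np.ndarray, size: int) -> tuple[np.ndarray, int]:
    """Centered moving average over ``size`` points ('valid' region only).

    Returns the smoothed matrix and the offset of its first column in the
    original index space (floor-centred for even sizes).
    """
    if size == 1:
        return X, 0
    # running sums: exact to ~1e-13 on absorbance-scale data and O(nW)
    c = np.cumsum(np.concatenate([np.zeros((X.shape[0], 1)), X], axis=1), axis=1)
    out = (c[:, size:] - c[:, :-size]) / size
    return out, (size - 1) // 2


def gap_segment_derivative(
    X: np.ndarray, d: int, g: int, s1: int, s2: int
) -> tuple[np.ndarray, int]:
    """Gap-segment derivative of spectra (rows of ``X``).

    Each spectrum is smoothed with a centred moving average of ``s1``
    points, differenced across a gap of ``g`` points (first derivative:
    ``x̄(i+g) − x̄(i−g)``; second: ``x̄(i−g) − 2·x̄(i) + x̄(i+g)``;
    ``d = 0`` keeps the smoothed spectrum), then smoothed again over ``s2``
    points.  Differences are not divided by the gap width, matching common
    chemometrics-software convention; only relative scale matters to a
    centred regression.  Edges are truncated, never padded.

    Returns the transformed matrix and the offset of its first retained
    column on the original grid.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if d not in (0, 1, 2):
        raise ValueError(f"derivative order must be 0, 1 or 2, got {d}")
    if d >= 1 and g < 1:
        raise ValueError("gap must be >= 1 for a derivative")
    if s1 < 1 or s2 < 1:
        raise ValueError("segment lengths must be >= 1")
    needed = (s1 - 1) + (2 * g if d >= 1 else 0) + (s2 - 1) + 1
    if X.shape[1] < needed + 1:
        raise ValueError(
            f"spectrum length {X.shape[1]} too short for code {d},{g},{s1},{s2}"
        )

    sm, offset = _moving_average(X, s1)
    if d == 0:
        y = sm
    elif d == 1:
        y = sm[:, 2 * g :] - sm[:, : -2 * g]
        offset += g
    else:
        y = sm[:, : -2 * g] - 2.0 * sm[:, g : -g] + sm[:, 2 * g :]
        offset += g
    y, off2 = _moving_average(y, s2)
    return y, offset + off2


def apply_pretreatment(
    s: SpectraSet, spec: PretreatmentSpec, fit: bool = False
) -> SpectraSet:
    """Scatter-correct then differentiate a SpectraSet.

    In fit mode, MSC references (and WMSC weights) are learned from ``s``
    and stored on ``spec`` so the identical transform can be replayed on new
    spectra.  The returned SpectraSet carries the truncated wavelength grid.
    """
    Xc, reference = scatter_correct(
        s.absorbance,
        spec.scatter_method,
        wavelengths=s.wavelengths,
        reference=spec.reference,
        fit=fit,
    )
    if fit and reference is not None:
        spec.reference = reference
    y, offset = gap_segment_derivative(
        Xc, spec.derivative_order, spec.gap, spec.segment1, spec.segment2
    )
    wl = s.wavelengths[offset : offset + y.shape[1]]
    return SpectraSet(wl, y, list(s.sample_ids), None if s.subsample_ids is None else list(s.subsample_ids))
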