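"""Spectra and reference-table I/O.

Spectra are stored as a samples x wavelengths matrix of log(1/R) absorbance
on an evenly spaced nanometre grid (default 400-2498 nm in 2 nm steps, 1050
points, the working range of scanning monochromator instruments).  Each
sample may be scanned in several independent subsamples; replicate scans are
averaged before chemometric analysis.

File dialect: comma-separated text with a ``sample_id`` column, an optional
``subsample_id`` column, and one numeric column per wavelength (the header
row carries the wavelengths in nm).  One scan per row.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "SpectraFormatError",
    "SpectraParseError",
    "default_grid",
    "read_spectra",
    "write_spectra",
    "average_duplicates",
    "split_cal_val",
    "COMPOSITION_COLUMNS",
    "ENERGY_COLUMNS",
]

COMPOSITION_COLUMNS = ("moisture", "cp", "ee", "ash", "adf", "ndf")
ENERGY_COLUMNS = ("de_d", "me_d", "de_c", "me_c")


class SpectraFormatError(ValueError):
    """The wavelength grid or file layout violates the declared dialect."""


class SpectraParseError(ValueError):
    """A cell in a spectra file could not be parsed as a number."""


def default_grid() -> np.ndarray:
    """The 400-2498 nm grid at 2 nm steps (1050 points)."""
    return np.arange(400.0, 2500.0, 2.0)


def _validate_grid(wavelengths: np.ndarray) -> None:
    if wavelengths.ndim != 1 or wavelengths.size < 2:
        raise SpectraFormatError("wavelength grid must be a 1-D vector with >= 2 points")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise SpectraFormatError("wavelengths must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise SpectraFormatError(
            f"wavelength grid has non-constant step (first step {steps[0]:g})"
        )


@dataclasses.dataclass
class SpectraSet:
    """Absorbance spectra on a common, evenly spaced wavelength grid.

    Parameters
    ----------
    wavelengths : array, shape (W,)
        Strictly increasing grid in nm with constant step.
    absorbance : array, shape (n, W)
        log(1/R) values, one scan per row.
    sample_ids : sequence of str
        One id per row.  Must be unique unless ``subsample_ids`` marks
        replicate scans of the same sample.
    subsample_ids : sequence of str, optional
        Replicate-scan labels; rows sharing a ``sample_id`` are treated as
        repeated scans of that sample.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    subsample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.subsample_ids is not None:
            self.subsample_ids = [str(s) for s in self.subsample_ids]
        _validate_grid(self.wavelengths)
        n, w = self.absorbance.shape
        if w != self.wavelengths.size:
            raise SpectraFormatError(
                f"absorbance has {w} columns but the grid has {self.wavelengths.size} points"
            )
        if len(self.sample_ids) != n:
            raise SpectraFormatError("sample_ids length does not match the number of rows")
        if self.subsample_ids is not None and len(self.subsample_ids) != n:
            raise SpectraFormatError("subsample_ids length does not match the number of rows")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("absorbance contains non-finite values")
        if self.subsample_ids is None and len(set(self.sample_ids)) != n:
            raise SpectraFormatError(
                "duplicate sample_ids without subsample_ids; label replicate scans"
            )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, index: Sequence[int] | np.ndarray) -> "SpectraSet":
        """Row subset (by positional index or boolean mask), grid unchanged."""
        idx = np.asarray(index)
        idx = np.flatnonzero(idx) if idx.dtype == bool else idx.astype(int)
        sub_ids = None
        if self.subsample_ids is not None:
            sub_ids = [self.subsample_ids[i] for i in idx]
        return SpectraSet(
            self.wavelengths.copy(),
            self.absorbance[idx],
            [self.sample_ids[i] for i in idx],
            sub_ids,
        )

    def select_samples(self, ids: Sequence[str]) -> "SpectraSet":
        """Subset by sample id, in the order given."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"sample id {exc.args[0]!r} not present") from None
        return self.subset(idx)


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a spectra CSV (dialect described in the module docstring).

    Raises
    ------
    SpectraFormatError
        If the wavelength header is missing, non-monotone, or gapped.
    SpectraParseError
        If an absorbance cell is not numeric (reports row and column).
    """
    frame = pd.read_csv(path, dtype=str)
    if "sample_id" not in frame.columns:
        raise SpectraFormatError("spectra file must have a 'sample_id' column")
    meta_cols = ["sample_id"]
    if "subsample_id" in frame.columns:
        meta_cols.append("subsample_id")
    wl_cols = [c for c in frame.columns if c not in meta_cols]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from None
    _validate_grid(wavelengths)

    values = np.empty((len(frame), len(wl_cols)))
    for j, col in enumerate(wl_cols):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna())[0])
            raise SpectraParseError(
                f"non-numeric value at data row {row + 1}, column {col!r}"
            )
        values[:, j] = numeric.to_numpy()

    sub = frame["subsample_id"].tolist() if "subsample_id" in frame.columns else None
    return SpectraSet(wavelengths, values, frame["sample_id"].tolist(), sub)


def write_spectra(s: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as CSV; values round-trip exactly through repr."""
    data: dict[str, object] = {"sample_id": s.sample_ids}
    if s.subsample_ids is not None:
        data["subsample_id"] = s.subsample_ids
    for j, wl in enumerate(s.wavelengths):
        data[f"{wl:g}"] = s.absorbance[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def average_duplicates(s: SpectraSet) -> SpectraSet:
    """Average replicate scans of each sample into one spectrum.

    Scans are grouped by ``sample_id``; the arithmetic mean is taken on the
    raw log(1/R) spectra.  Output rows follow the order of first occurrence.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(s.sample_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    if any(len(v) == 0 for v in groups.values()):  # pragma: no cover - unreachable
        raise ValueError("sample with zero scans")
    mean = np.vstack([s.absorbance[groups[sid]].mean(axis=0) for sid in order])
    return SpectraSet(s.wavelengths.copy(), mean, order, None)


def split_cal_val(
    ids: Sequence[str], n_val: int, seed: int
) -> tuple[list[str], list[str]]:
    """Randomly split sample ids into calibration and validation sets.

    A seeded uniform draw without stratification.  The two outputs are
    disjoint, exhaustive, and preserve the input ordering within each set.
    """
    ids = list(ids)
    n = len(ids)
    if not 0 < n_val < n:
        raise ValueError(f"n_val must be in (0, {n}), got {n_val}")
    rng = np.random.default_rng(seed)
    val_pos = set(rng.permutation(n)[:n_val].tolist())
    cal = [ids[i] for i in range(n) if i not in val_pos]
    val = [ids[i] for i in range(n) if i in val_pos]
    return cal, val


@dataclasses.dataclass
class ReferenceTable:
    """Per-sample chemical composition and reference energy values.

    Wraps a DataFrame with a ``sample_id`` column, composition columns
    (% DM): moisture, cp, ee, ash, adf, ndf; energy columns (MJ/kg DM):
    de_d, me_d (determined in digestion-metabolism trials) and de_c, me_c
    (calculated from composition).  Optional duplicate laboratory
    determinations are stored as ``<constituent>_a`` / ``<constituent>_b``
    and feed the standard error of laboratory (SEL).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("reference table must have a 'sample_id' column")
        self.data = self.data.reset_index(drop=True)
        self.data["sample_id"] = self.data["sample_id"].astype(str)
        for col in COMPOSITION_COLUMNS:
            if col in self.data.columns and (self.data[col] < 0).any():
                raise ValueError(f"negative composition value in column {col!r}")
        if {"de_d", "me_d"} <= set(self.data.columns):
            both = self.data[["de_d", "me_d"]].dropna()
            if (both["me_d"] > both["de_d"] + 1e-9).any():
                raise ValueError("ME_D exceeds DE_D for at least one sample")
        if {"de_c", "me_c"} <= set(self.data.columns):
            both = self.data[["de_c", "me_c"]].dropna()
            if (both["me_c"] > both["de_c"] + 1e-9).any():
                raise ValueError("ME_C exceeds DE_C for at least one sample")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        return cls(pd.read_csv(path, dtype={"sample_id": str}))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def values(self, column: str, ids: Sequence[str] | None = None) -> np.ndarray:
        """Values of one column, optionally aligned to a given id order."""
        if column not in self.data.columns:
            raise KeyError(f"column {column!r} not in reference table")
        series = self.data.set_index("sample_id")[column]
        if ids is not None:
            series = series.reindex(list(ids))
            if series.isna().any():
                missing = series.index[series.isna()][0]
                raise KeyError(f"sample id {missing!r} missing value for {column!r}")
        return series.to_numpy(dtype=float)

    def duplicate_pairs(self, constituent: str) -> np.ndarray:
        """(m, 2) array of duplicate lab determinations for one constituent."""
        a, b = f"{constituent}_a", f"{constituent}_b"
        if a not in self.data.columns or b not in self.data.columns:
            raise KeyError(f"no duplicate columns for {constituent!r}")
        pairs = self.data[[a, b]].dropna().to_numpy(dtype=float)
        if pairs.size == 0:
            raise ValueError(f"no duplicate pairs for {constituent!r}")
        return pairs
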