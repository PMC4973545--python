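"""Synthetic corn NIRS datasets with known structure.

No public corn spectra accompany the reference composition/energy ranges
this package targets, so every pipeline stage is exercised on simulated
data: proximate compositions drawn from a truncated multivariate normal
calibrated to the published per-constituent ranges, means and SDs;
reference energies from the Noblet–Perez equations (calculated values
exactly, determined values with seeded metabolism-trial noise); and
absorbance spectra built from a fixed library of Gaussian absorption
bands plus baseline, multiplicative scatter, additive offsets, tilt and
white noise — the qualitative features of real log(1/R) corn spectra
(broad peaks, baseline shifts, parallel scatter shifts).

The band library is an invented fixture, not corn spectroscopy: band
centres sit in plausible NIR regions (1100-2400 nm) but amplitudes are
chosen only so that composition is recoverable at realistic signal-to-
noise.  See the methods note for what this does and does not demonstrate
about real spectra.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .energy import noblet_perez_de, noblet_perez_me
from .spectra_io import (
    COMPOSITION_COLUMNS,
    ReferenceTable,
    SpectraSet,
    default_grid,
    write_spectra,
)

__all__ = [
    "SimConfig",
    "sample_compositions",
    "generate_energies",
    "generate_spectra",
    "make_dataset",
]

# per-constituent (min, max, mean, sd) in % DM for the entire 117-sample set
DEFAULT_COMPOSITION_STATS: dict[str, tuple[float, float, float, float]] = {
    "moisture": (10.90, 14.00, 12.63, 0.892),
    "cp": (7.80, 11.00, 9.41, 0.718),
    "ee": (2.09, 4.97, 3.87, 0.580),
    "ash": (0.83, 1.82, 1.41, 0.257),
    "adf": (1.73, 3.69, 2.33, 0.443),
    "ndf": (6.40, 19.37, 12.02, 3.083),
}

# duplicate-determination laboratory error (SEL) per constituent, % DM
DEFAULT_SEL: dict[str, float] = {
    "moisture": 0.129,
    "cp": 0.057,
    "ee": 0.025,
    "ash": 0.015,
    "adf": 0.053,
    "ndf": 0.228,
}

# Gaussian absorption bands per constituent: (centre nm, width nm,
# amplitude in absorbance units per g/kg DM).  Invented fixture; centres
# sit in overtone/combination regions where organic constituents absorb.
DEFAULT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "moisture": [(1450.0, 45.0, 1.2e-3), (1940.0, 55.0, 1.6e-3)],
    "cp": [(1510.0, 40.0, 1.0e-3), (2055.0, 45.0, 1.3e-3), (2180.0, 40.0, 0.9e-3)],
    "ee": [(1725.0, 35.0, 1.4e-3), (2310.0, 35.0, 1.6e-3), (2348.0, 30.0, 1.2e-3)],
    "ash": [(2100.0, 60.0, 0.6e-3)],
    "adf": [(1780.0, 45.0, 0.8e-3), (2270.0, 40.0, 0.9e-3)],
    "ndf": [(1680.0, 50.0, 0.8e-3), (2100.0, 50.0, 1.0e-3), (2270.0, 45.0, 1.1e-3)],
}

# Single-latent-factor correlation structure: a "fibre quality" axis along
# which NDF, ADF and ash rise while protein and oil fall (moisture is
# independent).  corr = L L^T + diag(1 - L^2) is positive definite by
# construction, and propagating the composition SDs through the DE
# equation under it yields an energy CV near the ~4.5 % reported for
# diverse corn collections; independent constituents would understate it.
_LOADINGS = {"moisture": 0.0, "cp": -0.7, "ee": -0.7, "ash": 0.7, "adf": 0.8, "ndf": 0.9}
_L = np.array([_LOADINGS[c] for c in COMPOSITION_COLUMNS])
DEFAULT_CORRELATION = np.outer(_L, _L) + np.diag(1.0 - _L**2)


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults reproduce the reference study's design: 117 samples scanned
    in two subsamples on the 400-2498 nm / 2 nm grid, compositions matching
    the published entire-set ranges and moments, lab noise on the
    determined energies of 0.15 MJ/kg DM (chosen so that the reference-SD
    to cross-validation-error regime of the published models is
    attainable but not trivial).
    """

    n_samples: int = 117
    duplicate_scans: int = 2
    wavelengths: np.ndarray | None = None  # default 400-2498 nm / 2 nm
    composition_stats: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_STATS)
    )
    correlation: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_CORRELATION.copy()
    )
    bands: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_BANDS))
    sel: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_SEL))
    # baseline shape (absorbance units across the grid)
    baseline_offset: float = 0.35
    baseline_tilt: float = 0.25
    baseline_curve: float = 0.05
    # per-scan perturbations
    scatter_mult_sd: float = 0.05
    additive_offset_sd: float = 0.02
    tilt_sd: float = 0.01
    white_noise_sd: float = 1.0e-3
    # determined-energy (metabolism trial) error, MJ/kg DM
    lab_noise_sd: float = 0.15
    urinary_noise_sd: float = 0.04

    def grid(self) -> np.ndarray:
        return default_grid() if self.wavelengths is None else np.asarray(self.wavelengths, float)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wavelengths"] = None if self.wavelengths is None else list(map(float, self.wavelengths))
        d["correlation"] = np.asarray(self.correlation).tolist()
        d["bands"] = {k: [list(b) for b in v] for k, v in self.bands.items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.as_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("wavelengths") is not None:
            d["wavelengths"] = np.asarray(d["wavelengths"], dtype=float)
        if "correlation" in d:
            d["correlation"] = np.asarray(d["correlation"], dtype=float)
        if "bands" in d:
            d["bands"] = {k: [tuple(b) for b in v] for k, v in d["bands"].items()}
        if "composition_stats" in d:
            d["composition_stats"] = {
                k: tuple(v) for k, v in d["composition_stats"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text))


def sample_compositions(cfg: SimConfig, seed=0) -> pd.DataFrame:
    """Draw compositions (% DM) from a range-truncated multivariate normal.

    Gaussian with the configured per-constituent means/SDs and correlation
    matrix, rejected and redrawn until every constituent lies inside its
    configured [min, max] range.  Seed-reproducible.
    """
    names = list(COMPOSITION_COLUMNS)
    stats = [cfg.composition_stats[c] for c in names]
    mins = np.array([s[0] for s in stats])
    maxs = np.array([s[1] for s in stats])
    means = np.array([s[2] for s in stats])
    sds = np.array([s[3] for s in stats])
    if np.any(maxs <= mins) or np.any(sds <= 0):
        raise ValueError("composition ranges/SDs must be non-degenerate")
    corr = np.asarray(cfg.correlation, dtype=float)
    if corr.shape != (len(names), len(names)):
        raise ValueError("correlation matrix has the wrong shape")
    if np.min(np.linalg.eigvalsh((corr + corr.T) / 2)) < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    cov = corr * np.outer(sds, sds)

    rng = np.random.default_rng(seed)
    rows = np.empty((0, len(names)))
    for _ in range(1000):
        draw = rng.multivariate_normal(means, cov, size=2 * cfg.n_samples, method="svd")
        ok = np.all((draw >= mins) & (draw <= maxs), axis=1)
        rows = np.vstack([rows, draw[ok]])
        if rows.shape[0] >= cfg.n_samples:
            break
    else:  # pragma: no cover - only with absurd ranges
        raise RuntimeError("rejection sampling failed; widen the composition ranges")
    rows = rows[: cfg.n_samples]
    out = pd.DataFrame(rows, columns=names)
    out.insert(0, "sample_id", [f"corn{i + 1:03d}" for i in range(cfg.n_samples)])
    return out


def generate_energies(compositions: pd.DataFrame, cfg: SimConfig, seed=0) -> pd.DataFrame:
    """Reference energies (MJ/kg DM) for a composition table (% DM).

    Calculated values (de_c, me_c) are the exact Noblet–Perez outputs for
    the tabulated composition.  Determined values (de_d, me_d) add a shared
    per-sample trial error (SD ``lab_noise_sd``) — digestibility error
    propagates to DE and ME alike — plus a small independent urinary
    component for ME; ME is clipped to never exceed DE.
    """
    g = {c: compositions[c].to_numpy() * 10.0 for c in ("ash", "cp", "ee", "ndf")}
    de_c = noblet_perez_de(g["ash"], g["cp"], g["ee"], g["ndf"])
    me_c = noblet_perez_me(de_c, g["cp"])
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, cfg.lab_noise_sd, size=len(compositions)) if cfg.lab_noise_sd > 0 else 0.0
    u = (
        rng.normal(0.0, cfg.urinary_noise_sd, size=len(compositions))
        if cfg.urinary_noise_sd > 0
        else 0.0
    )
    de_d = de_c + e
    ratio = 1.003 - 0.00021 * g["cp"]
    me_d = me_c + np.asarray(e) * ratio + u
    me_d = np.minimum(me_d, de_d)
    return pd.DataFrame(
        {
            "sample_id": compositions["sample_id"],
            "de_d": de_d,
            "me_d": me_d,
            "de_c": de_c,
            "me_c": me_c,
        }
    )


def _band_matrix(wavelengths: np.ndarray, bands) -> np.ndarray:
    profile = np.zeros_like(wavelengths)
    for centre, width, amplitude in bands:
        profile += amplitude * np.exp(-0.5 * ((wavelengths - centre) / width) ** 2)
    return profile


def generate_spectra(compositions: pd.DataFrame, cfg: SimConfig, seed=0) -> SpectraSet:
    """Simulated log(1/R) spectra with replicate scans per sample.

    Each scan is ``m × (baseline + Σ_c conc_c · band_c) + a + t·z + ε``
    with per-scan multiplicative scatter ``m ~ N(1, scatter_mult_sd)``,
    additive offset ``a``, baseline tilt variation ``t`` (``z`` is the
    centred normalised wavelength) and white noise ``ε``.  Replicate scans
    of one sample share its composition but draw independent scatter and
    noise.
    """
    wl = cfg.grid()
    z = (wl - wl.mean()) / (wl.max() - wl.min())
    baseline = cfg.baseline_offset + cfg.baseline_tilt * z + cfg.baseline_curve * (z**2)
    profiles = np.vstack(
        [_band_matrix(wl, cfg.bands.get(c, [])) for c in COMPOSITION_COLUMNS]
    )  # (n_constituents, W)
    conc = compositions[list(COMPOSITION_COLUMNS)].to_numpy() * 10.0  # g/kg DM
    signal = conc @ profiles + baseline  # (n, W)

    n, k = len(compositions), cfg.duplicate_scans
    if k < 1:
        raise ValueError("duplicate_scans must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((n * k, wl.size))
    sample_ids: list[str] = []
    subsample_ids: list[str] | None = [] if k > 1 else None
    for i in range(n):
        for j in range(k):
            mult = 1.0 + rng.normal(0.0, cfg.scatter_mult_sd)
            add = rng.normal(0.0, cfg.additive_offset_sd)
            tilt = rng.normal(0.0, cfg.tilt_sd)
            noise = rng.normal(0.0, cfg.white_noise_sd, size=wl.size)
            rows[i * k + j] = mult * signal[i] + add + tilt * z + noise
            sample_ids.append(str(compositions["sample_id"].iloc[i]))
            if subsample_ids is not None:
                subsample_ids.append(chr(ord("a") + j))
    return SpectraSet(wl, rows, sample_ids, subsample_ids)


def _lab_duplicates(compositions: pd.DataFrame, cfg: SimConfig, seed) -> pd.DataFrame:
    """Duplicate lab determinations around the true composition (for SEL)."""
    rng = np.random.default_rng(seed)
    out = {}
    for c in COMPOSITION_COLUMNS:
        true = compositions[c].to_numpy()
        s = cfg.sel.get(c, 0.0)
        out[f"{c}_a"] = np.maximum(true + rng.normal(0.0, s, size=true.size), 0.0)
        out[f"{c}_b"] = np.maximum(true + rng.normal(0.0, s, size=true.size), 0.0)
    return pd.DataFrame(out)


def make_dataset(
    cfg: SimConfig, seed: int = 0, outdir: str | Path | None = None
) -> tuple[SpectraSet, ReferenceTable]:
    """Compose the three generators into one dataset.

    Returns the spectra (with replicate scans) and the reference table
    (composition in % DM, duplicate lab values, and the four energy
    columns).  If ``outdir`` is given, writes ``spectra.csv`` and
    ``reference.csv`` there.  Byte-identical for identical (cfg, seed).
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    comp = sample_compositions(cfg, seed=ss[0])
    energies = generate_energies(comp, cfg, seed=ss[1])
    spectra = generate_spectra(comp, cfg, seed=ss[2])
    dups = _lab_duplicates(comp, cfg, seed=ss[3])
    table = pd.concat(
        [comp.reset_index(drop=True), dups, energies.drop(columns="sample_id")], axis=1
    )
    ref = ReferenceTable(table)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_spectra(spectra, outdir / "spectra.csv")
        ref.to_csv(outdir / "reference.csv")
    return spectra, ref
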