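"""Reference energy values: prediction equations and the direct method.

The Noblet–Perez equations predict the digestible energy (DE) and
metabolizable energy (ME) content of pig feeds from proximate composition
expressed in g/kg dry matter (DM):

    DE (MJ/kg DM) = (4168 − 9.1·Ash + 1.9·CP + 3.9·EE − 3.6·NDF) × 4.18/1000
    ME (MJ/kg DM) = DE × (1.003 − 0.00021·CP)

The leading constant is in kcal/kg; the factor 4.18/1000 converts to MJ/kg.
Composition tables are often reported in % DM; multiply by 10 to obtain
g/kg DM before evaluating the equations.

The direct method recovers DE/ME of a single test ingredient from a
digestion-metabolism balance trial in which that ingredient is the only
energy source of the diet (here fed at a 96.8 % inclusion rate):
diet DE = (GE_intake − GE_feces)/intake, diet ME additionally subtracts
urinary GE, and ingredient values are diet values divided by the inclusion
fraction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "Composition",
    "BalanceRecord",
    "KCAL_TO_MJ",
    "DEFAULT_CORN_INCLUSION",
    "pct_dm_to_g_kg",
    "noblet_perez_de",
    "noblet_perez_me",
    "direct_method",
]

KCAL_TO_MJ = 4.18 / 1000.0  # conversion used with the equations' constants
DEFAULT_CORN_INCLUSION = 0.968


def pct_dm_to_g_kg(value):
    """Convert % DM to g/kg DM (×10)."""
    return np.asarray(value, dtype=float) * 10.0


@dataclasses.dataclass
class Composition:
    """Proximate composition in g/kg DM (ADF optional, not used by the equations)."""

    ash: float
    cp: float
    ee: float
    ndf: float
    adf: float | None = None

    def __post_init__(self) -> None:
        for name in ("ash", "cp", "ee", "ndf"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")
        if self.adf is not None and self.ndf < self.adf:
            raise ValueError("NDF must be >= ADF")

    def de(self) -> float:
        return float(noblet_perez_de(self.ash, self.cp, self.ee, self.ndf))

    def me(self) -> float:
        return float(noblet_perez_me(self.de(), self.cp))


def noblet_perez_de(ash, cp, ee, ndf):
    """DE (MJ/kg DM) from composition in g/kg DM.  Vectorized."""
    ash, cp, ee, ndf = (np.asarray(v, dtype=float) for v in (ash, cp, ee, ndf))
    if any(np.any(v < 0) for v in (ash, cp, ee, ndf)):
        raise ValueError("composition values must be non-negative")
    kcal = 4168.0 - 9.1 * ash + 1.9 * cp + 3.9 * ee - 3.6 * ndf
    return kcal * KCAL_TO_MJ


def noblet_perez_me(de, cp):
    """ME (MJ/kg DM) from DE (MJ/kg DM) and CP (g/kg DM).  Vectorized.

    For CP below ~14.3 g/kg the multiplier exceeds 1 and the formula yields
    ME > DE; that is the equation's own behaviour and only triggers a
    warning (no feed-grade cereal is that low in protein).
    """
    de = np.asarray(de, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if np.any(de < 0):
        raise ValueError("DE must be non-negative")
    factor = 1.003 - 0.00021 * cp
    if np.any(factor > 1.0):
        warnings.warn("CP < 14.3 g/kg: equation yields ME > DE", stacklevel=2)
    return de * factor


@dataclasses.dataclass
class BalanceRecord:
    """One digestion-metabolism balance observation (per-period totals)."""

    intake_kg_dm: float
    ge_diet_mj: float
    ge_feces_mj: float
    ge_urine_mj: float
    inclusion: float = DEFAULT_CORN_INCLUSION

    def __post_init__(self) -> None:
        if self.intake_kg_dm <= 0:
            raise ValueError("feed intake must be positive")
        if not 0 < self.inclusion <= 1:
            raise ValueError("inclusion fraction must be in (0, 1]")
        if min(self.ge_diet_mj, self.ge_feces_mj, self.ge_urine_mj) < 0:
            raise ValueError("gross energies must be non-negative")
        if self.ge_feces_mj + self.ge_urine_mj > self.ge_diet_mj:
            raise ValueError("excreted GE exceeds GE intake")


def direct_method(b: BalanceRecord) -> tuple[float, float]:
    """(DE, ME) of the test ingredient, MJ/kg DM, by the direct method."""
    de_diet = (b.ge_diet_mj - b.ge_feces_mj) / b.intake_kg_dm
    me_diet = (b.ge_diet_mj - b.ge_feces_mj - b.ge_urine_mj) / b.intake_kg_dm
    return de_diet / b.inclusion, me_diet / b.inclusion
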