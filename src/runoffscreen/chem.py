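"""Chemical property records for screening and simulation.

AERO (aerobic soil metabolism half-life, days) drives first-order decay in the
soil; KOC (L/kg organic carbon) drives linear-equilibrium partitioning through
KD = KOC * OC1; SOL (water solubility, mg/L) caps dissolved concentrations;
FD (field dissipation half-life, days) drives the multiple-application
equivalent-rate decay only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["ChemicalProperties", "read_chemicals"]

#: Expected columns of a chemical input CSV (trailing ones optional).
CHEMICAL_COLUMNS = (
    "name", "aero_days", "koc", "sol_mg_per_l", "fd_days",
    "rate_kg_per_ha", "interval_days", "max_applications",
)


@dataclass(frozen=True)
class ChemicalProperties:
    """Fate properties of one active ingredient."""

    aero_days: float
    koc: float
    sol_mg_per_l: float | None = None
    fd_days: float | None = None
    name: str = ""

    def __post_init__(self):
        if not self.aero_days > 0:
            raise ValueError(f"aero_days must be > 0, got {self.aero_days}")
        if not self.koc > 0:
            raise ValueError(f"koc must be > 0, got {self.koc}")
        if self.sol_mg_per_l is not None and not self.sol_mg_per_l > 0:
            raise ValueError("sol_mg_per_l must be > 0 when given")
        if self.fd_days is not None and not self.fd_days > 0:
            raise ValueError("fd_days must be > 0 when given")

    @property
    def decay_rate_per_day(self) -> float:
        """First-order soil decay constant ln2 / AERO (1/day)."""
        return math.log(2.0) / self.aero_days

    def kd(self, oc1: float) -> float:
        """Soil-water distribution coefficient KD = KOC * OC1 (L/kg)."""
        return self.koc * oc1


def read_chemicals(path) -> pd.DataFrame:
    """Read a chemical input CSV.

    Requires ``name``, ``aero_days`` and ``koc``; the solubility, field
    dissipation half-life and label use-pattern columns are optional and
    filled with NA when absent.
    """
    df = pd.read_csv(path, comment="#")
    required = ("name", "aero_days", "koc")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"chemical file missing required columns: {missing}")
    for col in CHEMICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[list(CHEMICAL_COLUMNS)]
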