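"""Screening application of use-exposure relationships.

Turns a parameterized relationship (fitted or shipped) plus a chemical's
AERO, KOC and label use pattern into an exposure-index estimate:

    EI = exp(b1 + b2 lnAERO + b3 lnKOC_eff) * RATE / BASE

For multiple applications the rate entering that expression is the maximum
equivalent application rate — the decayed cumulative rate over the season,
with first-order decay at the field dissipation half-life (FD) and all
transport losses ignored, which keeps the estimate conservative. Dissolved
estimates are flagged (not truncated) when they exceed the water solubility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import ChemicalProperties
from .model import UseExposureRelationship, load_relationships
from .scenario import Scenario

__all__ = [
    "LabelUsePattern",
    "ei_from_relationship",
    "decay_fraction",
    "rate_eq_series",
    "max_rate_eq",
    "sol_check",
    "kd_star",
    "screen_batch",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class LabelUsePattern:
    """A label use pattern: single rate, application interval, max count."""

    single_rate_kg_per_ha: float
    interval_days: float = 0.0
    max_applications: int = 1
    fd_days: float = math.inf

    def __post_init__(self):
        if not self.single_rate_kg_per_ha > 0:
            raise ValueError("single_rate_kg_per_ha must be > 0")
        if self.max_applications < 1:
            raise ValueError("max_applications must be >= 1")
        if self.max_applications > 1 and self.interval_days < 1:
            raise ValueError("interval_days must be >= 1 when "
                             "max_applications > 1")
        if not self.fd_days > 0:
            raise ValueError("fd_days must be > 0")


def decay_fraction(delta_days, fd_days: float):
    """Fraction remaining after delta_days of first-order decay: D(0) = 1."""
    if not fd_days > 0:
        raise ValueError("fd_days must be > 0")
    dt = np.asarray(delta_days, dtype=float)
    if math.isinf(fd_days):
        out = np.ones_like(dt)
    else:
        out = np.exp(-LN2 * dt / fd_days)
    return out if out.ndim else float(out)


def _as_day(x) -> float:
    """Dates or numeric day offsets -> float days on a common axis."""
    if isinstance(x, (int, float, np.integer, np.floating)):
        return float(x)
    ts = pd.Timestamp(x)
    return float(ts.toordinal()) + (ts - ts.normalize()).total_seconds() / 86400.0


def rate_eq_series(schedule, fd_days: float, t) -> float:
    """Equivalent application rate at time t from dated applications.

    RATE_eq(t) = sum over applications at tau <= t of RATE(tau) * D(t - tau),
    a decay-only convolution: degradation is the only loss accounted for
    (runoff, erosion and leaching losses are ignored, which makes the
    remaining-mass estimate conservative). Times before the first
    application return 0.

    ``schedule`` is a sequence of (time, rate) with times either dates or
    numeric day offsets; ``t`` uses the same convention.
    """
    t_day = _as_day(t)
    total = 0.0
    for when, rate in schedule:
        dt = t_day - _as_day(when)
        if dt >= 0:
            total += rate * decay_fraction(dt, fd_days)
    return total


def max_rate_eq(pattern: LabelUsePattern) -> float:
    """Maximum equivalent rate of a label pattern (closed form).

    With M applications of RATE every INTERVAL days the maximum is attained
    on the day of the last application:

        max RATE_eq = RATE * sum_{m=0}^{M-1} D(m * INTERVAL)

    Satisfies RATE <= max_rate_eq <= M * RATE.
    """
    m = np.arange(pattern.max_applications)
    return float(pattern.single_rate_kg_per_ha
                 * np.sum(decay_fraction(m * pattern.interval_days,
                                         pattern.fd_days)))


def ei_from_relationship(uer: UseExposureRelationship, aero_days, koc,
                         rate_kg_per_ha):
    """Exposure index from a relationship at an actual application rate.

    Linear in rate; continuous in KOC across the breakpoint.
    """
    if np.any(np.asarray(aero_days) <= 0) or np.any(np.asarray(koc) <= 0) \
            or np.any(np.asarray(rate_kg_per_ha) <= 0):
        raise ValueError("aero_days, koc and rate must be > 0")
    return np.exp(uer.ln_ei_base(aero_days, koc)) \
        * rate_kg_per_ha / uer.base_rate_kg_per_ha


def sol_check(ei_dissolved_ug_per_l: float,
              sol_mg_per_l: float | None) -> bool | None:
    """Whether a dissolved EI exceeds the water solubility (strict).

    SOL is mg/L, EI is ug/L; returns None when no solubility is given.
    The EI itself is reported unmodified — the flag marks estimates beyond
    the physically attainable dissolved concentration.
    """
    if sol_mg_per_l is None:
        return None
    if not sol_mg_per_l > 0:
        raise ValueError("sol_mg_per_l must be > 0 when given")
    return ei_dissolved_ug_per_l > 1000.0 * sol_mg_per_l


def kd_star(uer: UseExposureRelationship, scenario: Scenario) -> float:
    """Limiting distribution coefficient KD* = exp(lnKOC*) * OC1 (L/kg).

    Below KD* the dissolved exposure index is insensitive to KOC; across
    scenarios KD* is approximately invariant, making it the natural
    mobility threshold diagnostic of a relationship table.
    """
    return float(np.exp(uer.ln_koc_star) * scenario.oc1)


def _rate_for(row: pd.Series) -> tuple[float, int]:
    """Screening rate for one chemical row: max equivalent rate when the
    label allows multiple applications (requires FD), else the single rate."""
    rate = float(row["rate_kg_per_ha"])
    m = row.get("max_applications")
    m = 1 if pd.isna(m) else int(m)
    if m > 1:
        fd = row.get("fd_days")
        if pd.isna(fd):
            raise ValueError(
                f"chemical {row.get('name', '?')!r}: fd_days is required "
                "when max_applications > 1")
        pattern = LabelUsePattern(
            single_rate_kg_per_ha=rate,
            interval_days=float(row["interval_days"]),
            max_applications=m,
            fd_days=float(fd))
        return max_rate_eq(pattern), m
    return rate, 1


def screen_batch(chemicals: pd.DataFrame,
                 scenarios: dict[str, Scenario],
                 phases=("dissolved", "adsorbed"),
                 relationships=None) -> pd.DataFrame:
    """Screen a table of chemicals against a set of scenarios.

    Parameters
    ----------
    chemicals : DataFrame
        Columns as in :data:`runoffscreen.chem.CHEMICAL_COLUMNS`.
    scenarios : dict name -> Scenario
        Used for the KD* diagnostic; every scenario must have a relationship.
    relationships : dict (scenario, phase) -> UseExposureRelationship, optional
        Defaults to the shipped published tables.

    Returns
    -------
    DataFrame
        One row per (chemical x scenario x phase): the exposure index, the
        rate actually used (equivalent rate for multi-application labels),
        the solubility flag (dissolved only) and provenance.
    """
    if relationships is None:
        relationships = load_relationships()
    columns = ["chemical", "scenario", "phase", "ei", "units",
               "rate_used_kg_per_ha", "n_applications", "kd_star",
               "sol_exceeded", "provenance"]
    records = []
    for _, row in chemicals.iterrows():
        aero = float(row["aero_days"])
        koc = float(row["koc"])
        sol = None if pd.isna(row.get("sol_mg_per_l")) \
            else float(row["sol_mg_per_l"])
        rate, n_apps = _rate_for(row)
        for name, scen in scenarios.items():
            for phase in phases:
                key = (name, phase)
                if key not in relationships:
                    raise KeyError(
                        f"no relationship for {key}; available: "
                        f"{sorted(relationships)}")
                uer = relationships[key]
                ei = float(ei_from_relationship(uer, aero, koc, rate))
                records.append({
                    "chemical": row["name"],
                    "scenario": name,
                    "phase": phase,
                    "ei": ei,
                    "units": uer.units,
                    "rate_used_kg_per_ha": rate,
                    "n_applications": n_apps,
                    "kd_star": kd_star(uer, scen),
                    "sol_exceeded": (sol_check(ei, sol)
                                     if phase == "dissolved" else None),
                    "provenance": uer.provenance,
                })
    return pd.DataFrame(records, columns=columns)
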