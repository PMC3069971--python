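"""Surrogate field-scale pesticide runoff model.

A daily, single-mixing-layer root-zone model standing in for a full
multi-layer model such as PRZM. Each day it:

1. applies scheduled pesticide into the surface mixing layer (application
   efficiency retained on the field; the drift fraction leaves the system);
2. decays the stored mass first-order with the AERO half-life (dissolved and
   sorbed phases share the decay constant);
3. generates runoff from rain plus irrigation with the SCS curve-number
   method (AMC II throughout), using the curve number of the current cover
   phase (fallow / cropping / residue);
4. erodes sediment with a MUSLE-type event relation driven by runoff volume
   and a fixed-duration peak-flow proxy;
5. partitions the layer mass between pore water and sorbed phase by linear
   equilibrium (KD = KOC * OC1) and exports dissolved mass with runoff and
   percolation and sorbed mass with eroded sediment.

Edge-of-field concentrations are the pore-water concentration in runoff
(optionally capped at the water solubility) and the OC-normalized sorbed
concentration on eroded sediment. The model is deliberately linear in the
applied rate whenever the solubility cap is inactive, which is the structural
assumption behind use-exposure regression.

Unit conventions: mass in kg/ha, depths in mm, mixing depth in cm, bulk
density g/cm3, concentrations mg/L (water) and mg/kg (soil) internally;
reported series are ug/L and ng/g-OC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ChemicalProperties
from .scenario import Scenario
from .weather import WeatherSeries

__all__ = [
    "ApplicationEvent",
    "DailyFluxSeries",
    "Hydrology",
    "curve_number_runoff",
    "peak_flow_proxy",
    "musle_sediment_yield",
    "partition_concentrations",
    "compute_hydrology",
    "simulate",
]

logger = logging.getLogger(__name__)

#: MUSLE event coefficient and exponent: SY = a * (V*qp)**b * K*LS*C*P.
MUSLE_A = 1.586
MUSLE_B = 0.56
#: Effective storm duration (h) converting daily runoff volume to peak flow.
HYDROGRAPH_HOURS = 2.0


class ScheduleError(ValueError):
    """Raised when an application date falls outside the weather record."""


@dataclass(frozen=True)
class ApplicationEvent:
    """One dated pesticide application.

    The efficiency fraction reaches the field (soil-incorporated into the
    mixing layer); the drift fraction leaves the system entirely.
    """

    date: pd.Timestamp
    rate_kg_per_ha: float
    efficiency: float = 0.99
    drift_fraction: float = 0.01
    incorporation_depth_cm: float = 4.0

    def __post_init__(self):
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        if not self.rate_kg_per_ha > 0:
            raise ValueError("rate_kg_per_ha must be > 0")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")
        if not 0.0 <= self.drift_fraction <= 1.0:
            raise ValueError("drift_fraction must be in [0, 1]")


@dataclass
class DailyFluxSeries:
    """Daily simulated fluxes and edge-of-field concentrations.

    Attributes
    ----------
    dissolved_conc_ug_per_l : ndarray
        Concentration in runoff water on runoff days, 0 otherwise (ug/L).
    adsorbed_conc_ng_per_g_oc : ndarray
        OC-normalized concentration on eroded sediment on erosion days,
        0 otherwise (ng/g organic carbon).
    soil_mass_kg_per_ha : ndarray
        Pesticide mass stored in the mixing layer at the end of each day.
    mass_balance : dict
        Ledger of applied / decayed / runoff / eroded / leached / stored
        mass (kg/ha); closes to machine precision.
    """

    dates: pd.DatetimeIndex
    runoff_mm: np.ndarray
    sediment_yield_t_per_ha: np.ndarray
    dissolved_conc_ug_per_l: np.ndarray
    adsorbed_conc_ng_per_g_oc: np.ndarray
    soil_mass_kg_per_ha: np.ndarray
    mass_balance: dict
    sol_cap_days: int = 0

    def mass_balance_error(self) -> float:
        """Relative closure error |applied - (losses + stored)| / applied."""
        mb = self.mass_balance
        applied = mb["applied"]
        if applied == 0:
            return abs(mb["decayed"] + mb["runoff"] + mb["eroded"]
                       + mb["leached"] + mb["stored"])
        out = (mb["decayed"] + mb["runoff"] + mb["eroded"]
               + mb["leached"] + mb["stored"])
        return abs(applied - out) / applied

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "runoff_mm": self.runoff_mm,
                "sediment_yield_t_per_ha": self.sediment_yield_t_per_ha,
                "dissolved_conc_ug_per_l": self.dissolved_conc_ug_per_l,
                "adsorbed_conc_ng_per_g_oc": self.adsorbed_conc_ng_per_g_oc,
                "soil_mass_kg_per_ha": self.soil_mass_kg_per_ha,
            },
            index=self.dates,
        )


def curve_number_runoff(water_input_mm, cn):
    """SCS curve-number daily runoff depth (mm).

    S = 25400/CN - 254 (mm); Ia = 0.2 S; Q = (P - Ia)^2 / (P - Ia + S) for
    P > Ia, else 0. CN is the AMC-II value for the current cover.
    Accepts scalars or arrays; 0 <= Q <= P always.
    """
    p = np.asarray(water_input_mm, dtype=float)
    cn_arr = np.asarray(cn, dtype=float)
    if np.any(p < 0):
        raise ValueError("water input must be >= 0")
    if np.any((cn_arr <= 30.0) | (cn_arr > 100.0)):
        raise ValueError(f"curve number outside (30, 100]: {cn}")
    s = 25400.0 / cn_arr - 254.0
    ia = 0.2 * s
    excess = p - ia
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(excess > 0, excess**2 / (excess + s), 0.0)
    # CN = 100 -> S = 0, impervious limit Q = P
    q = np.where(np.broadcast_to(s, q.shape) == 0.0,
                 np.where(p > 0, p, 0.0), q)
    return q if q.ndim else float(q)


def peak_flow_proxy(runoff_mm, area_ha: float = 1.0,
                    duration_hours: float = HYDROGRAPH_HOURS):
    """Event peak discharge (m3/s) from daily runoff depth.

    Daily weather carries no within-day structure, so the event hydrograph is
    idealized as uniform over a fixed effective duration.
    """
    volume_m3 = 10.0 * np.asarray(runoff_mm, dtype=float) * area_ha
    return volume_m3 / (duration_hours * 3600.0)


def musle_sediment_yield(runoff_mm, peak_flow_m3_per_s, scenario: Scenario,
                         a: float = MUSLE_A, b: float = MUSLE_B):
    """MUSLE-type event sediment yield (t/ha).

    SY = a * (V * qp)^b * K * LS * C * P with V the runoff volume (m3/ha)
    and qp the peak discharge; zero runoff yields zero sediment, and the
    yield is linear in each USLE factor.
    """
    q = np.asarray(runoff_mm, dtype=float)
    qp = np.asarray(peak_flow_m3_per_s, dtype=float)
    if np.any(q < 0):
        raise ValueError("runoff must be >= 0")
    volume_m3 = 10.0 * q
    energy = volume_m3 * qp
    sy = a * energy**b * (scenario.usle_k * scenario.usle_ls
                          * scenario.usle_c * scenario.usle_p)
    sy = sy / max(scenario.field_area_ha, 1e-12)
    return sy if sy.ndim else float(sy)


def partition_concentrations(soil_mass_kg_per_ha, scenario: Scenario,
                             chem: ChemicalProperties):
    """Linear-equilibrium phase split of the mixing-layer pesticide mass.

    Returns ``(porewater_mg_per_l, sorbed_mg_per_kg)`` satisfying the mass
    conservation identity  M = 0.1 * d * (theta * Cw + rho_b * Cs)  with
    d in cm, M in kg/ha, and Cs = KD * Cw, KD = KOC * OC1.
    """
    m = float(soil_mass_kg_per_ha)
    if m < 0:
        raise ValueError("soil mass must be >= 0")
    d = scenario.mixing_depth_cm
    if d <= 0:
        raise ValueError("mixing depth must be > 0")
    kd = chem.kd(scenario.oc1)
    denom = d * (scenario.water_content + scenario.bulk_density * kd)
    cw = 10.0 * m / denom
    cs = kd * cw
    return cw, cs


@dataclass
class Hydrology:
    """Chemistry-independent daily water and sediment fluxes for one weather
    record on one scenario (computed once, reusable across chemicals)."""

    runoff_mm: np.ndarray
    sediment_yield_t_per_ha: np.ndarray
    percolation_mm: np.ndarray


def compute_hydrology(scenario: Scenario, weather: WeatherSeries) -> Hydrology:
    """Run the water/sediment part of the model for a scenario and weather.

    Runoff uses the cover-phase curve number of each date; infiltration in
    excess of the day's reference ET percolates below the mixing layer
    (single-bucket balance, profile held at field capacity).
    """
    months_days = weather.dates.strftime("%m-%d")
    # phase lookup via a one-year calendar cache
    cn = np.empty(len(weather))
    unique_md = pd.unique(months_days)
    cn_by_md = {md: scenario.curve_number(f"2001-{md}" if md != "02-29"
                                          else "2004-02-29")
                for md in unique_md}
    cn[:] = [cn_by_md[md] for md in months_days]

    p = weather.water_input_mm
    runoff = curve_number_runoff(p, cn)
    qp = peak_flow_proxy(runoff, area_ha=scenario.field_area_ha)
    sy = musle_sediment_yield(runoff, qp, scenario)
    infiltration = p - runoff
    percolation = np.clip(infiltration - weather.et_mm, 0.0, None)
    return Hydrology(runoff_mm=runoff, sediment_yield_t_per_ha=sy,
                     percolation_mm=percolation)


def simulate(scenario: Scenario, chem: ChemicalProperties,
             schedule, weather: WeatherSeries, *,
             extraction_factor: float = 1.0,
             hydrology: Hydrology | None = None) -> DailyFluxSeries:
    """Simulate daily pesticide fate and edge-of-field concentrations.

    Parameters
    ----------
    schedule : sequence of ApplicationEvent
        Application dates must fall inside the weather record.
    extraction_factor : float
        Fraction of the mixing-layer pore-water concentration carried by
        runoff water (default 1.0, the most conservative choice).
    hydrology : Hydrology, optional
        Pre-computed water/sediment fluxes (they do not depend on the
        chemical); computed on the fly when omitted.

    Notes
    -----
    Daily transport losses are limited to the mass present: on days where the
    nominal dissolved + eroded + leached export would exceed the stored mass,
    all three are scaled down proportionally. Reported concentrations are the
    pre-export equilibrium values and are unaffected by that cap, so they
    stay exactly linear in the application rate while the solubility cap is
    inactive.
    """
    if hydrology is None:
        hydrology = compute_hydrology(scenario, weather)
    n = len(weather)
    start = weather.dates[0]

    applications = [0.0] * n
    total_applied = 0.0
    total_drift = 0.0
    for ev in schedule:
        idx = (ev.date - start).days
        if idx < 0 or idx >= n:
            raise ScheduleError(
                f"application on {ev.date.date()} outside weather record "
                f"({weather.dates[0].date()}..{weather.dates[-1].date()})")
        applications[idx] += ev.rate_kg_per_ha * ev.efficiency
        total_applied += ev.rate_kg_per_ha * ev.efficiency
        total_drift += ev.rate_kg_per_ha * ev.drift_fraction

    kd = chem.kd(scenario.oc1)
    denom = scenario.mixing_depth_cm * (scenario.water_content
                                        + scenario.bulk_density * kd)
    decay_f = math.exp(-chem.decay_rate_per_day)
    sol = chem.sol_mg_per_l
    ef = extraction_factor

    runoff = hydrology.runoff_mm.tolist()
    sy = hydrology.sediment_yield_t_per_ha.tolist()
    perc = hydrology.percolation_mm.tolist()

    mass = 0.0
    tot_decayed = tot_runoff = tot_eroded = tot_leached = 0.0
    sol_cap_days = 0
    diss_out = np.zeros(n)
    ads_out = np.zeros(n)
    stored = np.zeros(n)

    for i in range(n):
        mass += applications[i]
        decayed = mass * (1.0 - decay_f)
        mass -= decayed
        tot_decayed += decayed

        if mass > 0.0:
            cw = 10.0 * mass / denom              # pore water, mg/L
            cs = kd * cw                          # sorbed, mg/kg
            cw_runoff = ef * cw
            if sol is not None and cw_runoff > sol:
                cw_runoff = sol
                sol_cap_days += 1

            q = runoff[i]
            m_run = 0.01 * q * cw_runoff if q > 0.0 else 0.0
            m_ero = 1e-3 * sy[i] * cs if sy[i] > 0.0 else 0.0
            m_lea = 0.01 * perc[i] * cw if perc[i] > 0.0 else 0.0
            loss = m_run + m_ero + m_lea
            if loss > mass:
                scale = mass / loss
                m_run *= scale
                m_ero *= scale
                m_lea *= scale
                loss = mass
            mass -= loss
            tot_runoff += m_run
            tot_eroded += m_ero
            tot_leached += m_lea

            if q > 0.0:
                diss_out[i] = 1000.0 * cw_runoff          # ug/L
            if sy[i] > 0.0:
                ads_out[i] = 1000.0 * cs / scenario.oc1   # ng/g-OC
        stored[i] = mass

    if sol_cap_days:
        logger.warning("solubility cap limited the runoff concentration on "
                       "%d day(s)", sol_cap_days)

    mb = {
        "applied": total_applied,
        "drift": total_drift,
        "decayed": tot_decayed,
        "runoff": tot_runoff,
        "eroded": tot_eroded,
        "leached": tot_leached,
        "stored": mass,
    }
    return DailyFluxSeries(
        dates=weather.dates,
        runoff_mm=hydrology.runoff_mm,
        sediment_yield_t_per_ha=hydrology.sediment_yield_t_per_ha,
        dissolved_conc_ug_per_l=diss_out,
        adsorbed_conc_ng_per_g_oc=ads_out,
        soil_mass_kg_per_ha=stored,
        mass_balance=mb,
        sol_cap_days=sol_cap_days,
    )
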