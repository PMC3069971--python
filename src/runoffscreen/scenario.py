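"""Crop-scenario definitions: landscape, soil, cover calendar and management.

A :class:`Scenario` bundles everything the field simulator needs that is not
weather or chemistry: SCS curve numbers for the three cover states, USLE
erosion factors, the surface-soil organic carbon fraction (OC1), the mixing
layer geometry, and the application window. Eight scenarios transcribed from
the USEPA Tier-2 crop scenario set for California (plus a Florida tomato
reference) ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

from .weather import WeatherConfig

__all__ = ["Scenario", "load_scenarios", "get_scenario", "default_weather_config"]

#: Cover phases distinguished by the curve-number calendar.
COVER_PHASES = ("fallow", "cropping", "residue")

#: Default cover calendar for the Mediterranean scenarios: residue (post-harvest
#: or dormant cover) through the rainy winter, fallow seedbed in early spring,
#: crop cover through the irrigation season.
DEFAULT_CROP_CALENDAR = (
    ("11-01", "02-29", "residue"),
    ("03-01", "04-30", "fallow"),
    ("05-01", "10-31", "cropping"),
)

#: Default furrow/gravity irrigation calendar: weekly sets of 60 mm gross
#: depth, early May through early September (~1100 mm gross seasonal water,
#: typical of furrow-irrigated row crops in the San Joaquin Valley).
DEFAULT_IRRIGATION = tuple(
    (f"{month:02d}-{day:02d}", 60.0)
    for month, days in ((5, (7, 14, 21, 28)), (6, (4, 11, 18, 25)),
                        (7, (2, 9, 16, 23, 30)), (8, (6, 13, 20, 27)),
                        (9, (3,)))
    for day in days
)


@dataclass(frozen=True)
class Scenario:
    """Landscape / soil / management configuration of one crop scenario."""

    name: str
    cn_fallow: float
    cn_cropping: float
    cn_residue: float
    usle_k: float
    usle_ls: float
    usle_p: float
    usle_c: float
    oc1: float
    bulk_density: float = 1.35          # g/cm3, surface soil
    water_content: float = 0.30         # volumetric, held at field capacity
    mixing_depth_cm: float = 4.0        # surface mixing / incorporation layer
    field_area_ha: float = 1.0
    crop_calendar: tuple = DEFAULT_CROP_CALENDAR
    application_window: tuple = ("06-01", "06-30")
    irrigation_schedule: tuple = ()
    use_pattern: str = ""
    soil: str = ""
    hydro_group: str = ""
    weather_station: str = ""

    def __post_init__(self):
        if not 0.0 < self.oc1 <= 1.0:
            raise ValueError(f"oc1 must be in (0, 1], got {self.oc1}")
        for label in ("cn_fallow", "cn_cropping", "cn_residue"):
            cn = getattr(self, label)
            if not 30.0 < cn <= 100.0:
                raise ValueError(f"{label}={cn} outside (30, 100]")
        for label in ("usle_k", "usle_ls", "usle_p", "usle_c"):
            if getattr(self, label) < 0:
                raise ValueError(f"{label} must be >= 0")
        if self.mixing_depth_cm <= 0:
            raise ValueError("mixing_depth_cm must be > 0")
        if self.bulk_density <= 0 or not 0 < self.water_content < 1:
            raise ValueError("invalid soil physical properties")

    def cover_phase(self, date) -> str:
        """Cover phase ('fallow' | 'cropping' | 'residue') for a calendar date.

        Ranges are compared on the month-day string, with wrap-around ranges
        (start > end) spanning the year boundary.
        """
        md = pd.Timestamp(date).strftime("%m-%d")
        for start, end, phase in self.crop_calendar:
            if start <= end:
                if start <= md <= end:
                    return phase
            elif md >= start or md <= end:
                return phase
        return "fallow"

    def curve_number(self, date) -> float:
        """AMC-II curve number for a date, per the cover calendar."""
        phase = self.cover_phase(date)
        return {
            "fallow": self.cn_fallow,
            "cropping": self.cn_cropping,
            "residue": self.cn_residue,
        }[phase]

    @property
    def kd_per_koc(self) -> float:
        """KD obtained from unit KOC: the organic-carbon fraction OC1."""
        return self.oc1


def _data_path(name: str):
    return resources.files("runoffscreen.data").joinpath(name)


def load_scenarios() -> dict[str, Scenario]:
    """Load the shipped crop scenarios, keyed by name.

    USLE C is taken as the midpoint of the published seasonal range (a single
    constant factor; the surrogate simulator does not vary cover seasonally).
    """
    with resources.as_file(_data_path("scenarios.csv")) as p:
        df = pd.read_csv(p, comment="#")
    out: dict[str, Scenario] = {}
    for _, r in df.iterrows():
        out[r["name"]] = Scenario(
            name=r["name"],
            cn_fallow=float(r["cn_fallow"]),
            cn_cropping=float(r["cn_cropping"]),
            cn_residue=float(r["cn_residue"]),
            usle_k=float(r["usle_k"]),
            usle_ls=float(r["usle_ls"]),
            usle_p=float(r["usle_p"]),
            usle_c=0.5 * (float(r["usle_c_min"]) + float(r["usle_c_max"])),
            oc1=float(r["oc1"]),
            bulk_density=float(r["bulk_density"]),
            water_content=float(r["water_content"]),
            application_window=(r["app_window_start"], r["app_window_end"]),
            irrigation_schedule=DEFAULT_IRRIGATION if int(r["irrigated"]) else (),
            use_pattern=r["use_pattern"],
            soil=r["soil"],
            hydro_group=r["hydro_group"],
            weather_station=r["weather_station"],
        )
    return out


def get_scenario(name: str) -> Scenario:
    """Fetch one shipped scenario by name; error lists the available names."""
    scenarios = load_scenarios()
    try:
        return scenarios[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(scenarios)}"
        ) from None


def default_weather_config(scenario: Scenario, n_years: int = 30,
                           seed: int = 0, **overrides) -> WeatherConfig:
    """Mediterranean weather configuration matching a scenario's management.

    Winter-dominant rainfall (Nov–Mar) with a Fresno-like 285 mm/yr mean, and
    the scenario's irrigation calendar. Florida-style wetter climates can be
    expressed through ``overrides`` (e.g. higher mean rain, flat seasonality).
    """
    kwargs = dict(
        n_years=n_years,
        seed=seed,
        irrigation_schedule=scenario.irrigation_schedule,
    )
    kwargs.update(overrides)
    return WeatherConfig(**kwargs)
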