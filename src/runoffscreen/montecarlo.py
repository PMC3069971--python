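"""Stochastic driver: Latin hypercube sampling of chemical properties and
batch simulation at the base application rate.

AERO and KOC are treated as independent lognormal variables (maximum-
likelihood parameters over a 172-pesticide registration database ship with
the package). Latin hypercube sampling stratifies the central 95% of each
distribution's cumulative probability, one draw per stratum, and the two
marginals are paired by independent random permutation.

Each Monte Carlo run applies the base rate (0.1 kg/ha) once per year on a
run-specific random day inside the scenario's application window, simulates
the full weather record, and reduces the daily concentrations to dissolved
and adsorbed exposure indices. The result is the N x 3 regression matrix
(lnAERO, lnKOC, lnEI_BASE) per phase that the breakpoint fit consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .chem import ChemicalProperties
from .exposure import ExposureIndexSpec, exposure_index
from .scenario import Scenario
from .simulator import ApplicationEvent, compute_hydrology, simulate
from .weather import WeatherSeries

__all__ = [
    "PropertyDistribution",
    "MonteCarloDesign",
    "RegressionMatrix",
    "load_property_distributions",
    "lhs_sample",
    "pair_samples",
    "run_batch",
]

logger = logging.getLogger(__name__)

PHASES = ("dissolved", "adsorbed")


@dataclass(frozen=True)
class PropertyDistribution:
    """Lognormal distribution of a chemical property, sampled truncated.

    ``mu`` and ``sigma`` are the mean and standard deviation of the natural
    logarithm; sampling is restricted to the central ``truncation_mass`` of
    cumulative probability (default 95%, i.e. the 2.5th–97.5th percentiles).
    """

    mu: float
    sigma: float
    truncation_mass: float = 0.95
    name: str = ""

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.truncation_mass <= 1.0:
            raise ValueError("truncation_mass must be in (0, 1]")

    @property
    def mean(self) -> float:
        """Arithmetic mean of the (untruncated) lognormal: exp(mu + sigma^2/2)."""
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    @property
    def sd(self) -> float:
        """Arithmetic standard deviation of the (untruncated) lognormal."""
        return self.mean * float(np.sqrt(np.expm1(self.sigma**2)))


def load_property_distributions() -> dict[str, PropertyDistribution]:
    """The shipped AERO / KOC lognormal parameters, keyed by variable name."""
    path = resources.files("runoffscreen.data").joinpath("distributions.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    return {
        r["variable"]: PropertyDistribution(
            mu=float(r["mu"]), sigma=float(r["sigma"]), name=r["variable"])
        for _, r in df.iterrows()
    }


def lhs_sample(dist: PropertyDistribution, n: int, rng) -> np.ndarray:
    """Latin hypercube sample of n values from a truncated lognormal.

    The cumulative-probability interval covering the central
    ``truncation_mass`` is divided into n equal strata; one uniform draw is
    taken inside each stratum, the stratum order is randomly permuted, and
    the draws are mapped through the lognormal quantile function.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    lower = (1.0 - dist.truncation_mass) / 2.0
    width = dist.truncation_mass / n
    u = lower + width * (np.arange(n) + rng.uniform(size=n))
    u = rng.permutation(u)
    return np.exp(stats.norm.ppf(u, loc=dist.mu, scale=dist.sigma))


def pair_samples(aero_values, koc_values, rng) -> np.ndarray:
    """Pair two marginal samples by independent random permutation.

    Returns an (n, 2) array of (AERO, KOC) pairs. Random pairing destroys
    any ordering induced by the stratified sampling, so the joint sample
    carries no rank correlation beyond sampling noise — the two properties
    are modeled as independent. Pass ``rng=None`` for the identity pairing.
    """
    aero = np.asarray(aero_values, dtype=float)
    koc = np.asarray(koc_values, dtype=float)
    if aero.shape != koc.shape:
        raise ValueError(
            f"length mismatch: {aero.shape} vs {koc.shape}")
    if rng is None:
        perm = np.arange(len(koc))
    else:
        perm = np.random.default_rng(rng).permutation(len(koc))
    return np.column_stack([aero, koc[perm]])


@dataclass(frozen=True)
class MonteCarloDesign:
    """Design of a stochastic derivation experiment."""

    n_runs: int
    base_rate_kg_per_ha: float = 0.1
    seed: int = 0
    application_window: tuple | None = None   # ("MM-DD", "MM-DD"); scenario's if None
    return_period_years: int = 3
    aero_dist: PropertyDistribution | None = None
    koc_dist: PropertyDistribution | None = None

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not self.base_rate_kg_per_ha > 0:
            raise ValueError("base_rate_kg_per_ha must be > 0")

    def distributions(self) -> tuple[PropertyDistribution, PropertyDistribution]:
        if self.aero_dist is not None and self.koc_dist is not None:
            return self.aero_dist, self.koc_dist
        shipped = load_property_distributions()
        return (self.aero_dist or shipped["AERO"],
                self.koc_dist or shipped["KOC"])


@dataclass
class RegressionMatrix:
    """The (lnAERO, lnKOC, lnEI_BASE) matrix for one phase, plus metadata."""

    data: pd.DataFrame                     # columns ln_aero, ln_koc, ln_ei_base
    phase: str
    scenario_name: str = ""
    n_requested: int = 0
    n_dropped: int = 0
    base_rate_kg_per_ha: float = 0.1
    seed: int | None = None

    COLUMNS = ("ln_aero", "ln_koc", "ln_ei_base")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"regression matrix missing columns: {missing}")
        values = self.data[list(self.COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("regression matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, phase: str, **meta) -> "RegressionMatrix":
        return cls(data=pd.read_csv(path, comment="#"), phase=phase, **meta)


def _window_days(window: tuple, year: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(f"{year}-{window[0]}")
    end = pd.Timestamp(f"{year}-{window[1]}")
    if end < start:  # window wraps the year boundary; anchor on the start year
        end = pd.Timestamp(f"{year + 1}-{window[1]}")
    return pd.date_range(start, end, freq="D")


def annual_schedule(window: tuple, offset_days: int, years,
                    rate_kg_per_ha: float) -> list[ApplicationEvent]:
    """One application per year at a fixed day-offset into the window."""
    events = []
    for year in years:
        days = _window_days(window, year)
        events.append(ApplicationEvent(
            date=days[min(offset_days, len(days) - 1)],
            rate_kg_per_ha=rate_kg_per_ha))
    return events


def run_batch(design: MonteCarloDesign, scenario: Scenario,
              weather: WeatherSeries) -> dict[str, RegressionMatrix]:
    """Run the full stochastic derivation and return one matrix per phase.

    For each of the ``design.n_runs`` LHS-sampled (AERO, KOC) pairs: draw an
    application day uniformly in the window (one draw per run, reused every
    simulated year), apply the base rate annually, simulate, and compute the
    4-day dissolved and 10-day adsorbed exposure indices at the design's
    return period. Runs whose EI is zero for a phase (no runoff or erosion
    contact) are excluded from that phase's matrix with a logged count,
    since their logarithm is undefined.

    Deterministic for a fixed ``design.seed``.
    """
    n_years = len(np.unique(weather.dates.year))
    if n_years < 3:
        raise ValueError("weather record must span at least 3 years")
    rng = np.random.default_rng(design.seed)
    aero_dist, koc_dist = design.distributions()
    aero = lhs_sample(aero_dist, design.n_runs, rng)
    koc_marginal = lhs_sample(koc_dist, design.n_runs, rng)
    pairs = pair_samples(aero, koc_marginal, rng)

    window = design.application_window or scenario.application_window
    years = sorted(np.unique(weather.dates.year))
    window_len = len(_window_days(window, years[0]))
    offsets = rng.integers(0, window_len, size=design.n_runs)

    hydrology = compute_hydrology(scenario, weather)
    specs = {ph: ExposureIndexSpec.for_phase(
        ph, return_period_years=design.return_period_years) for ph in PHASES}

    rows = {ph: [] for ph in PHASES}
    dropped = dict.fromkeys(PHASES, 0)
    for i in range(design.n_runs):
        chem = ChemicalProperties(aero_days=pairs[i, 0], koc=pairs[i, 1])
        schedule = annual_schedule(window, int(offsets[i]), years,
                                   design.base_rate_kg_per_ha)
        flux = simulate(scenario, chem, schedule, weather,
                        hydrology=hydrology)
        for ph in PHASES:
            ei = exposure_index(flux, specs[ph])
            if ei > 0.0 and np.isfinite(ei):
                rows[ph].append((np.log(pairs[i, 0]), np.log(pairs[i, 1]),
                                 np.log(ei)))
            else:
                dropped[ph] += 1

    out = {}
    for ph in PHASES:
        if dropped[ph]:
            logger.warning("%s phase: %d of %d runs had zero exposure index "
                           "and were dropped", ph, dropped[ph], design.n_runs)
        out[ph] = RegressionMatrix(
            data=pd.DataFrame(rows[ph], columns=list(RegressionMatrix.COLUMNS)),
            phase=ph,
            scenario_name=scenario.name,
            n_requested=design.n_runs,
            n_dropped=dropped[ph],
            base_rate_kg_per_ha=design.base_rate_kg_per_ha,
            seed=design.seed,
        )
    return out
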