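"""Piecewise log-log use-exposure regression.

The use-exposure relationship predicts the log exposure index at the base
application rate from two chemical properties:

    ln EI_BASE = b1 + b2 * ln AERO + b3 * ln KOC_eff

where ln KOC_eff is ln KOC clamped at a breakpoint ln KOC*:
clamped from below for the dissolved phase (EI is insensitive to KOC for
weakly sorbed chemicals, and substituting KOC* keeps the estimate
conservative) and from above for the adsorbed phase (EI saturates once
essentially all residue is particle-bound).

:class:`UseExposureModel` fits b1–b3 by ordinary least squares for every
candidate breakpoint on a grid and selects the breakpoint maximizing R²,
with ties broken toward the smaller lnKOC* (the more conservative dissolved
estimate). The fit is evaluated on the full matrix with the clamped
predictor, which makes the R² objective well-defined across candidates.
:class:`UseExposureResults` carries the estimates, their standard errors and
diagnostics, predicts exposure indices at arbitrary rates, and renders a
summary table. Published coefficients for the eight shipped scenarios are
available through :func:`load_relationships`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "clamp_ln_koc",
    "r_squared",
    "UseExposureRelationship",
    "UseExposureModel",
    "UseExposureResults",
    "load_relationships",
    "shipped_relationship",
]

#: Default breakpoint search grid: half-unit resolution over the plausible
#: lnKOC range.
DEFAULT_GRID = np.arange(0.0, 12.0 + 1e-9, 0.5)

PHASE_UNITS = {"dissolved": "ug/L", "adsorbed": "ng/g-OC"}


class FittingError(RuntimeError):
    """Raised when no breakpoint candidate yields a well-posed regression."""


def clamp_ln_koc(ln_koc, ln_koc_star: float, phase: str):
    """Effective lnKOC entering the regression.

    dissolved: max(lnKOC, lnKOC*) — weakly sorbed chemicals are treated as if
    at the breakpoint; adsorbed: min(lnKOC, lnKOC*) — strongly sorbed
    chemicals are treated as if at the breakpoint. Accepts scalars or arrays.
    """
    x = np.asarray(ln_koc, dtype=float)
    if phase == "dissolved":
        out = np.maximum(x, ln_koc_star)
    elif phase == "adsorbed":
        out = np.minimum(x, ln_koc_star)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return out if out.ndim else float(out)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot, floored at 0."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share length >= 2")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed series has zero variance; R2 undefined")
    ss_res = np.sum((obs - pred) ** 2)
    return max(0.0, 1.0 - ss_res / ss_tot)


@dataclass(frozen=True)
class UseExposureRelationship:
    """A parameterized use-exposure relationship for one scenario and phase."""

    scenario_name: str
    phase: str
    b1: float
    b2: float
    b3: float
    ln_koc_star: float
    r_squared: float
    base_rate_kg_per_ha: float = 0.1
    provenance: str = "fitted"

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must be in [0, 1]")
        if self.phase not in PHASE_UNITS:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def units(self) -> str:
        return PHASE_UNITS[self.phase]

    @property
    def koc_star(self) -> float:
        return float(np.exp(self.ln_koc_star))

    def ln_ei_base(self, aero_days, koc):
        """ln of the exposure index at the base application rate."""
        ln_koc_eff = clamp_ln_koc(np.log(koc), self.ln_koc_star, self.phase)
        return self.b1 + self.b2 * np.log(aero_days) + self.b3 * ln_koc_eff


def load_relationships(phase: str | None = None
                       ) -> dict[tuple[str, str], UseExposureRelationship]:
    """The shipped published coefficient tables, keyed by (scenario, phase)."""
    path = resources.files("runoffscreen.data").joinpath("coefficients.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    if phase is not None:
        df = df[df["phase"] == phase]
    return {
        (r["scenario"], r["phase"]): UseExposureRelationship(
            scenario_name=r["scenario"],
            phase=r["phase"],
            b1=float(r["b1"]),
            b2=float(r["b2"]),
            b3=float(r["b3"]),
            ln_koc_star=float(r["ln_koc_star"]),
            r_squared=float(r["r_squared"]),
            base_rate_kg_per_ha=float(r["base_rate"]),
            provenance="shipped",
        )
        for _, r in df.iterrows()
    }


def shipped_relationship(scenario: str, phase: str) -> UseExposureRelationship:
    """One shipped relationship; error lists what is available."""
    rels = load_relationships()
    try:
        return rels[(scenario, phase)]
    except KeyError:
        raise KeyError(
            f"no shipped relationship for ({scenario!r}, {phase!r}); "
            f"available: {sorted(rels)}") from None


class UseExposureModel:
    """Breakpoint log-log regression of lnEI_BASE on (lnAERO, lnKOC).

    Parameters
    ----------
    matrix : RegressionMatrix or DataFrame
        Must provide columns ``ln_aero``, ``ln_koc``, ``ln_ei_base``.
    phase : str, optional
        'dissolved' or 'adsorbed'; defaults to the matrix's phase.

    Examples
    --------
    >>> model = UseExposureModel(matrix)           # doctest: +SKIP
    >>> res = model.fit()                          # doctest: +SKIP
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(self, matrix, phase: str | None = None):
        if hasattr(matrix, "data"):  # RegressionMatrix
            self.matrix = matrix
            data = matrix.data
            phase = phase or matrix.phase
            self.scenario_name = matrix.scenario_name
            self.base_rate_kg_per_ha = matrix.base_rate_kg_per_ha
        else:
            self.matrix = None
            data = matrix
            self.scenario_name = ""
            self.base_rate_kg_per_ha = 0.1
        if phase not in PHASE_UNITS:
            raise ValueError(f"phase must be one of {sorted(PHASE_UNITS)}")
        missing = [c for c in ("ln_aero", "ln_koc", "ln_ei_base")
                   if c not in data.columns]
        if missing:
            raise ValueError(f"matrix missing columns: {missing}")
        if len(data) < 10:
            raise ValueError(f"need >= 10 rows to fit, got {len(data)}")
        self.phase = phase
        self.ln_aero = data["ln_aero"].to_numpy(dtype=float)
        self.ln_koc = data["ln_koc"].to_numpy(dtype=float)
        self.ln_ei = data["ln_ei_base"].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phase: str) -> "UseExposureModel":
        return cls(df, phase=phase)

    def _ols(self, ln_koc_star: float):
        x_koc = clamp_ln_koc(self.ln_koc, ln_koc_star, self.phase)
        if np.ptp(x_koc) < 1e-12:
            return None  # every KOC clamped: design is rank-deficient
        exog = sm.add_constant(
            np.column_stack([self.ln_aero, x_koc]), has_constant="add")
        return sm.OLS(self.ln_ei, exog).fit()

    def fit(self, grid=None) -> "UseExposureResults":
        """Grid search the breakpoint; OLS at each candidate; keep max R².

        Rank-deficient candidates (all KOC on one side of the breakpoint)
        are skipped. Ties in R² go to the smaller lnKOC*.
        """
        grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("breakpoint grid is empty")
        best = None
        best_star = None
        skipped = []
        for star in np.sort(grid):
            res = self._ols(float(star))
            if res is None:
                skipped.append(float(star))
                continue
            if best is None or res.rsquared > best.rsquared + 1e-12:
                best, best_star = res, float(star)
        if best is None:
            raise FittingError(
                "no valid breakpoint candidate: design rank-deficient at "
                f"every grid point {list(grid)}")
        return UseExposureResults(self, best, best_star, skipped)


class UseExposureResults:
    """Fit results: coefficients, breakpoint, diagnostics, prediction."""

    def __init__(self, model: UseExposureModel, ols_results,
                 ln_koc_star: float, skipped_grid_points=()):
        self.model = model
        self._ols = ols_results
        self.ln_koc_star = ln_koc_star
        self.skipped_grid_points = list(skipped_grid_points)
        self.params = pd.Series(ols_results.params, index=["b1", "b2", "b3"])
        self.bse = pd.Series(ols_results.bse, index=["b1", "b2", "b3"])
        self.rsquared = float(ols_results.rsquared)
        self.nobs = int(ols_results.nobs)

    @property
    def b1(self) -> float:
        return float(self.params["b1"])

    @property
    def b2(self) -> float:
        return float(self.params["b2"])

    @property
    def b3(self) -> float:
        return float(self.params["b3"])

    @property
    def relationship(self) -> UseExposureRelationship:
        """The fitted relationship as a portable record."""
        return UseExposureRelationship(
            scenario_name=self.model.scenario_name,
            phase=self.model.phase,
            b1=self.b1, b2=self.b2, b3=self.b3,
            ln_koc_star=self.ln_koc_star,
            r_squared=min(1.0, max(0.0, self.rsquared)),
            base_rate_kg_per_ha=self.model.base_rate_kg_per_ha,
            provenance="fitted",
        )

    def predict(self, aero_days, koc, rate_kg_per_ha=None):
        """Exposure index at the given application rate (base rate if None).

        EI scales linearly with rate: EI = EI_BASE * RATE / BASE.
        """
        rel = self.relationship
        rate = rel.base_rate_kg_per_ha if rate_kg_per_ha is None \
            else rate_kg_per_ha
        return np.exp(rel.ln_ei_base(aero_days, koc)) \
            * rate / rel.base_rate_kg_per_ha

    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._ols.fittedvalues)

    def resid(self) -> np.ndarray:
        return np.asarray(self._ols.resid)

    def summary(self) -> str:
        """Plain-text summary table of the fitted relationship."""
        m = self.model
        lines = [
            "Use-exposure relationship (piecewise log-log OLS)",
            "=" * 58,
            f"scenario:        {m.scenario_name or '<unnamed>'}",
            f"phase:           {m.phase} (EI_BASE in {PHASE_UNITS[m.phase]})",
            f"n obs:           {self.nobs}",
            f"base rate:       {m.base_rate_kg_per_ha} kg/ha",
            f"ln KOC*:         {self.ln_koc_star:.4g}"
            f"   (KOC* = {np.exp(self.ln_koc_star):.4g} L/kg-OC)",
            f"R-squared:       {self.rsquared:.4f}",
            "-" * 58,
            f"{'':14s}{'coef':>12s}{'std err':>12s}",
            f"{'b1 (const)':14s}{self.b1:12.4f}{self.bse['b1']:12.4f}",
            f"{'b2 (lnAERO)':14s}{self.b2:12.4f}{self.bse['b2']:12.4f}",
            f"{'b3 (lnKOC)':14s}{self.b3:12.4f}{self.bse['b3']:12.4f}",
            "=" * 58,
        ]
        if self.skipped_grid_points:
            lines.append(
                f"skipped rank-deficient grid points: "
                f"{self.skipped_grid_points}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of lnEI_BASE vs lnKOC with the fitted piecewise line at
        the median lnAERO."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.scatter(m.ln_koc, m.ln_ei, s=8, alpha=0.4, label="simulated")
        xs = np.linspace(m.ln_koc.min(), m.ln_koc.max(), 200)
        med_aero = np.median(m.ln_aero)
        ys = (self.b1 + self.b2 * med_aero
              + self.b3 * clamp_ln_koc(xs, self.ln_koc_star, m.phase))
        ax.plot(xs, ys, color="C3",
                label=f"fit at median lnAERO (R$^2$={self.rsquared:.2f})")
        ax.axvline(self.ln_koc_star, ls="--", color="gray", lw=1,
                   label="lnKOC*")
        ax.set_xlabel("ln KOC")
        ax.set_ylabel("ln EI$_{BASE}$")
        ax.set_title(f"{m.scenario_name} — {m.phase}")
        ax.legend()
        return ax
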