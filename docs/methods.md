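# Methods

This note documents the models implemented in `runoffscreen`, the parameter
choices that matter, and what the synthetic components do and do not
represent.

## Scope and overall design

The package has two faces. The *screening* face applies a parameterized
use-exposure relationship — published coefficients for eight USEPA crop
scenarios ship with the package — to estimate edge-of-field exposure indices
from AERO, KOC and the application rate. The *derivation* face re-creates
such relationships end to end with the package's own components: a synthetic
weather generator, a surrogate daily field model, an exposure-index
reduction, a Latin-hypercube Monte Carlo driver, and a breakpoint
regression. The derivation face is a scaled-down, fully open surrogate for
the original workflow, which used 5000 PRZM runs per scenario over 30 years
of station weather; it reproduces the *structure* of the published
relationships (sign, rough magnitude, explanatory power of the fit), not
their exact coefficient values, which encode full PRZM physics and
1961–1990 meteorology.

## Exposure index

The daily edge-of-field concentration series is reduced to its w-day moving
averages (w = 4 dissolved, w = 10 adsorbed, matching acute water-quality and
10-day sediment-toxicity conventions), to one maximum per calendar year
(windows assigned to the year of their starting day), and finally to the
empirical 1-in-T-year return level with T = 3. The return-level estimator is
the k-th largest annual maximum with k = floor(n_years/T), clamped to
k ≥ 1 — the distribution-free reading of "exceeded on average once every T
years" (k = 10 for a 30-year record; k = 3 for the package's default
10-year derivations). No extreme-value distribution is fitted; with records
this short a rank statistic is both simpler and more defensible. Whether the
original derivation used a rank statistic, a percentile, or an event count
is not documented; the rank method is this package's committed choice.

## Surrogate field model

A single 4-cm surface mixing layer replaces a multi-layer soil column. This
is the layer that controls runoff-borne exposure: applications are
soil-incorporated into it (application efficiency 0.99 retained on field,
drift fraction 0.01 leaves the system, matching the incorporation settings
of the original simulations), and all foliar processes (interception,
washoff, canopy decay, volatilization, plant uptake) are set to zero for a
conservative edge-of-field estimate.

Daily sequence:

1. **Application** — scheduled mass enters the layer.
2. **Decay** — both phases decay by exp(−ln2/AERO) per day (dissolved and
   sorbed decay rates equal).
3. **Runoff** — SCS curve-number method on rain + irrigation, with the
   AMC-II curve number of the current cover phase (fallow / cropping /
   residue from the crop calendar; no antecedent-moisture adjustment).
   Residue curve numbers apply through the rainy winter months, which is
   when they matter in a Mediterranean climate.
4. **Erosion** — MUSLE event form SY = a·(V·qp)^0.56·K·LS·C·P with
   a = 1.586, V the runoff volume (m³/ha) and qp a peak-flow proxy obtained
   by spreading the daily runoff over a fixed 2-hour effective duration
   (daily weather has no within-day structure). USLE C is the midpoint of
   each scenario's published seasonal range, held constant.
5. **Partitioning and export** — linear equilibrium with KD = KOC·OC1:
   Cw = 10·M / (d·(θ + ρb·KD)) (mg/L, M in kg/ha, d in cm). Runoff water
   carries the full pore-water concentration (extraction factor 1.0,
   configurable), capped at the water solubility when one is supplied (the
   cap applies to the runoff concentration only and is logged). Eroded
   sediment carries Cs = KD·Cw, reported OC-normalized (Cs/OC1, ng/g-OC).
   Percolation — infiltration in excess of the day's reference ET — carries
   Cw out of the layer as leaching. On days where the nominal combined
   export would exceed the stored mass, all three export terms are scaled
   down proportionally; reported concentrations are the pre-export
   equilibrium values, so concentrations remain exactly linear in the
   application rate while the solubility cap is inactive. The mass ledger
   (applied = decayed + runoff + eroded + leached + stored) closes to
   machine precision by construction and is asserted to 1e-6 in tests.

Soil physical defaults (bulk density 1.35 g/cm³, volumetric water content
0.30, held at field capacity) are uniform surrogate choices, not
scenario-file transcriptions; scenario-specific values can be set on the
`Scenario`.

## Synthetic weather

Daily rainfall is a two-state occurrence process: wet-day probability 0.28
inside the November–March wet season and 0.03 outside, with exponential
wet-day depths whose mean is derived from a 285 mm/yr target — a Fresno-like
Mediterranean regime in which ~85% of rain falls in November–March.
Reference ET is a deterministic sinusoid totalling 1400 mm/yr and peaking in
mid-July. Irrigation is a fixed annual calendar taken from the scenario's
management: gravity-irrigated scenarios use weekly 60-mm sets from early May
to early September (~1100 mm gross seasonal water, typical of furrow
irrigation on row crops in the San Joaquin Valley). The weekly spacing
matters scientifically: the methodology's premise is that peak
concentrations occur shortly after application once irrigation- or
rain-induced runoff is available, so the spacing of runoff contact bounds
the decay-timing scatter of short-half-life chemicals (see Limitations).

What the generator does *not* emulate: persistence/clustering of real storm
sequences beyond the two-state daily process, interannual regimes (ENSO-type
variability), temperature effects (decay is temperature-independent here),
and demand-triggered irrigation. Passing tests therefore show the pipeline
behaves correctly under a statistically Mediterranean regime, not that it
reproduces any particular station record.

## Stochastic derivation

AERO ~ lognormal(μ = 3.44, σ = 1.99) and KOC ~ lognormal(μ = 6.51,
σ = 2.52) (natural-log parameters), sampled by Latin hypercube restricted to
the central 95% of cumulative probability — read as the 2.5th–97.5th
percentile band; one draw per equal-probability stratum, order permuted, and
the two marginals paired by an independent random permutation (the
properties are treated as independent). Each run applies the 0.1 kg/ha base
rate once per year on a run-specific day drawn uniformly from the scenario's
30-day application window (drawn once per run and reused every year). The
base rate is small enough that the solubility cap never binds, preserving
exact linearity in rate. Runs with a zero exposure index (no runoff or
erosion contact) are dropped from the regression matrix with a logged count,
since their logarithm is undefined; under the default weather they do not
occur.

Default derivation size is N = 500 runs over 10 years of weather (a few
seconds on one core), against the original 5000 runs over 30 years. N mostly
controls coefficient standard errors; the record length controls the
resolution of the return-period statistic (k = 3 vs k = 10). Both are
arguments of `derive_relationships`.

## Breakpoint regression

For each candidate lnKOC\* on a grid (default 0 to 12 in steps of 0.5,
matching the half-unit resolution of the published tables), lnEI_BASE is
regressed by OLS on (lnAERO, clamped lnKOC) over the *full* matrix, and the
candidate maximizing R² is selected, ties going to the smaller lnKOC\* (the
more conservative dissolved choice). The original description fits on the
KOC > KOC\* subset and extends by substitution; fitting the clamped
predictor on all rows makes the R² objective comparable across candidates
and is the package's documented divergence. Candidates that clamp every row
(rank-deficient design) are skipped and reported. Adsorbed-phase high-KOC
scatter is handled by the same clamped fit; no robust-regression variant is
provided.

On noiseless synthetic matrices the fit recovers generating coefficients to
1e-6 with R² = 1; under Gaussian noise at n = 5000 it recovers them within
three standard errors and the breakpoint within one grid step (both are
test-enforced).

## Screening conventions

- EI scales linearly with rate via the relationship's stored base rate.
- Multiple applications: the equivalent-rate convolution uses first-order
  decay exp(−ln2·Δt/FD) — the convention consistent with half-life inputs —
  and its closed form at the last application equals the convolution
  (test-enforced). Losses other than degradation are ignored, keeping the
  remaining-mass estimate conservative.
- Solubility: dissolved EI is compared to SOL (mg/L → µg/L ×1000) with a
  strict inequality; the EI is reported unmodified alongside the flag.
- Adsorbed EI is expressed per gram of organic carbon (sediment
  concentration divided by OC1). Published sediment LC50s are often quoted
  "at 1% OC"; numerically 1 ng/g-OC equals 0.01 ng/g at 1% OC, so users
  comparing to such endpoints should rescale explicitly. The package does
  not silently adopt the 1%-OC basis.
- KD\* = exp(lnKOC\*)·OC1 is exposed as a diagnostic; on the shipped tables
  it reproduces the published cross-scenario bands (0.5–0.7 L/kg dissolved,
  160–240 L/kg adsorbed).

## Numerical choices

- Curve number: the impervious limit CN = 100 (S = 0) returns Q = P exactly.
- The simulator caps per-day export at the stored mass by proportional
  scaling of the three export fluxes — a continuity-preserving, linear
  limiter.
- Return-period rank uses floor division with a clamp to k ≥ 1, so records
  shorter than T years degrade to the overall maximum.
- R² is floored at 0 for reporting; a zero-variance response is an error.
- Breakpoint ties break toward smaller lnKOC\*.
- Weather CSVs round-trip bit-exactly (`float_precision="round_trip"`).

## Limitations

- The surrogate is not PRZM: no multi-layer transport, no depth-weighted
  runoff extraction, no crop growth or canopy dynamics, no
  antecedent-moisture CN adjustment, no receiving-water (pond/stream)
  dilution. Exact published coefficient values are out of reach by design;
  the shipped tables are provided for application, the surrogate for
  structure and methodology.
- Short-half-life chemicals (AERO of a few days or less, a few percent of
  the sampled population) have exposure indices that are acutely sensitive
  to the gap between application and the next runoff event; this is the
  dominant residual term in surrogate-derived dissolved fits and puts the
  dissolved R² near 0.91 with a Monte Carlo spread of about ±0.02 across
  seeds at N = 500.
- The dissolved surrogate breakpoint lands near KD\* ≈ 0.16 L/kg versus the
  published 0.5–0.7 band: with extraction factor 1.0 the transition to
  KOC-insensitivity occurs where ρb·KD ≈ θ. A smaller extraction factor
  shifts it upward; the default is kept at the most conservative 1.0.
- Application windows for the shipped scenarios (dormant-season for almond,
  pre-emergent for turf, in-season otherwise) are qualitative
  reconstructions and are configurable on the `Scenario`.
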