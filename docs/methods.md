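# Methods

## Scope and modeling stance

`nearsource` estimates the *incremental* ground-level NO₂ contribution of a
single elevated point source and propagates it into health-burden and
demographic-equity statistics at the block-group level. It deliberately
replaces a regulatory dispersion system (similarity-theory boundary-layer
profiles, terrain, land-cover surface parameters, building downwash) with
the classical analytical Gaussian-plume machinery, and replaces real
census/meteorological inputs with seeded synthetic generators. The package
is therefore an *emulator of the analysis chain*, validated by physical
invariants and planted-structure recovery rather than by regression
against any particular regulatory model's output files.

## Dispersion model

Steady-state Gaussian plume from a continuous point release, hourly
meteorology, flat terrain, receptors at ground level (z = 0):

C(x, y, 0) = Q / (2π u σy σz) · exp(−y²/2σy²) · Σᵢ [vertical reflection terms]

* **Emission rate.** The annual NOx total (U.S. short tons/yr;
  1 ton = 907,184.74 g) is spread uniformly over a 365-day year, giving a
  constant Q in g/s. 4,267 tons/yr ⇒ 122.75 g/s.
* **Plume rise** (Briggs final rise). Buoyancy flux
  F = g·vs·(d/2)²·(Ts−Ta)/Ts. Unstable/neutral classes:
  Δh = 1.6 F^⅓ (3.5 x*)^⅔ / u with x* = 14 F^⅝ for F < 55, else
  34 F^⅖. Stable classes: Δh = 2.6 (F/(u·s))^⅓ with
  s = 0.02 g/Ta (E) and 0.035 g/Ta (F). Non-buoyant effluent
  (Ts ≤ Ta): momentum rise Δh = 3 d vs/u. The 10-m wind speed is used
  unadjusted for stack height — a documented simplification.
* **Dispersion coefficients.** Briggs rural (open-country) curves; the
  full table is fixed in `dispersion.py` (σy = a·x·(1+0.0001x)^−½ with
  a = 0.22/0.16/0.11/0.08/0.06/0.04 for A–F; σz per-class power laws,
  e.g. class D σz = 0.06x(1+0.0015x)^−½). Class D at x = 1 km gives
  σy = 76.28 m, σz = 37.95 m.
* **Mixing lid.** N = 4 image-source pairs about the mixing height zi;
  once σz > 1.6 zi the plume is treated as vertically well mixed,
  C = Q/(√(2π)·σy·u·zi)·exp(−y²/2σy²). N = 4 matches N = 50 to better
  than 0.1% throughout the σz ≤ 1.6 zi regime (tested).
* **Geometry.** Meteorological direction convention: wind_dir_from is the
  bearing the wind blows *from*; the transport bearing is
  wind_dir_from + 180°. Receptors are rotated into the downwind frame each
  hour; upwind receptors (x ≤ 0), including one exactly at the source,
  receive zero.
* **Calm hours.** u < 0.5 m/s: the steady-state solution diverges as
  1/u, so calm hours are emitted as missing and excluded from daily
  maxima, mirroring regulatory calm treatment. The calm fraction is
  logged in the run manifest (~1% under the default wind rose).

Mass conservation is the kernel's primary acceptance surface: the
crosswind-vertical trapezoidal integral of C·u across a transect recovers
Q to well within 0.5%, and concentration is exactly linear in Q.

## Stability classification

A Pasquill lookup replaces boundary-layer similarity theory: daytime
(hours 07–19) insolation is strong near midday under clear sky
(< 0.5 cloud fraction), moderate otherwise, slight when cloudy; classes
run A–C for light winds weakening toward neutral, u ≥ 6 m/s is always D;
night gives E (overcast, u < 3), F (clear, u < 3), grading to D. Mixing
heights default to 1,200 m (day) / 400 m (night), configurable.

## Chemistry

NOx is carried as NO₂-equivalent mass until speciation. Schemes:
FULL (no2 = nox), ARM (no2 = ratio·nox, default 0.80), and OLM —
no2 = f·nox + min((1−f)·nox, O₃) with in-stack NO₂ fraction f
(default 0.10, a common regulatory default) and a constant annual-mean
background ozone per scenario (default 36.8 ppb). OLM is the default: it
is the simplest scheme that avoids assuming complete NOx→NO₂ conversion
while capping conversion at the available oxidant. The plume-volume and
reaction-set schemes used in regulatory practice are intentionally out of
scope; the scheme flag preserves the three-way comparison shape. Unit
conversion uses 1 ppb = 1.88 μg/m³ exactly (≈ 46.0055/24.45 at 25 °C,
1 atm).

## Exposure metrics

Per block group: the series of daily 1-hr maxima over valid hours; its
annual mean (averaged within each calendar year, then across years with
equal weights) — this is ΔC for the health stage; and the plain annual
mean of valid hours, emitted alongside because summary tables in this
literature do not always state which of the two they print.
CER_avg and CER_max divide the unweighted block-group mean / maximum of
the metric by annual emissions (ppb per ton); under linear (FULL)
chemistry CER is invariant to uniform emission scaling.

## Health burden

β = ln(RR)/ΔC₀; attributable incidence per block group
= Σ_bins BIR/10⁵ · Pop · (1 − e^(−β·ΔC)), with ΔC converted to μg/m³
for the mortality CRF (mass-based increment) and kept in ppb for asthma.
Mortality uses age-specific baseline rates over all nine 10-year age bins
(0–14 first, 85+ last; no age floor by default — configurable via the
CRF's bin range); pediatric asthma uses the 0–14 bin only. Confidence
intervals re-run the calculation at the RR bounds — RR uncertainty only,
no exposure uncertainty. Rates are per 100,000 of the endpoint's
population base. The attributable fraction lies in [0, 1), counts are
additive across block groups, and under spatially constant ΔC the rate
differences across block groups are exactly proportional to their
population-weighted baseline rates (tested).

## Equity statistics

* **Distance quintiles**: block groups sorted by centroid distance (ties
  by id), split into five contiguous groups whose sizes differ by at most
  one, remainders nearest-first. All table cells are unweighted
  block-group means (including elderly%, computed per block group then
  averaged).
* **POC% stratification**: bins [0,20)…[80,100]; box statistics with
  1.5×IQR outliers.
* **Intersectional groups**: HH/HL/LH/LL by ≥/< the scenario-mean POC%
  and LI%; per-group exposure mean/min/max.
* **Spatial weights**: symmetric k-nearest-neighbor (k = 8 default),
  union-symmetrized, row-standardized. kNN is robust to the irregular
  centroid spacing an area-uniform draw produces.
* **Moran's I** with a 999-permutation two-sided pseudo p-value (seeded).
* **Spatial regression**: OLS (statsmodels) plus profile-ML SLM and SEM.
  The spatial parameter is concentrated out: for each candidate ρ (or λ)
  the coefficients are closed-form least squares, and
  ln|I − ρW| = Σ ln(1 − ρωᵢ) over the (real) eigenvalues of the
  row-standardized W; the scalar optimization is bounded in
  (1/ω_min, 1) with tolerance 1e-6. Reported coefficient standard errors
  are conditional on the estimated spatial parameter. Non-convergence is
  flagged on the result, never silent. Parameter recovery (ρ = 0.5
  recovered within ±0.1 at n = 400) is the module's acceptance surface.

## Synthetic generators: what they emulate, what they do not

The region generator emulates the *marginal* structure of a real study
region: area-uniform centroids over an annulus (inner radius 2 km by
default — the plume formula is undefined at the source and real
block-group centroids start a few km out), logistic-transformed Gaussian
latent fields for POC%/LI% with planted distance correlations (the
logistic transform attenuates a planted Pearson r by only a few percent
at the default latent SD of 1.0, comfortably within the ±0.1 recovery
tolerance at n = 500), Dirichlet-jittered national-like age structure,
and lognormal block-group noise on national-like baseline rates
(mortality 30→13,000 per 100k across bins; asthma 1,400 per 100k
children). It does **not** emulate: polygon geometries, spatially
clustered (autocorrelated) demographics beyond the distance gradient,
tract-level rate sharing, population-density gradients, or correlation
between age structure and income. Passing equity tests therefore
demonstrate that the *statistics* recover planted structure — not that
any real site exhibits it.

The meteorology generator emulates a stationary hourly wind rose
(16-sector multinomial, within-sector uniform direction, Weibull speeds
with shape 2 and scale 4.5 m/s ≈ 4 m/s mean), sinusoidal seasonal/diurnal
temperature, and iid Beta(1.5, 1.5) cloud cover. It does not emulate
autocorrelated weather, frontal passages, diurnal wind veering, or
sea-breeze regimes.

## Problem sizes and determinism

Default analysis scale is 500 block groups × 1 met year (8,760 hours),
which runs end-to-end in well under a minute; the test suite uses 20–500
block groups per check. Every random draw flows from explicit seeds;
the pipeline's single global seed fans out to stage seeds via
`SeedSequence.spawn`, and reruns are byte-identical at the CSV payload
level.

## Known limitations

Single point source per scenario (no source aggregation); no terrain,
downwash, deposition, or coastal effects; no background NO₂ (results are
facility increments only, so burden estimates are incremental, not total);
constant annual ozone; 10-m wind speed used at stack height; no secondary
pollutant formation; CI propagation ignores exposure-side uncertainty;
SLM/SEM standard errors are conditional on the spatial parameter.
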