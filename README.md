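# nearsource

Desk-scale assessment of near-source NO₂ exposure, attributable health
burden, and demographic equity around a high-emitting industrial point
source (e.g. an LNG export terminal or other large NOx stack).

Regulatory dispersion modeling around such facilities is usually the
province of heavyweight tooling driven by proprietary-format meteorology,
terrain, and census extracts. `nearsource` reimplements the analysis chain
as a tested, seeded Python pipeline over *synthetic* study regions with
planted, known spatial structure, so every downstream statistic — exposure
gradients, attributable burden, equity disparities — can be validated
against ground truth:

1. **Region synthesis** — a point source (stack geometry, exit conditions,
   annual NOx short tons/yr) surrounded by census-style block groups
   within 50 km: centroids, age-stratified populations, POC% (share not
   identifying as non-Hispanic White), LI% (share at ≤2× the federal
   poverty level), age-specific baseline mortality, pediatric asthma
   incidence. Correlations between demographics and distance from the
   source are *planted* with controllable sign and magnitude.
2. **Meteorology synthesis** — hourly wind speed/direction from a
   configurable wind rose, temperature, cloud cover, Pasquill stability
   classes A–F, and day/night mixing heights; calm hours (u < 0.5 m/s)
   are flagged and excluded from dispersion.
3. **Dispersion** — steady-state Gaussian plume with Briggs plume rise and
   Briggs rural dispersion coefficients, mixing-lid image reflections, and
   hourly receptor rotation into the downwind frame.
4. **Chemistry** — NOx→NO₂ speciation by full conversion, a fixed ambient
   ratio (ARM), or the ozone-limiting method (OLM), with ppb ↔ μg/m³ at
   1 ppb = 1.88 μg/m³ (25 °C, 1 atm).
5. **Exposure** — daily 1-hr maxima, their annual mean (the health
   metric ΔC), the plain annual mean, and the Concentration-to-Emission
   Ratio CER = C̄/E (ppb per ton/yr), both average and maximum.
6. **Health burden** — log-linear concentration-response:
   β = ln(RR)/ΔC₀ and attributable incidence
   `ΔM = BIR × Pop × (1 − e^(−β·ΔC))` summed over age bins, with
   confidence intervals propagated through the RR bounds. Defaults:
   all-cause mortality RR 1.04 (1.02–1.06) per 10 μg/m³
   (β = 0.003922 per μg/m³) and pediatric asthma RR 1.26 (1.10–1.37)
   per 10 ppb (β = 0.02311 per ppb).
7. **Equity** — distance quintile tables, POC%-stratified box statistics,
   intersectional race–income exposure groups (HH/HL/LH/LL split at the
   scenario means), and spatial regression of exposure on POC% + LI%:
   OLS with residual Moran's I, plus maximum-likelihood Spatial Lag
   (y = ρWy + Xβ + ε) and Spatial Error (u = λWu + ε) models on symmetric
   k-nearest-neighbor weights.

## Worked example

```python
import nearsource as ns

# plant high-POC / high-LI clustering near the source
gs = ns.GradientSpec(r_poc_dist=-0.6, r_li_dist=-0.5)
scenario = ns.generate_region(200, gradient_spec=gs, seed=42)
met = ns.generate_met_year(2022, seed=7)
res = ns.analyze_scenario(scenario, met, equity_seed=1)
print(res["quintile_table"].round(2))
```

prints (distance quintile Q1 = nearest 20% of block groups):

```
 quintile  distance_km  exposure_ppb  poc_pct  li_pct  elderly_pct  mortality_rate_per_100k  asthma_rate_per_100k
        1        15.68          5.44    57.22   46.70        17.02                    36.29                170.35
        2        27.08          3.20    46.95   39.67        17.47                    21.13                103.99
        3        35.12          2.49    38.49   35.22        17.54                    17.41                 81.27
        4        41.68          2.16    30.94   29.61        17.43                    15.31                 65.39
        5        46.88          1.96    28.45   27.67        17.84                    13.06                 58.61
```

Exposure (annual mean of daily 1-hr NO₂ maxima, ppb) declines with
distance while the planted demographic gradient places the highest POC%,
LI%, and attributable burden rates in the nearest quintile — the
disproportionate-impact signature the equity stage is designed to detect.
The same run reports

```
CER_avg = 7.15e-04 ppb/ton   CER_max = 2.38e-03 ppb/ton
max/min exposure ratio = 6.25
total attributable deaths/yr = 62.40
OLS POC% coef = 0.0315 (residual Moran's I = 0.574)
SLM rho = 0.965, POC% coef = 0.0058
```

i.e. each percentage point of POC% is associated with +0.03 ppb exposure
in the naive OLS fit; the strongly autocorrelated residuals (Moran's
I = 0.57) are absorbed by the spatial lag term (ρ = 0.97), shrinking the
direct demographic coefficient — the standard motivation for fitting
SLM/SEM alongside OLS.

## Command line

```sh
nearsource run-all --config config.yaml          # full pipeline
nearsource simulate-region --config config.yaml  # ... or stage by stage
nearsource simulate-met ... disperse ... expose ... health ... equity
nearsource report --run-dir run_output           # render the summary tables
```

`run-all` and the chained subcommands produce byte-identical CSV outputs;
a JSON manifest records the seed, config hash, calm-hour fraction, and
per-stage row counts. A single global seed fans out to per-stage seeds via
`numpy.random.SeedSequence.spawn`, so every stage is independently
reproducible.

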