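# Methods

This note documents the models, the processing rules, the numerical
choices and the limits of what the test suite demonstrates.

## Psychrometrics

Saturation vapour pressure uses the Magnus form with Alduchov–Eskridge
coefficients, `es(T) = 6.1094·exp(17.625·T/(243.04 + T))` hPa, chosen
because it is accurate to well under 0.1 % over 0–50 °C and inverts in
closed form for the dew point.  Vapour pressure, relative humidity and
dew point are the elementary identities around that curve; RH computed
from a pooled vapour pressure is clipped at 100 % (settlement-level
pooling can imply supersaturation for the coolest unit in an hour).

Two wet-bulb routes are deliberately independent:

* **Closed form (Stull).** A polynomial/arctangent fit in T and RH.
  Results are capped at the dry-bulb temperature (the raw fit can exceed
  it by a few hundredths of a degree near saturation) and RH > 99 % is
  treated as saturated air with TW = T.
* **Thermodynamic solver.** Bisection of
  `es(Tw) − e = γ·P·(T − Tw)` on the bracket [dew point, T], with the
  Assmann psychrometer constant γ = 6.66×10⁻⁴ K⁻¹ (configurable) and
  P = 1013 hPa everywhere, since the settlements and stations of
  interest lie 1–19 m above sea level.  Bracket tolerance 0.001 °C, cap
  100 iterations; the bracket endpoints have opposite residual signs, so
  convergence is guaranteed.

**Accuracy of the closed form.** Over the full validity rectangle
T ∈ [−20, 50] °C × RH ∈ [5, 99] % (grid steps 0.5 °C and 1 %), the mean
absolute difference from the solver is ≈ 0.43 °C, dominated by the
cold-and-dry corner (errors up to ≈ 2.2 °C below 0 °C at low RH) that
the approximation's source explicitly excludes from its accuracy claim.
Restricted to the warm, humid conditions this package targets
(T ≥ 20 °C), the MAE is ≈ 0.2 °C.  The figure is insensitive to the
oracle's formulation: an adiabatic-saturation solver in mixing-ratio
form with temperature-dependent latent heat moves the grid MAE by under
0.01 °C.

## WBGT models

**Indoor (Bernard).** The psychrometric wet bulb from the thermodynamic
solver is converted to a natural wet bulb by the empirical indoor
relation `Tnwb = Ta − (Ta − Tpwb)(0.96 + 0.069·log10 v)` for
0.3 ≤ v < 3 m/s and `Tnwb = Tpwb + 0.25` for v ≥ 3 m/s, then
`WBGT = 0.67·Tnwb + 0.33·Ta`.  The default wind speed is 1 m/s (the
log term vanishes there).  In full shade the globe equilibrates with the
air, so no globe term appears.

**Outdoor (Liljegren).** Coupled energy balances for a 50.8 mm black
globe (published constants; emissivity 0.95, albedo 0.05) and a wetted
wick (7 mm × 25.4 mm cylinder, albedo 0.4), solved by damped fixed-point
iteration (damping 0.9, convergence 0.02 °C per component, cap 50
iterations), with convective coefficients from the standard
sphere/cylinder Reynolds–Prandtl correlations and surface albedo 0.45.
When only global horizontal irradiance is supplied, the direct-beam
fraction comes from the clearness-index parameterization
`fdir = exp(3 − 1.34k − 1.65/k)` clipped to [0, 0.9], and irradiance is
clipped to the top-of-atmosphere value.  Zenith angles above ~89.5° zero
the solar input, so continuous day/night series never error.  The
solvers are vectorized: all records iterate simultaneously with a
convergence mask.

**Solar geometry.** The NOAA fractional-year series for declination and
the equation of time; agreement with an independent Michalsky ephemeris
is within 0.3° on random samples, ample for the direct-beam terms.

**Scenarios.** Four fixed (solar, wind) exposure scenarios — shade at
10 m/s, 400 W/m² at 3 m/s, 1000 W/m² at 10 m/s, 1000 W/m² at 1 m/s —
are evaluated at the 12:00 local zenith at the mean settlement
coordinates (−5.14, 119.43) on a configurable reference date (default
1 March, mid wet season; ~4.7°).  Shade scenarios route through the
Bernard model with the scenario wind.  A caveat worth knowing: at
near-overhead sun the direct-beam load on globe and wick is small, so
(400 W/m², 3 m/s) and (1000 W/m², 10 m/s) produce WBGTs within a few
hundredths of a degree of each other — a physical near-tie, not an
ordered pair; the shade scenario is always coolest and (1000 W/m²,
1 m/s) always hottest.

## Sensor pipeline

Processing order and rules:

1. **Joint validity.** A (settlement, calendar month) block is kept only
   if it contains at least one temperature and one humidity record;
   otherwise all of the settlement's records in that month are dropped
   and counted.  The period granularity is configurable.
2. **Percentile adjustment.** Within each (settlement, placement, hour)
   group, readings above the group's 95th percentile (linear
   interpolation between order statistics, the R default) are capped to
   it.  Record counts are conserved and capped records are flagged, so
   attrition is fully auditable.  A city-wide pooling mode exists for
   sensitivity checks; per-settlement is the default because settlements
   have distinct climates and retrieval periods.  Note the operation is
   *not* exactly idempotent under an interpolated quantile: after one
   pass ≥5 % of a group sits at the old cap and the re-computed
   interpolated quantile falls slightly below it.  Idempotence is exact
   when q·(n−1) is integral; a second pass otherwise shifts capped
   values by at most a few hundredths of a degree at realistic noise.
3. **House hourly means** over whatever loggers reported that hour
   (two-hourly members simply thin the denominator on odd hours).
4. **Settlement vapour pressure**: the hourly median across the outdoor
   loggers' `vp = RH/100·es(adj T)` (even counts take the midpoint).
5. **Humidity reconstruction** per unit from the settlement vapour
   pressure and the unit's own adjusted temperature; dew point from the
   vapour pressure, capped at the unit temperature.
6. **Indices.**  TW via the closed form (saturation rule applied after
   reconstruction); WBGT via Bernard for houses and Liljegren for
   outdoor loggers with a user-supplied hourly wind/solar series or
   constants.  The built-in default is deliberately conservative
   (1 m/s, no sun) — realistic sun exposure is explored through the
   scenario machinery.  Records outside the closed form's validity
   range are flagged, never silently dropped.

Timestamps are timezone-aware local time at a fixed UTC+8 offset
(Makassar has no DST); naive CSV timestamps are assumed local.

## Exposure statistics

* **Daily maximum TW**: per unit and local calendar date; equal maxima
  resolve to the earliest record of the day.
* **Exceedance runs**: maximal periods whose observed WBGT stays at or
  above a threshold, bridging *silent* intervals of up to 2 h between
  above-threshold records (the gap rule compensates for two-hourly
  recovery, not for cool interludes — an observed below-threshold record
  always terminates a run).  Duration counts clock hours inclusive of
  bridged gaps; `n_records` counts observed records only.
* **Band frequencies**: half-open bands between the ordered thresholds
  plus cumulative ≥-fractions.
* **Day/night**: day is [06:00, 18:00) local by default — equatorial
  daylight is nearly constant twelve hours; the boundary is
  configurable.
* **Station comparison**: same-day pairing of in-situ daily maxima with
  the cross-station daily maximum (per-station pairings also reported);
  returns per-day differences, their mean and standard error, and the
  count of unpairable days.

## Station reading

ISD-Lite (fixed-width, tenths scaling, −9999 sentinel, implicit passing
QC) and the full-ISD mandatory section (explicit per-field QC codes) are
auto-detected per line.  QC filtering keeps codes {1, 5} ("passed all
quality control checks") and additionally enforces dew point ≤
temperature and plausibility bounds of −30…60 °C, with removals counted
by reason.  Sub-hourly records are averaged field-wise into clock
hours.  Station TW uses exactly the in-situ machinery (RH from
`es(Td)/es(T)`, same saturation rule), after converting timestamps to
local time for daily grouping.

## Synthetic data

The generator is a *controllable truth*, not a microclimate model.
Outdoor truth per settlement is `mean_t + offset + seasonal +
A·cos(2π(h−14)/24)`; house truth damps the amplitude (×0.5), lags it
(3 h) and adds a warm bias (+0.5 °C), which reproduces the qualitative
day/night inversion (houses warmer than outdoors at night, cooler by
day).  A smooth vapour-pressure series is shared within a settlement;
observed RH derives from true vapour pressure at the observed (noisy)
temperature.  Defaults: 12 settlements spanning ±1 °C, diurnal amplitude
4 °C around 29 °C, vapour pressure ~32 hPa, sensor noise σ = 0.3 °C,
2 % of outdoor daytime records spiked by |N(3, 1)| °C, block dropout
(rate 0.002/h, 48 h blocks), stations 1.3 °C cooler than the
settlement mean at equal humidity.  Per-logger RNG sub-streams hang off
one seed, so adding units never perturbs existing series.

What passing recovery tests do **not** show: real iButton data have
calibration drift, radiative errors correlated across neighbours,
non-sinusoidal weather, and humidity sensor failure modes none of which
are modelled; the tests demonstrate the pipeline's algebra and
robustness properties, not field accuracy.

Problem sizes used by the acceptance suite: the adjustment-recovery test
runs the default 12-settlement structure over 14 days (~200k raw
records); the fraction-recovery test over 28 days (~10⁴ records per
settlement); the station-offset test pairs 200 simulated days; oracle
tests use 1000 random series each.

## Known limitations

* No pressure/altitude dependence beyond the configurable constant; no
  ice-phase psychrometrics.
* No gap-filling or calibration-drift modelling; missing data stay
  missing.
* Wind and solar radiation must be supplied (series or scenario
  constants); no reanalysis downscaling.
* The scenario mid-pair near-tie above means record-wise scenario
  orderings are only guaranteed for the shade/extreme pairs.
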