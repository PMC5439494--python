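# Methods

## Model structure and assumptions

The simulation follows the water-driven crop-model paradigm: biomass is a
linear function of accumulated transpiration normalized by atmospheric
demand, and all ecophysiological detail is collapsed into a small set of
crop parameters. The daily loop is:

1. **Thermal time.** Daily growing degree days are
   `clamp(mean(Tmin, Tmax), Tb, Tu) - Tb` with base temperature Tb = 0 °C
   and upper optimum Tu = 25 °C, the simplest of the published GDD
   variants (a single clamp of the daily mean). Phenology milestones
   (emergence, maximum rooting, senescence onset, maturity) are expressed
   in cumulative GDD from emergence and mapped to calendar dates.
2. **Canopy cover.** Piecewise exponential trajectory: growth
   `CC = CC0*exp(CGC*t)` up to CCx/2, then the mirrored approach
   `CC = CCx - 0.25*(CCx^2/CC0)*exp(-CGC*t)`, a plateau at CCx, and after
   senescence onset the decline `CCx*(1 - 0.05*(exp((CDC/CCx)*ts) - 1))`
   floored at zero. The approach form is asymptotic, so full cover is
   declared once it comes within 1% of CCx and the plateau then holds CCx
   exactly; the decline is additionally capped by the pre-senescence cover
   so CC is non-increasing after senescence. Both conventions introduce
   steps below 1% of cover and are invisible at observation noise levels.
3. **Reference evapotranspiration.** FAO-56 daily Penman-Monteith with
   soil heat flux G = 0, vapour pressures from the Tmin/Tmax and
   RHmin/RHmax extremes, net radiation from measured shortwave radiation
   against the clear-sky envelope, and the result clipped at zero. The
   implementation is cross-checked against an independently coded oracle
   to 0.01 mm over 1000 random days.
4. **Soil-water balance.** 0.1-m compartments to 1.5 m depth (covering the
   0.8-m root zone and typical sensor depths). Order of operations:
   curve-number runoff (S = 254*(100/Cn - 1), initial abstraction 0.05*S)
   — infiltration (fill toward saturation, excess joins runoff) — drainage
   of above-field-capacity water with a daily fraction derived from Ksat —
   capillary rise — soil evaporation — root extraction. The daily balance
   must close to 1e-6 mm or the stepper raises: closure failure can only
   be an accounting bug.
5. **Production.** Transpiration demand `Ks*KcTr,x*CC**ET0` (CC* is the
   published cubic micro-advective adjustment `1.72CC - CC^2 + 0.3CC^3`,
   isolated in one function so it can be swapped), extracted from the root
   zone under per-compartment caps interpolated from `rtexup` (top
   quarter) to `rtexlw` (bottom quarter). Biomass accumulates as
   `WP*Ksb*Tr/ET0` per day during the growing season, in g m-2 internally
   and Mg ha-1 at the interface. The harvest index rises logistically over
   the final `HI_length` = 50% of the cycle.

### Assumptions worth stating

- **Constant rooting depth** of 0.8 m: minimum and maximum effective
  rooting depth coincide for an established coppice root system, so root
  deepening is disabled.
- **Ks regime.** Stress thresholds default to depletion fractions 0.5/1.0
  of total available water. Under a shallow water table with capillary
  rise the simulated crop effectively never leaves Ks = 1, but the stress
  machinery is in place and tested.
- **Biomass per rotation year.** B restarts at each emergence and WP
  differs between the coppice year (10.4 g m-2) and the resprout year
  (14 g m-2), matching how a coppice plantation is measured and harvested.
  The final yield of a year uses the HI at maturity. Only the
  rotation-cumulative Y/B ratio is HI-constrained; per-year ratios are
  reported but not interpreted.
- **Harvest index growth coefficient.** HIGC is not part of the parameter
  sheet; it is derived so the logistic covers 98% of (HI - HI_ini) exactly
  at the end of the build-up window. The end-of-season HI is therefore
  ~0.666 rather than the asymptotic 0.68 — a deliberate convention of the
  98% rule.
- **Woody-crop HI definition.** B is total (above- plus belowground)
  biomass and HI the woody aboveground fraction without leaves, so Y <= B
  always.

## Parameters

Crop parameter sets (one per rotation-year type) carry canopy (CC0, CCx,
CGC, CDC), phenology (Eme/Root/Sen/Mat in GDD), transpiration (KcTr,x =
0.99), production (WP, HI = 68%, HI_ini = 0.01%, HI_length = 50%), root
extraction caps, and the mulch schedule. The mulch percentages reduce soil
evaporation by phase: before/during/after the season 63/21/81% in coppice
years and 81/86/81% in resprout years. (The parameter sheet and its prose
description disagree on two of these values — the sheet's 21/86 vs the
prose's 63/83 for the growing seasons; the sheet values are used verbatim
and the conflict is recorded here rather than resolved.) In late season,
senesced canopy still shades the soil: the effective cover for evaporation
is raised by `evardc` = 70% of the cover lost since the seasonal peak,
applied before the mulch factor.

Soil: loamy sand with field capacity 22 vol%, wilting point 10 vol%,
saturation 41 vol%, Ksat 1200 mm day-1, curve number 46, readily
evaporable water 8 mm (typical for loamy sand), evaporative layer = top
compartment (0.1 m), air-dry content = half the wilting point.

**Capillary rise** is a parametric stand-in: `CR(z) = CRmax*exp(-z/zs)`
with CRmax = 5 mm day-1, zs = 0.5 m, cutoff 2 m, capped by the root-zone
deficit below field capacity. The exponential decay reproduces the
qualitative behaviour (strong rise under a sub-meter water table,
negligible below 2 m); the two shape parameters are configurable and
should be re-fitted if a texture-specific steady-state solution is
available.

**Percolation** drains above-field-capacity water with daily fraction
`tau = min(1, Ksat/(1000*(sat - fc)*dz*10))`, an open simplification of
the full drainage calculus; at Ksat = 1200 mm day-1 it saturates at 1, so
excess water leaves within a day, appropriate for a coarse soil.

## Synthetic data: what it emulates, and what it does not

The generators target a temperate maritime lowland site: ~820 mm annual
precipitation spread uniformly (Bernoulli occurrence p = 0.5, exponential
amounts), annual reference evapotranspiration falling in 550-900 mm,
seasonal temperature cycle with winter means near 3 °C and summer near
18 °C plus AR(1) anomalies, radiation as a clear-sky envelope times
rain-coupled cloudiness, and a water table shallow in winter (~0.35 m)
dipping to ~1.5-1.7 m in late summer (U-shaped daily curves). Each year's
precipitation total is regulated toward the annual target with ~3.5% scatter:
the emulated climate shows remarkably stable annual totals, and a free sum
of exponential day amounts would scatter three times wider.

Pseudo-observations around a truth run carry: Laplace
(double-exponential) noise on daily ET with scale following the
random-error law `a*(ln ET + c)`, a = 0.0609, c = 0.209 (floored at 0.01
mm where the law turns negative); Gaussian noise (sigma = 0.02) on soil
water content and canopy cover; ~12 canopy surveys per growing season; 5%
relative noise on end-of-season biomass; and synthetic energy fluxes
constructed so the turbulent fluxes close the available energy at a
configurable fraction (default 0.72) with LE consistent with the observed
ET.

For the random-error round trip a dedicated paired-day series is
generated: consecutive days share identical true ET and reference demand
(so the pair survives the |dET0| filter) while demand jumps between pairs
(so cross-pair differences are filtered out) — exactly the
equivalent-conditions premise of the paired-day error method. Because the
estimator takes the MAD of *differences* of two noisy days, and the
difference of two independent Laplace variables has MAD 1.5 times the
per-day scale, the generator divides the per-day scale by 1.5 so that the
quantity the estimator measures follows the stated law. Levels are drawn
above `exp(-c) + 0.4` mm, the domain where the logarithmic law is
positive.

What passing tests therefore show: the statistical machinery (skill
scores, calibration, error estimators) is correct and recovers known
truth at realistic noise. What they do not show: skill against real field
records — the synthetic observations are noise around the model's own
truth run, so they cannot expose structural model error (canopy-conductance
dynamics, sensor drift and changes, gap-filling artefacts, weed
understorey), and real-data skill will be lower.

## Numerical and statistical choices

- **Skill.** NRMSE = 100*RMSE/(max(obs) - min(obs)); R2 and the overall-F
  p-value come from the least-squares fit of observations on simulations
  (for simple linear regression the slope-t and overall-F tests coincide).
  Constant observed series are a hard error.
- **Annual tables.** Ratios are computed at full precision and rounded to
  2 decimals only for presentation; partial calendar years are an error
  unless explicitly allowed.
- **RME binning.** Pairs sorted by pair-mean ET into 10 equal-size groups;
  when the count is not divisible by 10 the earlier groups take the
  extras (`numpy.array_split` order, stable); the bin abscissa is the
  median ET of the group. A non-positive fitted slope or zero variance
  marks the model degenerate, and evaluating a degenerate model raises.
  Distribution diagnostics (skewness, excess kurtosis of the paired
  differences) are reported; formal normality testing is left to standard
  routines.
- **Calibration.** Canopy coefficients are fitted by deterministic
  multi-start (factors 0.5/1/2 on the starting point) bounded
  trust-region least squares; the recorded trace is the best objective
  after each start and is non-increasing by construction. WP is linear in
  the biomass equation, so its calibration is the exact quotient
  `B/(0.01*sum(Tr/ET0))`.
- **Stochastic recovery checks** are summarized by medians over seeds
  (10 seeds for parameter recovery, 5 for the random-error round trip)
  rather than single draws: the `c` coefficient of the error law is an
  intercept-to-slope ratio whose single-series sampling error is ~30% of
  its value, so any single-seed assertion would be a coin flip in either
  direction.
- **Missing weather** is a hard error by default; linear interpolation is
  available only for value gaps of at most 2 days and never for missing
  dates — silent infill would corrupt the water balance.
- **Problem sizes.** The default campaign is 4 years (1461 days, ~0.2 s
  per simulation); recovery studies use 10 seeds; the error-law round
  trip uses 3-year series (~547 retained pairs); ET0 validation uses 1000
  random days.

## Known limitations

- The capillary-rise form and the percolation fraction are transparent
  simplifications (see above); both are isolated behind single functions.
- No soil-salinity or soil-fertility stress, no preferential or lateral
  flow, no frozen-soil physics, no genotype-level canopy variation, no
  weed-understorey competition: yields are potential yields, and a real
  plantation with a substantial weed layer will fall short of them.
- Sub-daily (half-hourly) fluxes are out of scope; the energy-closure
  regression accepts any aligned series but the generator produces daily
  means.
- The two-sided t interval used for the mid-season crop-coefficient
  confidence bound is the conventional default; nothing fancier is
  attempted.
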