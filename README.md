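# aquasrc

Water-driven simulation of water use and yield of a poplar short-rotation
coppice (SRC), with model-skill evaluation and eddy-covariance uncertainty
estimation.

## The problem

Poplar SRC plantations are a candidate bioenergy crop in temperate maritime
Europe, and their water consumption and attainable yield are central to the
debate about converting agricultural land to them. This package implements a
water-driven crop simulation of the AquaCrop family for such a plantation:
a daily root-zone soil-water balance feeding canopy transpiration, biomass
accumulation through a normalized water productivity, and yield through a
harvest index — together with everything needed to calibrate and evaluate
such a simulation against field records (skill statistics, annual water-use
partitioning, canopy and water-productivity calibration, the random
measurement error of eddy-covariance ET, and energy-balance closure).

It is written for agro-ecosystem modellers and bioenergy researchers who
want a transparent, tested implementation of this model chain that runs
end-to-end on synthetic data with known truth, so that every statistical
procedure can be validated by parameter recovery before being pointed at
field data.

## The model

Daily crop transpiration (mm) is

    Tr_i = Ks_i * KcTr,x * CC*_i * ET0_i

where `Ks` is the soil-water stress coefficient from root-zone depletion,
`KcTr,x` the maximum crop transpiration coefficient, `CC*` the green canopy
cover adjusted for micro-advective effects, and `ET0` the FAO-56
Penman-Monteith reference evapotranspiration. Biomass accumulates as

    B = WP * sum_i Ksb_i * Tr_i / ET0_i

with `WP` the normalized water productivity (g m-2) and `Ksb` a cold-stress
coefficient, and yield is `Y_i = HI_i * B_i` with a logistic harvest index
building from `HI_ini` to its final value over the last part of the cycle.
Canopy cover develops in thermal time (growing degree days) through a
piecewise exponential growth/decline trajectory, and is linked to leaf area
index by Beer's law, `CC = 1 - exp(-k * LAI)` with `k = 0.6` for poplar.
The soil-water balance tracks curve-number runoff (initial abstraction 5%
of storage), infiltration, conductivity-limited drainage, capillary rise
from the shallow water table, two-stage mulch-modulated soil evaporation,
and depth-weighted root extraction over 0.1-m compartments, and must close
to 1e-6 mm every day.

A coppice rotation is handled as two parameter sets per 2-year rotation:
the year after the coppice cut (late emergence, slow canopy growth,
`WP = 10.4 g m-2`) and the resprout year (earlier emergence, fast closure,
`WP = 14 g m-2`).

The random measurement error of daily eddy-covariance ET is estimated from
pairs of consecutive days with near-identical atmospheric demand
(|dET0| <= 0.6 mm): the mean absolute deviation of the paired ET
differences in ten ET-magnitude groups, fitted as `RME = a*(ln ET + c)`.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
4-year campaign (two 2-year rotations, temperate maritime climate, shallow
water table) with known truth:

```sh
python analysis/01_generate_forcing.py --seed 0
python analysis/02_simulate_rotations.py
python analysis/03_evaluate_skill.py --seed 0
python analysis/04_uncertainty.py --seed 0
python analysis/05_calibration_recovery.py --seeds 10
```

The simulation stage prints, per calendar year (seed 0):

```
   year  pr_tot  et0_tot  e_soil_tot  tr_tot  et_tot  et_over_et0  tr_over_et  e_soil_over_et     b     y
   2012  861.87   614.69      171.16  350.74  521.90         0.85        0.67            0.33 17.35 11.54
   2013  815.33   631.04       31.03  409.48  440.51         0.70        0.93            0.07 22.90 15.22
   2014  862.38   632.15      161.34  371.02  532.36         0.84        0.70            0.30 18.06 12.03
   2015  813.20   652.84       32.60  395.65  428.25         0.66        0.92            0.08 20.85 13.84
```

Totals are mm per year, `b` and `y` Mg ha-1 yr-1 of dry mass. The
partitioning is the model's signature behaviour: in coppice years the young
canopy lets the soil evaporate freely (E_soil/ET ~ 0.3) while in resprout
years the closed canopy and mulch layer push transpiration to >90% of ET.
The evaluation stage scores the simulation against noisy
pseudo-observations (ET R2 ~ 1.0, SWC R2 ~ 0.74, CC R2 ~ 1.0), recovers
the mid-season crop transpiration coefficient (0.96, 90% CI 0.95-0.98,
generating value 0.99), and the uncertainty stage fits

```
RME(ET) = 0.0629 * (ln(ET) + 0.214) mm
energy balance closure: (H+LE) = 0.723 * (Rn-G), R2 = 0.975
```

against generating values of (0.0609, 0.209) and 0.72. The calibration
stage recovers the canopy growth/decline coefficients and the water
productivity from noisy observations with median errors of ~2%, ~1% and
~5%.

The same machinery is scriptable through the `aquasrc` CLI
(`synth`, `simulate`, `evaluate`, `calibrate`, `rme`).

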