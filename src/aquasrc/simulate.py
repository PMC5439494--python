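"""Full daily simulation pipeline.

Chains the forcing, canopy, soil-water and production components into the
four-step daily loop of a water-driven crop model: canopy cover from thermal
time, transpiration from canopy and atmospheric demand under soil-water
stress, biomass from normalized water productivity, and yield through the
harvest index.  One rotation year (one parameter set, one emergence date) is
simulated per calendar year; biomass restarts at each emergence, matching
how a coppice plantation is measured and harvested per year.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forcing, production, soil_water
from .canopy import RotationSchedule, canopy_cover, phase_for_date
from .forcing import SiteConfig, season_calendar
from .soil_water import SoilParams, SoilState

__all__ = ["SimOutput", "run_simulation", "interpolate_water_table"]

DAILY_COLUMNS = [
    "date", "label", "phase", "et0", "gdd", "cum_gdd", "cc", "swc_030",
    "water_table_depth", "pr", "runoff", "infiltration", "percolation",
    "capillary_rise", "e_soil", "tr", "et", "storage", "b", "hi", "y",
]


@dataclass
class SimOutput:
    """Daily series plus per-rotation-year production aggregates."""

    daily: pd.DataFrame
    per_year: pd.DataFrame  # one row per rotation year: b, y at season end
    schedule: RotationSchedule = field(repr=False, default=None)

    def rotation_totals(self, labels: list[str]) -> dict[str, float]:
        """Cumulative B and Y over a set of rotation years."""
        sub = self.per_year[self.per_year["label"].isin(labels)]
        return {"b": float(sub["b"].sum()), "y": float(sub["y"].sum())}


def interpolate_water_table(series: pd.DataFrame, dates: list[_dt.date]) -> np.ndarray:
    """Linearly interpolate observed water-table depths onto the daily grid.

    ``series`` has columns ``date`` and ``depth`` (m below surface); values
    outside the observed span hold the nearest observation.
    """
    obs_dates = pd.to_datetime(series["date"]).map(pd.Timestamp.toordinal).to_numpy()
    target = np.array([d.toordinal() for d in dates], dtype=float)
    depth = series["depth"].to_numpy(dtype=float)
    if np.any(depth < 0):
        raise ValueError("water-table depth must be non-negative")
    return np.interp(target, obs_dates, depth)


def run_simulation(
    weather: pd.DataFrame,
    site: SiteConfig,
    schedule: RotationSchedule,
    soil: SoilParams,
    water_table: pd.DataFrame | None = None,
    initial_state: SoilState | None = None,
    p_upper: float = 0.5,
    p_lower: float = 1.0,
) -> SimOutput:
    """Run the daily water-balance and production simulation.

    Parameters
    ----------
    weather
        Validated daily weather table (see :func:`aquasrc.forcing.load_weather`).
    water_table
        Optional observed water-table series (columns ``date``, ``depth``);
        without it no capillary rise occurs.
    initial_state
        Starting soil-water state; field capacity if omitted.
    p_upper, p_lower
        Depletion thresholds (fractions of total available water) of the
        water-stress coefficient.
    """
    dates = list(pd.to_datetime(weather["date"]).dt.date)
    et0 = forcing.et0_series(weather, site).to_numpy()
    calendar = season_calendar(schedule, weather)
    windows = {w.label: w for w in calendar}
    year_by_cal = {y.emergence.year: y for y in schedule.years}
    if len(year_by_cal) != len(schedule.years):
        raise ValueError("one rotation year per calendar year is required")

    wt = (interpolate_water_table(water_table, dates)
          if water_table is not None else np.full(len(dates), math.inf))

    state = initial_state.copy() if initial_state is not None else \
        SoilState.at_field_capacity(soil, wt[0])

    # per-rotation-year HI timing
    hi_timing: dict[str, tuple[_dt.date, float]] = {}
    for y in schedule.years:
        win = windows[y.label]
        mat = win.milestones_date.get("mat") or win.end
        cycle_days = (mat - y.emergence).days + 1
        buildup = max(1.0, y.params.hi_length * cycle_days)
        hi_start = mat - _dt.timedelta(days=int(round(buildup)) - 1)
        higc = production.derive_higc(y.params, buildup)
        hi_timing[y.label] = (hi_start, higc)

    n_root = {y.label: max(1, int(round(y.params.rt_x / soil.dz))) for y in schedule.years}
    rows = []
    prod: dict[str, production.ProductionState] = {}
    cc_peak: dict[str, float] = {}

    for i, date in enumerate(dates):
        ry = year_by_cal.get(date.year)
        if ry is None:
            raise ValueError(f"no rotation year covers {date.year}")
        p = ry.params
        win = windows[ry.label]
        _, phase = phase_for_date(date, schedule, calendar)
        state.water_table_depth = float(wt[i])

        if phase == "growing":
            cum_gdd = win.date_to_gdd(date)
            cc = canopy_cover(cum_gdd, p)
            daily_gdd = forcing.compute_gdd(
                float(weather["tmin"].iloc[i]), float(weather["tmax"].iloc[i]), p.tb, p.tu)
        else:
            cum_gdd, cc, daily_gdd = 0.0, 0.0, 0.0
        peak = cc_peak.get(ry.label, 0.0)
        if cc > peak:
            peak = cc
        cc_peak[ry.label] = peak

        nr = n_root[ry.label]
        cell = soil.dz * soil_water.MM_PER_M
        depletion = float(np.clip(soil.swc_fc - state.theta[:nr], 0.0, None).sum() * cell)
        taw = (soil.swc_fc - soil.swc_pwp) * p.rt_x * soil_water.MM_PER_M
        ks = soil_water.stress_coefficient(depletion, taw, p_upper, p_lower)
        demand = production.transpiration(ks, p.kctrx, production.cc_star(cc), float(et0[i]))

        state, fluxes = soil_water.step_water_balance(
            state, float(weather["pr"].iloc[i]), float(et0[i]), cc, phase,
            p, soil, tr_demand=demand, cc_peak=peak,
        )

        ps = prod.setdefault(ry.label, production.ProductionState())
        if phase == "growing" and et0[i] > 0:
            ps = production.accumulate_biomass(ps, fluxes.tr, float(et0[i]), p.wp, p.ksb)
        hi_start, higc = hi_timing[ry.label]
        t_hi = (date - hi_start).days
        if t_hi >= 0 and phase == "growing":
            ps.hi = production.harvest_index(float(t_hi), p, higc=higc)
        elif t_hi >= 0 and ps.hi == 0.0:
            ps.hi = p.hi_ini
        prod[ry.label] = ps
        y_val = production.harvestable_yield(ps.biomass, ps.hi)

        rows.append((date, ry.label, phase, float(et0[i]), daily_gdd, cum_gdd, cc,
                     state.layer_swc(soil), float(wt[i]) if math.isfinite(wt[i]) else np.nan,
                     fluxes.pr, fluxes.runoff, fluxes.infiltration, fluxes.percolation,
                     fluxes.capillary_rise, fluxes.e_soil, fluxes.tr, fluxes.et,
                     state.storage_mm(soil), ps.biomass, ps.hi, y_val))

    daily = pd.DataFrame(rows, columns=DAILY_COLUMNS)
    per_year = pd.DataFrame(
        [
            {"label": lbl, "b": st.biomass, "hi": st.hi,
             "y": production.harvestable_yield(st.biomass, st.hi),
             "tr_over_et0_sum": st.tr_over_et0_sum}
            for lbl, st in prod.items()
        ]
    )
    return SimOutput(daily=daily, per_year=per_year, schedule=schedule)
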