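"""Green canopy cover dynamics and the LAI <-> canopy-cover conversion.

Canopy cover (CC, fraction of ground shaded by green canopy) develops in
thermal time through a piecewise exponential trajectory: exponential growth
from the initial cover CC0 up to half the maximum cover CCx, an exponential
approach toward CCx after that, a plateau at CCx, and after the onset of
senescence an exponential-type decline governed by the canopy decline
coefficient.  LAI and CC are linked by Beer's law of light extinction,
CC = 1 - exp(-k * LAI), with extinction coefficient k estimable from
transmitted vs incoming photosynthetically active radiation.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CropPhaseParams",
    "RotationYear",
    "RotationSchedule",
    "lai_to_cc",
    "cc_to_lai",
    "extinction_coefficient",
    "canopy_cover",
    "phase_for_date",
]


@dataclass(frozen=True)
class CropPhaseParams:
    """Crop parameter set for one rotation year.

    Canopy-cover fractions are stored internally as fractions (0-1); percent
    appears only at I/O boundaries.  Phenology milestones are in growing
    degree days from planting/resprouting; canopy coefficients are per GDD.
    """

    cc0: float  # initial canopy cover, fraction
    ccx: float  # maximum canopy cover, fraction
    cgc: float  # canopy growth coefficient, fraction GDD-1
    cdc: float  # canopy decline coefficient, fraction GDD-1
    eme: float  # sowing -> emergence, GDD
    root: float  # sowing -> maximum rooting depth, GDD
    sen: float  # sowing -> senescence onset, GDD
    mat: float  # sowing -> maturity, GDD
    rt_n: float = 0.8  # minimum effective rooting depth, m
    rt_x: float = 0.8  # maximum effective rooting depth, m
    kctrx: float = 0.99  # maximum crop transpiration coefficient
    wp: float = 14.0  # normalized water productivity, g m-2
    hi: float = 0.68  # final harvest index, fraction
    hi_ini: float = 0.0001  # initial harvest index, fraction
    hi_length: float = 0.5  # HI build-up span, fraction of growing cycle
    higc: float | None = None  # HI growth coefficient, day-1 (derived if None)
    tb: float = 0.0  # base temperature, degC
    tu: float = 25.0  # upper temperature, degC
    ksb: float = 1.0  # cold-stress coefficient for biomass
    rtexup: float = 0.036  # max root extraction, top quarter, m3 m-3 day-1
    rtexlw: float = 0.009  # max root extraction, bottom quarter, m3 m-3 day-1
    mulch_pre: float = 0.0  # % soil-evaporation reduction before the season
    mulch_grow: float = 0.0  # % during the season
    mulch_post: float = 0.0  # % after the season
    evardc: float = 70.0  # % late-season soil-evaporation reduction by canopy

    def __post_init__(self) -> None:
        if not 0.0 < self.cc0 < self.ccx <= 1.0:
            raise ValueError("require 0 < cc0 < ccx <= 1")
        if self.cgc <= 0 or self.cdc <= 0:
            raise ValueError("canopy growth/decline coefficients must be positive")
        if not (self.eme <= self.root <= self.sen <= self.mat):
            raise ValueError("require Eme <= Root <= Sen <= Mat")
        if not 0.0 <= self.hi_ini < self.hi <= 1.0:
            raise ValueError("require 0 <= hi_ini < hi <= 1")
        for m in (self.mulch_pre, self.mulch_grow, self.mulch_post, self.evardc):
            if not 0.0 <= m <= 100.0:
                raise ValueError("mulch/evardc percentages must lie in [0, 100]")
        if self.rt_n > self.rt_x:
            raise ValueError("rt_n must not exceed rt_x")
        if self.tb >= self.tu:
            raise ValueError("tb must be below tu")


@dataclass(frozen=True)
class RotationYear:
    """One year of the rotation schedule."""

    label: str
    emergence: _dt.date
    params: CropPhaseParams
    coppice: bool = False  # first year after a coppice cut


@dataclass
class RotationSchedule:
    years: list[RotationYear] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [y.label for y in self.years]
        if len(set(labels)) != len(labels):
            raise ValueError("rotation-year labels must be unique")

    def __iter__(self):
        return iter(self.years)


# ---------------------------------------------------------------------------
# Beer's law


def lai_to_cc(lai: float, k: float = 0.6) -> float:
    """Canopy cover from leaf area index via Beer's law: 1 - exp(-k*LAI)."""
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    if k <= 0:
        raise ValueError("extinction coefficient must be positive")
    return 1.0 - math.exp(-k * lai)


def cc_to_lai(cc: float, k: float = 0.6) -> float:
    """Inverse of :func:`lai_to_cc`."""
    if not 0.0 <= cc < 1.0:
        raise ValueError("CC must lie in [0, 1)")
    return -math.log(1.0 - cc) / k


def extinction_coefficient(par_t, par_i, lai):
    """Light extinction coefficient k = -ln(PARt/PARi)/LAI.

    Accepts scalars or aligned arrays of below-canopy transmitted (PARt) and
    incoming (PARi) photosynthetically active radiation with the concurrent
    LAI.
    """
    par_t = np.asarray(par_t, dtype=float)
    par_i = np.asarray(par_i, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(par_t <= 0) or np.any(par_i <= 0):
        raise ValueError("PAR values must be positive")
    if np.any(par_t > par_i):
        raise ValueError("transmitted PAR cannot exceed incoming PAR")
    if np.any(lai <= 0):
        raise ValueError("LAI must be positive")
    k = -np.log(par_t / par_i) / lai
    return float(k) if k.ndim == 0 else k


# ---------------------------------------------------------------------------
# canopy trajectory


def canopy_cover(gdd_elapsed: float, p: CropPhaseParams) -> float:
    """Green canopy cover at a given thermal time since planting/resprouting.

    Piecewise trajectory: before emergence 0; exponential growth
    ``cc0*exp(cgc*t)`` while CC <= ccx/2; exponential approach
    ``ccx - 0.25*ccx^2/cc0 * exp(-cgc*t)`` toward the ccx plateau; after the
    senescence onset an exponential-type decline
    ``ccx*(1 - 0.05*(exp((cdc/ccx)*ts) - 1))`` floored at zero.  The decline
    is additionally capped by the pre-senescence cover so that CC is
    non-increasing after senescence.
    """
    if gdd_elapsed < 0:
        raise ValueError("thermal time must be non-negative")
    t = gdd_elapsed - p.eme
    if t < 0:
        return 0.0
    cc_grow = _growth_cc(min(t, p.sen - p.eme), p)
    if t <= p.sen - p.eme:
        return cc_grow
    ts = t - (p.sen - p.eme)
    cc_dec = p.ccx * (1.0 - 0.05 * (math.exp((p.cdc / p.ccx) * ts) - 1.0))
    return max(0.0, min(cc_grow, cc_dec))


def _growth_cc(t: float, p: CropPhaseParams) -> float:
    cc = p.cc0 * math.exp(p.cgc * t)
    if cc > p.ccx / 2.0:
        cc = p.ccx - 0.25 * (p.ccx ** 2 / p.cc0) * math.exp(-p.cgc * t)
        # full cover is attained once the approach is within 1% of ccx;
        # the mid-season plateau then holds ccx itself
        if cc >= 0.99 * p.ccx:
            cc = p.ccx
    return min(cc, p.ccx)


def phase_for_date(date: _dt.date, schedule: RotationSchedule, calendar) -> tuple[CropPhaseParams, str]:
    """Locate a date in the rotation schedule.

    Returns the governing year's parameter set and a phase label:
    ``pre-season`` (before that year's emergence), ``growing`` (emergence up
    to maturity), or ``post-season`` (after maturity).  ``calendar`` is the
    list of :class:`~aquasrc.forcing.SeasonWindow` from
    :func:`~aquasrc.forcing.season_calendar`.
    """
    for year, window in zip(schedule.years, calendar):
        if date.year != year.emergence.year:
            continue
        if date < year.emergence:
            return year.params, "pre-season"
        mat_date = window.milestones_date.get("mat")
        if mat_date is not None and date > mat_date:
            return year.params, "post-season"
        if date <= window.end:
            return year.params, "growing"
        return year.params, "post-season"
    raise ValueError(f"{date} outside the rotation schedule")
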