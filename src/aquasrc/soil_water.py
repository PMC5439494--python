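"""Daily root-zone soil-water balance.

The profile is discretised into thin compartments (default 0.1 m down to
1.5 m).  Each day, in order: curve-number surface runoff, infiltration,
drainage of water held above field capacity (rate limited by the saturated
conductivity), capillary rise from a shallow water table, soil evaporation
(two-stage drying, modulated by a mulch factor and by senesced canopy), and
root water extraction for transpiration.  The balance must close to 1e-6 mm
every day; a violation raises, as it can only be an accounting bug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .canopy import CropPhaseParams

__all__ = [
    "SoilParams",
    "SoilState",
    "DailyFluxes",
    "WaterBalanceError",
    "runoff",
    "soil_evaporation",
    "capillary_rise",
    "stress_coefficient",
    "extract_transpiration",
    "step_water_balance",
]

MM_PER_M = 1000.0


class WaterBalanceError(AssertionError):
    """Daily mass balance failed to close (internal consistency bug)."""


@dataclass(frozen=True)
class SoilParams:
    """Static soil hydraulic properties.

    Water contents are volumetric fractions internally; vol% only at I/O.
    The capillary-rise function is a parametric stand-in (exponential decay
    with water-table depth) whose two shape parameters are the maximum rise
    at the surface and the decay length scale.
    """

    swc_fc: float = 0.22  # field capacity, m3 m-3
    swc_pwp: float = 0.10  # permanent wilting point, m3 m-3
    swc_sat: float = 0.41  # saturation, m3 m-3
    ksat: float = 1200.0  # saturated hydraulic conductivity, mm day-1
    cn: float = 46.0  # curve number
    rew: float = 8.0  # readily evaporable water, mm (loamy sand)
    profile_depth: float = 1.5  # m
    dz: float = 0.1  # compartment thickness, m
    cr_max: float = 5.0  # capillary rise with water table at the surface, mm day-1
    cr_zscale: float = 0.5  # decay length of capillary rise with depth, m
    cr_cutoff: float = 2.0  # no capillary rise below this water-table depth, m

    def __post_init__(self) -> None:
        if not 0.0 < self.swc_pwp < self.swc_fc < self.swc_sat < 1.0:
            raise ValueError("require 0 < pwp < fc < sat < 1")
        if self.ksat <= 0:
            raise ValueError("ksat must be positive")
        if not 0.0 < self.cn < 100.0:
            raise ValueError("curve number must lie in (0, 100)")

    @property
    def n_compartments(self) -> int:
        return int(round(self.profile_depth / self.dz))

    @property
    def air_dry(self) -> float:
        """Air-dry water content of the evaporative layer (half of PWP)."""
        return self.swc_pwp / 2.0

    @property
    def tew(self) -> float:
        """Total evaporable water of the top compartment, mm."""
        return (self.swc_fc - self.air_dry) * self.dz * MM_PER_M

    @property
    def drainage_fraction(self) -> float:
        """Daily fraction of above-field-capacity water that drains."""
        return min(1.0, self.ksat / (MM_PER_M * (self.swc_sat - self.swc_fc) * self.dz * 10.0))


@dataclass
class SoilState:
    """Evolving water store: per-compartment contents plus trackers."""

    theta: np.ndarray  # volumetric content per compartment, m3 m-3
    water_table_depth: float = math.inf  # m below surface; inf = no water table
    stage2_deficit: float = 0.0  # cumulative evaporation deficit of the top layer, mm

    @classmethod
    def at_field_capacity(cls, soil: SoilParams, water_table_depth: float = math.inf) -> "SoilState":
        return cls(theta=np.full(soil.n_compartments, soil.swc_fc),
                   water_table_depth=water_table_depth)

    def copy(self) -> "SoilState":
        return SoilState(self.theta.copy(), self.water_table_depth, self.stage2_deficit)

    def storage_mm(self, soil: SoilParams) -> float:
        return float(self.theta.sum() * soil.dz * MM_PER_M)

    def layer_swc(self, soil: SoilParams, top: float = 0.0, bottom: float = 0.3) -> float:
        """Thickness-weighted mean water content of a depth slab (fraction)."""
        z0 = np.arange(soil.n_compartments) * soil.dz
        z1 = z0 + soil.dz
        w = np.clip(np.minimum(z1, bottom) - np.maximum(z0, top), 0.0, None)
        if w.sum() <= 0:
            raise ValueError("depth slab does not intersect the profile")
        return float((self.theta * w).sum() / w.sum())


@dataclass(frozen=True)
class DailyFluxes:
    """All water fluxes of one day, mm day-1 (all non-negative)."""

    pr: float = 0.0
    runoff: float = 0.0
    infiltration: float = 0.0
    percolation: float = 0.0
    capillary_rise: float = 0.0
    e_soil: float = 0.0
    tr: float = 0.0

    @property
    def et(self) -> float:
        return self.e_soil + self.tr


# ---------------------------------------------------------------------------
# individual processes


def runoff(pr: float, cn: float) -> float:
    """SCS curve-number surface runoff with initial abstraction = 5% of S.

    S = 254*(100/cn - 1) mm is the surface storage capacity; rainfall below
    the initial abstraction Ia = 0.05*S produces no runoff.
    """
    if pr < 0:
        raise ValueError("precipitation must be non-negative")
    if pr == 0.0:
        return 0.0
    s = 254.0 * (100.0 / cn - 1.0)
    ia = 0.05 * s
    if pr <= ia:
        return 0.0
    return (pr - ia) ** 2 / (pr - ia + s)


def soil_evaporation(
    et0: float,
    cc: float,
    phase: str,
    p: CropPhaseParams,
    state: SoilState,
    soil: SoilParams,
    cc_peak: float = 0.0,
) -> float:
    """Soil evaporation for one day (mm); does not mutate ``state``.

    Potential evaporation is the reference demand over the canopy-free soil
    fraction, with the effective cover raised in late season by ``evardc`` %
    of the senesced canopy (dead leaves still shade the soil).  A
    phase-dependent mulch factor then reduces it.  The two-stage drying of
    the evaporative layer (top compartment) runs at the full rate while the
    cumulative stage deficit is below the readily evaporable water, then
    declines proportionally to the remaining evaporable water, and never
    exceeds the water held above air-dryness.
    """
    cc = min(max(cc, 0.0), 1.0)
    cc_eff = cc
    if cc_peak > cc:
        cc_eff = min(1.0, cc + (p.evardc / 100.0) * (cc_peak - cc))
    mulch = {"pre-season": p.mulch_pre, "growing": p.mulch_grow,
             "post-season": p.mulch_post}[phase]
    potential = et0 * (1.0 - cc_eff) * (1.0 - mulch / 100.0)
    if state.stage2_deficit > soil.rew:
        kr = max(0.0, (soil.tew - state.stage2_deficit) / (soil.tew - soil.rew))
        potential *= kr
    available = max(0.0, (state.theta[0] - soil.air_dry)) * soil.dz * MM_PER_M
    return min(potential, available)


def capillary_rise(water_table_depth: float, root_zone_deficit: float, soil: SoilParams) -> float:
    """Capillary rise from a shallow water table into the root zone (mm day-1).

    Parametric form: exponential decay with water-table depth,
    ``cr_max * exp(-depth / cr_zscale)``, zero beyond the cutoff depth, and
    capped by the root-zone deficit below field capacity so that no
    compartment is pushed above field capacity.
    """
    if root_zone_deficit < 0:
        raise ValueError("root-zone deficit must be non-negative")
    return min(_capillary_rise_rate(water_table_depth, soil), root_zone_deficit)


def stress_coefficient(
    root_zone_depletion: float,
    taw: float,
    p_upper: float = 0.5,
    p_lower: float = 1.0,
) -> float:
    """Soil-water stress coefficient Ks in [0, 1].

    Ks = 1 while root-zone depletion stays below p_upper*TAW, falls linearly
    to 0 at p_lower*TAW, and is 0 beyond.
    """
    if not 0.0 <= p_upper < p_lower <= 1.0:
        raise ValueError("require 0 <= p_upper < p_lower <= 1")
    if taw <= 0:
        raise ValueError("total available water must be positive")
    d_up, d_lo = p_upper * taw, p_lower * taw
    if root_zone_depletion <= d_up:
        return 1.0
    if root_zone_depletion >= d_lo:
        return 0.0
    return (d_lo - root_zone_depletion) / (d_lo - d_up)


def _root_extraction_caps(p: CropPhaseParams, soil: SoilParams) -> np.ndarray:
    """Per-compartment maximum daily extraction (mm) over the root zone.

    The top quarter of the root zone extracts at ``rtexup``, the bottom
    quarter at ``rtexlw``, with a linear transition between; volumetric rates
    convert to mm via the compartment thickness.
    """
    n_root = max(1, int(round(p.rt_x / soil.dz)))
    centers = (np.arange(n_root) + 0.5) / n_root
    frac = np.clip((centers - 0.25) / 0.5, 0.0, 1.0)
    rates = p.rtexup + frac * (p.rtexlw - p.rtexup)
    return rates * soil.dz * MM_PER_M


def extract_transpiration(
    demand: float,
    state: SoilState,
    p: CropPhaseParams,
    soil: SoilParams,
) -> float:
    """Extract transpiration water from the root zone, top down (mutates state).

    Each compartment supplies at most its extraction cap and never draws the
    content below wilting point.  Returns the water actually extracted
    (<= demand).
    """
    if demand < 0:
        raise ValueError("transpiration demand must be non-negative")
    caps = _root_extraction_caps(p, soil)
    extracted = 0.0
    remaining = demand
    for i, cap in enumerate(caps):
        if remaining <= 0:
            break
        avail = max(0.0, (state.theta[i] - soil.swc_pwp)) * soil.dz * MM_PER_M
        take = min(remaining, cap, avail)
        state.theta[i] -= take / (soil.dz * MM_PER_M)
        extracted += take
        remaining -= take
    return extracted


def step_water_balance(
    state: SoilState,
    pr: float,
    et0: float,
    cc: float,
    phase: str,
    p: CropPhaseParams,
    soil: SoilParams,
    tr_demand: float = 0.0,
    cc_peak: float = 0.0,
) -> tuple[SoilState, DailyFluxes]:
    """Advance the soil-water store by one day.

    Order of operations: runoff -> infiltration -> percolation -> capillary
    rise -> soil evaporation -> transpiration extraction.  Returns the new
    state and the day's fluxes; the daily mass balance is asserted to close
    to 1e-6 mm.
    """
    st = state.copy()
    storage0 = st.storage_mm(soil)
    cell = soil.dz * MM_PER_M

    ro = runoff(pr, soil.cn)
    infil = pr - ro
    # fill compartments from the top, capped at saturation; excess joins runoff
    water = infil
    for i in range(soil.n_compartments):
        if water <= 0:
            break
        room = (soil.swc_sat - st.theta[i]) * cell
        add = min(water, room)
        st.theta[i] += add / cell
        water -= add
    ro += water
    infil -= water

    # drainage cascade of above-field-capacity water, bottom flux leaves
    tau = soil.drainage_fraction
    inflow = 0.0
    for i in range(soil.n_compartments):
        st.theta[i] += inflow / cell
        drain = tau * max(0.0, st.theta[i] - soil.swc_fc) * cell
        overflow = max(0.0, st.theta[i] - soil.swc_sat) * cell
        drain = max(drain, overflow)
        st.theta[i] -= drain / cell
        inflow = drain
    percolation = inflow

    # capillary rise into the root zone, filling from the bottom up to FC
    n_root = max(1, int(round(p.rt_x / soil.dz)))
    deficit = float(np.clip(soil.swc_fc - st.theta[:n_root], 0.0, None).sum() * cell)
    cr = _capillary_rise_rate(st.water_table_depth, soil)
    cr = min(cr, deficit)
    water = cr
    for i in reversed(range(n_root)):
        if water <= 0:
            break
        room = max(0.0, (soil.swc_fc - st.theta[i]) * cell)
        add = min(water, room)
        st.theta[i] += add / cell
        water -= add
    cr -= water  # any unplaced remainder (deficit already capped; usually 0)

    # soil evaporation; infiltration rewets the evaporative layer first
    st.stage2_deficit = max(0.0, st.stage2_deficit - infil)
    e = soil_evaporation(et0, cc, phase, p, st, soil, cc_peak=cc_peak)
    st.theta[0] -= e / cell
    st.stage2_deficit += e

    tr = extract_transpiration(tr_demand, st, p, soil)

    fluxes = DailyFluxes(pr=pr, runoff=ro, infiltration=infil,
                         percolation=percolation, capillary_rise=cr,
                         e_soil=e, tr=tr)
    closure = (st.storage_mm(soil) - storage0) - (
        pr - ro - percolation + cr - e - tr
    )
    if abs(closure) > 1e-6:
        raise WaterBalanceError(f"daily water balance off by {closure:.3e} mm")
    return st, fluxes


def _capillary_rise_rate(depth: float, soil: SoilParams) -> float:
    if depth < 0:
        raise ValueError("water-table depth must be non-negative")
    if depth >= soil.cr_cutoff or not math.isfinite(depth):
        return 0.0
    return soil.cr_max * math.exp(-depth / soil.cr_zscale)
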