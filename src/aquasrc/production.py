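"""Water-driven production: transpiration, biomass, harvest index, yield.

Crop transpiration is the product of the water-stress coefficient, the
maximum crop transpiration coefficient, the canopy cover adjusted for
micro-advective effects, and the reference evapotranspiration.  Biomass
accumulates as the normalized water productivity times the cold-stress
weighted transpiration-to-ET0 ratio, summed over the season.  The
harvestable yield is biomass times a logistic harvest index that builds up
over the final part of the growing cycle.  For a woody coppice crop, B is
the total (above- plus belowground) biomass and HI is the woody aboveground
fraction (without leaves) of that total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .canopy import CropPhaseParams

__all__ = [
    "ProductionState",
    "cc_star",
    "transpiration",
    "accumulate_biomass",
    "derive_higc",
    "harvest_index",
    "harvestable_yield",
]

#: g m-2 -> Mg ha-1
G_M2_TO_MG_HA = 0.01


@dataclass
class ProductionState:
    """Cumulative production bookkeeping for one rotation year."""

    biomass: float = 0.0  # B, Mg ha-1
    hi: float = 0.0  # current harvest index, fraction
    days_since_hi_start: float = 0.0
    tr_over_et0_sum: float = 0.0  # cumulative sum of Ksb * Tr / ET0


def cc_star(cc: float) -> float:
    """Canopy cover adjusted for micro-advective effects.

    Cubic adjustment ``1.72*CC - CC^2 + 0.30*CC^3``; sparse canopies
    transpire more than their geometric cover suggests because of advection
    from the exposed soil, so CC* >= CC for CC in (0, 1).
    """
    if not 0.0 <= cc <= 1.0:
        raise ValueError("CC must lie in [0, 1]")
    return 1.72 * cc - cc ** 2 + 0.30 * cc ** 3


def transpiration(ks: float, kctrx: float, cc_star_value: float, et0: float) -> float:
    """Daily crop transpiration demand: Ks * KcTr,x * CC* * ET0 (mm)."""
    for name, v in (("ks", ks), ("kctrx", kctrx), ("cc_star", cc_star_value), ("et0", et0)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if ks > 1.0 or cc_star_value > 1.0:
        raise ValueError("ks and cc_star are bounded by 1")
    return ks * kctrx * cc_star_value * et0


def accumulate_biomass(
    state: ProductionState,
    tr: float,
    et0: float,
    wp: float,
    ksb: float = 1.0,
) -> ProductionState:
    """Add one day's biomass: dB = WP * Ksb * Tr/ET0 (g m-2, kept as Mg ha-1)."""
    if tr > 0 and et0 <= 0:
        raise ValueError("positive transpiration requires positive ET0")
    ratio = ksb * tr / et0 if et0 > 0 else 0.0
    return replace(
        state,
        biomass=state.biomass + wp * ratio * G_M2_TO_MG_HA,
        tr_over_et0_sum=state.tr_over_et0_sum + ratio,
    )


def derive_higc(p: CropPhaseParams, buildup_days: float) -> float:
    """HI growth coefficient (day-1) for a given build-up window length.

    Chosen so the logistic covers 98% of the (hi - hi_ini) span exactly at
    the end of the build-up window (the hi_length fraction of the cycle).
    """
    if p.higc is not None:
        return p.higc
    if buildup_days <= 0:
        raise ValueError("build-up window must be positive")
    target = p.hi_ini + 0.98 * (p.hi - p.hi_ini)
    x = (p.hi_ini * p.hi / target - p.hi_ini) / (p.hi - p.hi_ini)
    return -math.log(x) / buildup_days


def harvest_index(t: float, p: CropPhaseParams, higc: float | None = None) -> float:
    """Harvest index t days after the start of HI build-up.

    Logistic rise from hi_ini toward the final hi:
    ``HI(t) = hi_ini*hi / (hi_ini + (hi - hi_ini)*exp(-higc*t))``.
    """
    if t < 0:
        raise ValueError("time since HI build-up start must be non-negative")
    g = higc if higc is not None else p.higc
    if g is None or g <= 0:
        raise ValueError("a positive HI growth coefficient is required "
                         "(pass higc= or use derive_higc)")
    return p.hi_ini * p.hi / (p.hi_ini + (p.hi - p.hi_ini) * math.exp(-g * t))


def harvestable_yield(b: float, hi: float) -> float:
    """Yield Y = HI * B (Mg ha-1); the harvestable woody fraction of B."""
    if b < 0:
        raise ValueError("biomass must be non-negative")
    if not 0.0 <= hi <= 1.0:
        raise ValueError("harvest index must lie in [0, 1]")
    return hi * b
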