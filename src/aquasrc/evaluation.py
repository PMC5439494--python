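"""Model evaluation and uncertainty statistics.

Skill of daily simulations is scored with the root-mean-square error
normalized by the observed range (NRMSE, %) and the coefficient of
determination of the least-squares linear fit of observations on
simulations, with the overall regression F-test p-value.  Annual water-use
summaries aggregate the daily output into totals and partitioning ratios.
Calibration helpers recover canopy coefficients from observed canopy cover,
the maximum crop transpiration coefficient from mid-season ET/ET0, and the
water productivity from observed biomass.  The random measurement error of
daily eddy-covariance ET is estimated from paired consecutive days with
similar atmospheric demand, via the mean absolute deviation of the paired
differences in ten ET-magnitude groups and a logarithmic fit
RME(ET) = a*(ln(ET) + c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .canopy import CropPhaseParams, canopy_cover

__all__ = [
    "EvalStats",
    "RMEModel",
    "EBCFit",
    "CalibrationResult",
    "skill",
    "summarize_totals",
    "annual_summary",
    "yield_deviation",
    "estimate_kctrx",
    "calibrate_canopy",
    "calibrate_wp",
    "energy_balance_closure",
    "estimate_rme",
    "rme_at",
]


@dataclass(frozen=True)
class EvalStats:
    """Model-skill statistics for one observed/simulated series pair."""

    n: int
    r2: float  # coefficient of determination of obs ~ sim
    nrmse: float  # %, RMSE normalized by the observed range
    f_pvalue: float  # overall F-test of the obs ~ sim linear relation


@dataclass(frozen=True)
class RMEModel:
    """Fitted magnitude-dependent random error of daily ET.

    ``rme(ET) = a * (ln(ET) + c)`` mm, fitted through the per-group mean
    absolute deviations of paired-day ET differences.
    """

    a: float
    c: float
    threshold: float  # pair filter on |dET0|, mm
    retained_fraction: float
    n_pairs: int
    bin_et: np.ndarray = field(repr=False)  # median ET per group
    bin_mad: np.ndarray = field(repr=False)
    skewness: float = math.nan
    kurtosis: float = math.nan  # excess kurtosis of the paired differences
    degenerate: bool = False


@dataclass(frozen=True)
class EBCFit:
    """Energy-balance-closure regression of (H + LE) on (Rn - G)."""

    slope: float
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class CalibrationResult:
    params: CropPhaseParams
    fitted: dict[str, float]
    objective: float
    trace: tuple[float, ...]  # best objective so far, per multi-start


# ---------------------------------------------------------------------------
# skill statistics


def skill(obs, sim) -> EvalStats:
    """NRMSE, R2 and overall-F p-value for aligned daily series.

    Pairs with a missing value on either side are dropped; the observed
    range must be non-zero.
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError("observed and simulated series must be aligned")
    keep = np.isfinite(obs) & np.isfinite(sim)
    obs, sim = obs[keep], sim[keep]
    n = obs.size
    if n < 2:
        raise ValueError("at least 2 finite observation pairs required")
    rng = obs.max() - obs.min()
    if rng == 0:
        raise ValueError("observed series is constant; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    if np.ptp(sim) == 0:
        r2, pval = 0.0, 1.0
    else:
        fit = stats.linregress(sim, obs)
        r2, pval = float(fit.rvalue ** 2), float(fit.pvalue)
    return EvalStats(n=n, r2=r2, nrmse=100.0 * rmse / rng, f_pvalue=pval)


# ---------------------------------------------------------------------------
# annual aggregation


def summarize_totals(totals: pd.DataFrame) -> pd.DataFrame:
    """Partitioning ratios and the cross-year average from yearly totals.

    ``totals`` has one row per year with (a subset of) columns ``pr_tot``,
    ``et0_tot``, ``et_tot``, ``tr_tot``, ``e_soil_tot``, ``et_daily_mean``,
    ``et_daily_max``, ``b``, ``y``.  Adds the ratios ``et_over_et0``,
    ``tr_over_et``, ``e_soil_over_et`` where the components are present and
    appends an ``Average`` row.  Values stay at full precision; round only
    for presentation.
    """
    out = totals.copy()
    if {"et_tot", "et0_tot"} <= set(out.columns):
        out["et_over_et0"] = out["et_tot"] / out["et0_tot"]
    if {"tr_tot", "et_tot"} <= set(out.columns):
        out["tr_over_et"] = out["tr_tot"] / out["et_tot"]
    if {"e_soil_tot", "et_tot"} <= set(out.columns):
        out["e_soil_over_et"] = out["e_soil_tot"] / out["et_tot"]
    avg = out.drop(columns=[c for c in out.columns if c == "year"]).mean(numeric_only=True)
    avg_row = {c: avg.get(c, np.nan) for c in out.columns}
    if "year" in out.columns:
        avg_row["year"] = "Average"
    out = pd.concat([out, pd.DataFrame([avg_row])], ignore_index=True)
    return out


def annual_summary(daily: pd.DataFrame, allow_partial: bool = False) -> pd.DataFrame:
    """Yearly totals, daily ET mean/max, partitioning ratios, B and Y.

    ``daily`` is the simulation output table.  Each calendar year must be
    complete (365/366 days) unless ``allow_partial``.
    """
    df = daily.copy()
    years = pd.to_datetime(df["date"]).dt.year
    rows = []
    for year, sub in df.groupby(years):
        n_days = 366 if _is_leap(int(year)) else 365
        if len(sub) != n_days and not allow_partial:
            raise ValueError(f"year {year} has {len(sub)} days; partial years "
                             "need allow_partial=True")
        row = {
            "year": int(year),
            "pr_tot": float(sub["pr"].sum()),
            "et0_tot": float(sub["et0"].sum()),
            "e_soil_tot": float(sub["e_soil"].sum()),
            "tr_tot": float(sub["tr"].sum()),
            "et_tot": float(sub["et"].sum()),
            "et_daily_mean": float(sub["et"].mean()),
            "et_daily_max": float(sub["et"].max()),
            "b": float(sub["b"].iloc[-1]),
            "y": float(sub["y"].iloc[-1]),
        }
        rows.append(row)
    return summarize_totals(pd.DataFrame(rows))


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def yield_deviation(obs_y: float, sim_y: float) -> tuple[float, float]:
    """(sim - obs, 100*(sim - obs)/obs); negative means underestimation."""
    if obs_y <= 0:
        raise ValueError("observed yield must be positive")
    dev = sim_y - obs_y
    return dev, 100.0 * dev / obs_y


# ---------------------------------------------------------------------------
# calibration helpers


def estimate_kctrx(
    et, et0, lai,
    lai_window: tuple[float, float] = (3.5, 5.0),
    confidence: float = 0.90,
) -> tuple[float, tuple[float, float]]:
    """Maximum crop transpiration coefficient from mid-season ET/ET0.

    Selects days whose LAI lies inside ``lai_window`` (full canopy, when ET
    is almost entirely transpiration), and returns the mean ET/ET0 ratio
    with its two-sided t-based confidence interval.
    """
    et = np.asarray(et, dtype=float)
    et0 = np.asarray(et0, dtype=float)
    lai = np.asarray(lai, dtype=float)
    mask = (lai >= lai_window[0]) & (lai <= lai_window[1]) & (et0 > 0) \
        & np.isfinite(et) & np.isfinite(et0)
    if mask.sum() < 2:
        raise ValueError("need at least 2 days with LAI inside the window")
    ratios = et[mask] / et0[mask]
    mean = float(ratios.mean())
    sem = float(stats.sem(ratios))
    if sem == 0:
        return mean, (mean, mean)
    lo, hi = stats.t.interval(confidence, ratios.size - 1, loc=mean, scale=sem)
    return mean, (float(lo), float(hi))


def calibrate_canopy(
    obs_gdd,
    obs_cc,
    p: CropPhaseParams,
    free: tuple[str, ...] = ("cgc", "cdc"),
    bounds: dict[str, tuple[float, float]] | None = None,
    start_factors: tuple[float, ...] = (0.5, 1.0, 2.0),
) -> CalibrationResult:
    """Least-squares fit of canopy coefficients to observed canopy cover.

    ``obs_gdd`` are thermal times since planting/resprouting at which
    ``obs_cc`` (fractions) were observed.  The fit is a deterministic
    multi-start trust-region least squares over the free parameters; the
    trace records the best objective after each start and is non-increasing
    by construction.
    """
    obs_gdd = np.asarray(obs_gdd, dtype=float)
    obs_cc = np.asarray(obs_cc, dtype=float)
    if obs_gdd.size != obs_cc.size or obs_gdd.size < len(free):
        raise ValueError("need at least as many CC observations as free parameters")
    default_bounds = {"cgc": (1e-4, 0.05), "cdc": (1e-4, 0.05),
                      "ccx": (0.2, 1.0), "cc0": (1e-3, 0.2)}
    bnds = {**default_bounds, **(bounds or {})}

    def residuals(x: np.ndarray) -> np.ndarray:
        cand = _dc_replace(p, **dict(zip(free, x)))
        return np.array([canopy_cover(g, cand) for g in obs_gdd]) - obs_cc

    x0 = np.array([getattr(p, name) for name in free], dtype=float)
    lo = np.array([bnds[name][0] for name in free])
    hi = np.array([bnds[name][1] for name in free])
    best, trace = None, []
    for f in start_factors:
        start = np.clip(x0 * f, lo, hi)
        sol = optimize.least_squares(residuals, start, bounds=(lo, hi), method="trf")
        cost = float(sol.cost)
        if best is None or cost < best[0]:
            best = (cost, sol.x)
        trace.append(best[0])
    if best is None or not np.all(np.isfinite(best[1])):
        raise RuntimeError(f"canopy calibration failed; objective trace {trace}")
    fitted = dict(zip(free, (float(v) for v in best[1])))
    return CalibrationResult(params=_dc_replace(p, **fitted), fitted=fitted,
                             objective=best[0], trace=tuple(trace))


def calibrate_wp(target_b: float, tr_over_et0_sum: float, ksb: float = 1.0) -> float:
    """Water productivity (g m-2) matching an observed seasonal biomass.

    Biomass is linear in WP, so the fit is exact:
    ``WP = B / (0.01 * sum(Ksb * Tr/ET0))`` with B in Mg ha-1.
    """
    if tr_over_et0_sum <= 0:
        raise ValueError("cumulative Tr/ET0 must be positive")
    if target_b < 0:
        raise ValueError("target biomass must be non-negative")
    return target_b / (0.01 * tr_over_et0_sum)


# ---------------------------------------------------------------------------
# uncertainty of eddy-covariance ET


def energy_balance_closure(h, le, rn, g) -> EBCFit:
    """Ordinary least squares of the turbulent fluxes (H + LE) on the
    available energy (Rn - G)."""
    h = np.asarray(h, float)
    le = np.asarray(le, float)
    rn = np.asarray(rn, float)
    g = np.asarray(g, float)
    y = h + le
    x = rn - g
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("energy-balance closure needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("available energy has no variance")
    fit = stats.linregress(x, y)
    return EBCFit(slope=float(fit.slope), intercept=float(fit.intercept),
                  r2=float(fit.rvalue ** 2), n=int(x.size))


def estimate_rme(
    et,
    et0,
    threshold: float = 0.6,
    n_bins: int = 10,
) -> RMEModel:
    """Random measurement error of daily ET from paired consecutive days.

    Pairs of consecutive days whose reference-demand difference |dET0|
    exceeds ``threshold`` (mm) are discarded: the retained pairs experienced
    near-identical atmospheric demand, so their ET difference reflects
    measurement noise.  The retained pairs are sorted by ET magnitude (pair
    mean) into ``n_bins`` equal-size groups (earlier groups take the
    extras); per group the mean absolute deviation (MAD) of the ET
    differences is the error estimate, robust against the heavy-tailed
    (Laplace) difference distribution.  A logarithmic model
    ``MAD = a*(ln(ET) + c)`` is fitted through the group medians.
    """
    et = np.asarray(et, dtype=float)
    et0 = np.asarray(et0, dtype=float)
    if et.shape != et0.shape:
        raise ValueError("et and et0 must be aligned")
    if et.size < 41:
        raise ValueError("need at least 40 consecutive-day pairs")
    d_et0 = np.abs(np.diff(et0))
    keep = d_et0 <= threshold
    diffs = np.diff(et)[keep]
    mags = ((et[:-1] + et[1:]) / 2.0)[keep]
    n_pairs = int(keep.sum())
    if n_pairs < n_bins:
        raise ValueError(
            f"only {n_pairs} pairs retained after the |dET0| <= {threshold} mm "
            f"filter; at least {n_bins} required"
        )
    order = np.argsort(mags, kind="stable")
    groups = np.array_split(order, n_bins)
    bin_et = np.array([float(np.median(mags[g])) for g in groups])
    bin_mad = np.array([float(np.mean(np.abs(diffs[g] - diffs[g].mean()))) for g in groups])

    degenerate = False
    if np.ptp(bin_et) == 0 or np.all(bin_mad == 0):
        a = c = math.nan
        degenerate = True
    else:
        fit = stats.linregress(np.log(bin_et), bin_mad)
        a = float(fit.slope)
        if a <= 0 or not math.isfinite(a):
            degenerate = True
            c = math.nan
        else:
            c = float(fit.intercept) / a
    return RMEModel(
        a=a, c=c, threshold=threshold,
        retained_fraction=n_pairs / d_et0.size, n_pairs=n_pairs,
        bin_et=bin_et, bin_mad=bin_mad,
        skewness=float(stats.skew(diffs)),
        kurtosis=float(stats.kurtosis(diffs)),
        degenerate=degenerate,
    )


def rme_at(et: float, model: RMEModel) -> float:
    """Random measurement error (mm) for a daily ET value."""
    if et <= 0:
        raise ValueError("ET must be positive")
    if model.degenerate:
        raise ValueError("cannot evaluate a degenerate RME model")
    return max(0.0, model.a * (math.log(et) + model.c))
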