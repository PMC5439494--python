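"""Synthetic forcing and pseudo-observations for a temperate maritime site.

The generators emulate the study conditions of a lowland poplar
short-rotation coppice in a temperate maritime climate: around 800 mm of
annual precipitation spread uniformly over the year, annual reference
evapotranspiration in the 550-900 mm range, a mild seasonal temperature
cycle (winter means near 3 degC, summer near 18 degC), and a shallow water
table that is high in winter and drops to 1.4-1.7 m in late summer
(U-shaped daily depth curves).

Pseudo-observations are drawn around a known-truth simulation: daily ET
carries Laplace (double-exponential) noise whose scale follows the
magnitude-dependent random-error law a*(ln ET + c) of eddy-covariance ET;
soil water content and canopy cover carry Gaussian noise; synthetic energy
fluxes close the energy balance at a configurable fraction.  Every
generator is a pure function of its configuration (including the seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canopy import CropPhaseParams, RotationSchedule, RotationYear
from .forcing import SiteConfig, extraterrestrial_radiation
from .simulate import SimOutput, run_simulation
from .soil_water import SoilParams

__all__ = [
    "SynthConfig",
    "default_site",
    "default_soil",
    "default_schedule",
    "gen_weather",
    "gen_water_table",
    "gen_observations",
    "gen_rme_pairs",
    "truth_run",
]

#: latent heat of vaporization, MJ per mm of evaporated water
_LAMBDA = 2.45
#: MJ m-2 day-1 -> W m-2 (daily mean)
_MJDAY_TO_W = 11.574


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic campaign (all randomness from ``seed``)."""

    seed: int = 0
    years: int = 4
    start_year: int = 2012
    latitude: float = 51.1
    elevation: float = 6.25
    # precipitation: Bernoulli occurrence x exponential amounts
    annual_pr: float = 820.0  # mm, target annual total
    wet_day_prob: float = 0.5
    # temperature seasonal cycle + AR(1) noise
    t_mean: float = 10.5  # degC, annual mean
    t_amp: float = 7.5  # degC, seasonal amplitude (winter ~3, summer ~18)
    t_phase_doy: float = 15.0  # coldest day of year
    diurnal_range: float = 8.0  # degC, tmax - tmin
    ar_rho: float = 0.7
    ar_sigma: float = 2.2  # degC, innovations of the AR(1) anomaly
    # water table seasonal U-shape
    wt_winter: float = 0.35  # m, winter depth
    wt_summer_drop: float = 1.1  # m, extra depth at the late-summer peak
    wt_peak_doy: float = 235.0
    wt_peak_width: float = 55.0  # days
    wt_sigma: float = 0.04  # m, smooth noise
    # observation noise
    rme_a: float = 0.0609  # mm, ET random-error law a*(ln ET + c)
    rme_c: float = 0.209
    et_min_scale: float = 0.01  # mm, floor of the Laplace scale
    swc_sigma: float = 0.02  # m3 m-3
    cc_sigma: float = 0.02  # cover fraction
    cc_obs_per_season: int = 12
    b_rel_sigma: float = 0.05  # relative noise on annual biomass
    closure_fraction: float = 0.72  # energy-balance closure of synthetic fluxes
    closure_noise: float = 5.0  # W m-2 on the turbulent fluxes

    def __post_init__(self) -> None:
        for name in ("annual_pr", "wet_day_prob", "diurnal_range", "ar_sigma",
                     "et_min_scale", "swc_sigma", "cc_sigma", "b_rel_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.closure_fraction <= 1:
            raise ValueError("closure fraction must lie in (0, 1]")


def default_site(cfg: SynthConfig | None = None) -> SiteConfig:
    cfg = cfg or SynthConfig()
    return SiteConfig(latitude=cfg.latitude, elevation=cfg.elevation)


def default_soil() -> SoilParams:
    """Loamy-sand profile with a shallow water table (values as calibrated)."""
    return SoilParams(swc_fc=0.22, swc_pwp=0.10, swc_sat=0.41, ksat=1200.0, cn=46.0)


#: parameter set of a coppice year (stems regrow from the cut stump: later
#: emergence, slower canopy growth, lower water productivity)
COPPICE_YEAR_PARAMS = CropPhaseParams(
    cc0=0.04, ccx=0.96, cgc=0.003131, cdc=0.004375,
    eme=0.0, root=1683.0, sen=2482.0, mat=3151.0,
    kctrx=0.99, wp=10.4, hi=0.68, hi_ini=0.0001, hi_length=0.5,
    mulch_pre=63.0, mulch_grow=21.0, mulch_post=81.0, evardc=70.0,
)

#: parameter set of a resprout year (standing stools: earlier start, faster
#: canopy closure, higher water productivity, more mulch on the ground)
RESPROUT_YEAR_PARAMS = CropPhaseParams(
    cc0=0.06, ccx=0.96, cgc=0.004525, cdc=0.002302,
    eme=0.0, root=1385.0, sen=1961.0, mat=3236.0,
    kctrx=0.99, wp=14.0, hi=0.68, hi_ini=0.0001, hi_length=0.5,
    mulch_pre=81.0, mulch_grow=86.0, mulch_post=81.0, evardc=70.0,
)


def default_schedule(cfg: SynthConfig | None = None) -> RotationSchedule:
    """Two 2-year rotations with a winter coppice between them.

    Coppice years emerge in early April; resprout years start 18 calendar
    days earlier in the season.
    """
    cfg = cfg or SynthConfig()
    years = []
    for i in range(cfg.years):
        year = cfg.start_year + i
        rotation = 2 + i // 2
        within = i % 2 + 1
        label = f"R{rotation}.{within}"
        if within == 1:
            emergence = _dt.date(year, 4, 6)
            params, coppice = COPPICE_YEAR_PARAMS, True
        else:
            emergence = _dt.date(year, 4, 6) - _dt.timedelta(days=18)
            params, coppice = RESPROUT_YEAR_PARAMS, False
        years.append(RotationYear(label=label, emergence=emergence,
                                  params=params, coppice=coppice))
    return RotationSchedule(years=years)


# ---------------------------------------------------------------------------
# forcing generators


def _dates(cfg: SynthConfig) -> pd.DatetimeIndex:
    start = _dt.date(cfg.start_year, 1, 1)
    end = _dt.date(cfg.start_year + cfg.years - 1, 12, 31)
    return pd.date_range(start, end, freq="D")


def gen_weather(cfg: SynthConfig) -> pd.DataFrame:
    """Generate a daily weather table for the configured campaign."""
    rng = np.random.default_rng(cfg.seed)
    idx = _dates(cfg)
    doy = idx.dayofyear.to_numpy(dtype=float)
    n = len(idx)

    # temperature: seasonal cosine + AR(1) anomaly shared by tmin/tmax
    seasonal = cfg.t_mean - cfg.t_amp * np.cos(
        2.0 * np.pi * (doy - cfg.t_phase_doy) / 365.25)
    anom = np.empty(n)
    anom[0] = rng.normal(0.0, cfg.ar_sigma)
    innov = rng.normal(0.0, cfg.ar_sigma * np.sqrt(1 - cfg.ar_rho ** 2), n)
    for i in range(1, n):
        anom[i] = cfg.ar_rho * anom[i - 1] + innov[i]
    tmean = seasonal + anom
    half_range = cfg.diurnal_range / 2.0 + rng.normal(0.0, 0.5, n)
    half_range = np.clip(half_range, 1.0, None)
    tmin, tmax = tmean - half_range, tmean + half_range

    # precipitation: Bernoulli occurrence x exponential amounts.  Each
    # year's total is regulated toward the annual target (+- a few %), the
    # interannual variability the emulated maritime climate actually shows;
    # a free sum of exponential day amounts would scatter three times wider.
    wet = rng.random(n) < cfg.wet_day_prob
    mean_amount = cfg.annual_pr / (365.25 * cfg.wet_day_prob)
    pr = np.where(wet, rng.exponential(mean_amount, n), 0.0)
    years_arr = idx.year.to_numpy()
    for yr in np.unique(years_arr):
        sel = years_arr == yr
        total = pr[sel].sum()
        if total > 0:
            target = cfg.annual_pr * (1.0 + rng.normal(0.0, 0.035))
            pr[sel] *= target / total

    # radiation: clear-sky envelope x cloudiness tied to rain occurrence
    ra = extraterrestrial_radiation(cfg.latitude, doy)
    rso = 0.75 * ra
    cloud = np.where(wet, rng.normal(0.35, 0.10, n), rng.normal(0.62, 0.15, n))
    rs = rso * np.clip(cloud, 0.08, 1.0)

    # humidity: moister on rain days
    rhmax = np.clip(rng.normal(94.0, 3.0, n), 70.0, 100.0)
    rhmin = np.where(wet, rng.normal(68.0, 8.0, n), rng.normal(52.0, 8.0, n))
    rhmin = np.clip(rhmin, 20.0, rhmax)

    u2 = np.clip(rng.normal(2.2, 0.8, n), 0.3, None)

    return pd.DataFrame({
        "date": idx.date, "tmin": tmin, "tmax": tmax,
        "rhmin": rhmin, "rhmax": rhmax, "rs": rs, "u2": u2, "pr": pr,
    })


def gen_water_table(cfg: SynthConfig) -> pd.DataFrame:
    """Daily water-table depth: shallow in winter, deepest in late summer."""
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    idx = _dates(cfg)
    doy = idx.dayofyear.to_numpy(dtype=float)
    n = len(idx)
    bump = np.exp(-(((doy - cfg.wt_peak_doy) / cfg.wt_peak_width) ** 2))
    depth = cfg.wt_winter + cfg.wt_summer_drop * bump
    # smooth noise: AR(1) with long memory so the daily curve stays plausible
    noise = np.empty(n)
    noise[0] = 0.0
    innov = rng.normal(0.0, cfg.wt_sigma * np.sqrt(1 - 0.95 ** 2), n)
    for i in range(1, n):
        noise[i] = 0.95 * noise[i - 1] + innov[i]
    depth = np.clip(depth + noise, 0.05, None)
    return pd.DataFrame({"date": idx.date, "depth": depth})


# ---------------------------------------------------------------------------
# truth run and pseudo-observations


def truth_run(
    schedule: RotationSchedule,
    soil: SoilParams,
    weather: pd.DataFrame,
    site: SiteConfig,
    water_table: pd.DataFrame | None = None,
) -> SimOutput:
    """Deterministic full-pipeline run used as ground truth."""
    return run_simulation(weather, site, schedule, soil, water_table=water_table)


def gen_observations(truth: SimOutput, cfg: SynthConfig) -> dict[str, pd.DataFrame]:
    """Noisy pseudo-observations around a known-truth simulation.

    Returns a dict with:

    ``et``
        Daily table (date, et_obs): truth ET plus Laplace noise whose scale
        follows ``rme_a*(ln ET + rme_c)`` (floored at ``et_min_scale``).
    ``swc``
        Daily table (date, swc_obs): 0-0.3 m soil water content plus
        Gaussian noise.
    ``cc``
        Sparse canopy-cover survey, about ``cc_obs_per_season`` dates per
        growing season, Gaussian noise, clipped to [0, 1].
    ``biomass``
        Per rotation year (label, b_obs): end-of-season biomass with
        relative Gaussian noise (allometric-type uncertainty).
    ``flux``
        Daily synthetic energy fluxes (h, le, rn, g, W m-2) built so the
        turbulent fluxes close the available energy at ``closure_fraction``
        and LE is consistent with the observed ET.
    """
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    daily = truth.daily
    dates = daily["date"].to_numpy()
    et_true = daily["et"].to_numpy(dtype=float)

    scale = np.maximum(cfg.et_min_scale,
                       cfg.rme_a * (np.log(np.maximum(et_true, 0.1)) + cfg.rme_c))
    et_obs = et_true + rng.laplace(0.0, scale)
    et_obs = np.maximum(et_obs, 0.0)

    swc_obs = daily["swc_030"].to_numpy(dtype=float) + rng.normal(0.0, cfg.swc_sigma, len(daily))
    swc_obs = np.clip(swc_obs, 0.005, 0.6)

    cc_rows = []
    for label, sub in daily[daily["phase"] == "growing"].groupby("label", sort=False):
        n_obs = min(cfg.cc_obs_per_season, len(sub))
        picks = np.linspace(5, len(sub) - 1, n_obs).round().astype(int)
        sel = sub.iloc[picks]
        noisy = np.clip(sel["cc"].to_numpy() + rng.normal(0.0, cfg.cc_sigma, n_obs), 0.0, 1.0)
        for d, g, v in zip(sel["date"], sel["cum_gdd"], noisy):
            cc_rows.append({"date": d, "label": label, "cum_gdd": g, "cc_obs": v})

    b_rows = [
        {"label": r["label"],
         "b_obs": float(r["b"] * (1.0 + rng.normal(0.0, cfg.b_rel_sigma)))}
        for _, r in truth.per_year.iterrows()
    ]

    # energy fluxes: LE consistent with the observed ET; net radiation
    # reconstructed from the reference demand (Rn ~ 1.6x ET0 equivalent)
    le = et_obs * _LAMBDA * _MJDAY_TO_W
    rn = np.maximum(daily["et0"].to_numpy(dtype=float), 0.2) * 1.6 * _LAMBDA * _MJDAY_TO_W
    g = 0.05 * rn
    avail = rn - g
    h = cfg.closure_fraction * avail - le + rng.normal(0.0, cfg.closure_noise, len(daily))

    return {
        "et": pd.DataFrame({"date": dates, "et_obs": et_obs}),
        "swc": pd.DataFrame({"date": dates, "swc_obs": swc_obs}),
        "cc": pd.DataFrame(cc_rows),
        "biomass": pd.DataFrame(b_rows),
        "flux": pd.DataFrame({"date": dates, "h": h, "le": le, "rn": rn, "g": g}),
    }


def gen_rme_pairs(cfg: SynthConfig, n_days: int = 1095) -> pd.DataFrame:
    """Paired-day ET series for the random-error estimator round trip.

    Emulates the sampling design the paired-day error estimator assumes:
    consecutive days come in pairs with identical true ET and identical
    reference demand (so the pair passes the |dET0| filter), while demand
    jumps between pairs (so cross-pair differences are filtered out).  Each
    day's measured ET carries Laplace noise; the per-day scale is set so the
    mean absolute deviation of the within-pair differences follows
    ``rme_a*(ln ET + rme_c)``, the law being emulated (the difference of two
    independent Laplace variables has a mean absolute deviation of 1.5 times
    the per-day scale).
    """
    rng = np.random.default_rng(cfg.seed + 3_000_003)
    n_pairs = (n_days + 1) // 2
    # sample ET levels over the domain where the error law is positive
    # (below ~exp(-c) mm the logarithmic law has no meaning)
    lo = float(np.exp(-cfg.rme_c)) + 0.4
    levels = rng.uniform(lo, 6.5, n_pairs)
    et_true = np.repeat(levels, 2)[:n_days]
    et0 = np.repeat(np.where(np.arange(n_pairs) % 2 == 0, 3.0, 6.0), 2)[:n_days]
    scale = np.maximum(cfg.et_min_scale,
                       cfg.rme_a * (np.log(et_true) + cfg.rme_c)) / 1.5
    et_obs = np.maximum(et_true + rng.laplace(0.0, scale), 0.0)
    start = _dt.date(cfg.start_year, 1, 1)
    dates = [start + _dt.timedelta(days=i) for i in range(n_days)]
    return pd.DataFrame({"date": dates, "et": et_obs, "et0": et0})
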