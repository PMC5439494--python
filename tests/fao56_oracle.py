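"""Independent scalar implementation of the FAO-56 daily Penman-Monteith
reference evapotranspiration, coded step by step from the published
worked procedure (psychrometrics, vapour pressures, extraterrestrial and
net radiation, aerodynamic term).  Used only as a cross-check oracle in
tests; intentionally written without reference to the package internals.
"""

import math


def saturation_vp(temp_c):
    return 0.6108 * math.exp(17.27 * temp_c / (temp_c + 237.3))


def reference_et_daily(tmin, tmax, rhmin, rhmax, rs_mj, wind2m, lat_deg, elev_m, day_of_year):
    tmean = 0.5 * (tmin + tmax)

    # slope of the saturation vapour pressure curve, kPa/degC
    slope = 4098.0 * saturation_vp(tmean) / (tmean + 237.3) ** 2

    # atmospheric pressure and psychrometric constant
    pressure = 101.3 * math.pow((293.0 - 0.0065 * elev_m) / 293.0, 5.26)
    psychro = 0.000665 * pressure

    # vapour pressures from the daily temperature and humidity extremes
    es = 0.5 * (saturation_vp(tmax) + saturation_vp(tmin))
    ea = 0.5 * (saturation_vp(tmin) * rhmax / 100.0 + saturation_vp(tmax) * rhmin / 100.0)
    if ea > es:
        ea = es

    # extraterrestrial radiation
    lat = math.pi * lat_deg / 180.0
    inv_dist = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    decl = 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)
    x = -math.tan(lat) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    sunset = math.acos(x)
    ra = (1440.0 / math.pi) * 0.0820 * inv_dist * (
        sunset * math.sin(lat) * math.sin(decl)
        + math.cos(lat) * math.cos(decl) * math.sin(sunset)
    )
    if ra < 0.0:
        ra = 0.0

    # net radiation: shortwave minus longwave against the clear-sky envelope
    rso = (0.75 + 2e-5 * elev_m) * ra
    ratio = 1.0 if rso <= 0.0 else min(1.0, max(0.0, rs_mj / rso))
    shortwave_net = 0.77 * rs_mj
    boltz = 4.903e-9
    tk4 = 0.5 * ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4)
    cloud_fn = 1.35 * ratio - 0.35
    if cloud_fn < 0.0:
        cloud_fn = 0.0
    longwave_net = boltz * tk4 * (0.34 - 0.14 * math.sqrt(ea)) * cloud_fn
    rnet = shortwave_net - longwave_net

    # combination equation with G = 0 at the daily step
    radiation_term = 0.408 * slope * rnet
    aero_term = psychro * (900.0 / (tmean + 273.0)) * wind2m * (es - ea)
    et0 = (radiation_term + aero_term) / (slope + psychro * (1.0 + 0.34 * wind2m))
    return max(0.0, et0)
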