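"""Weather I/O, reference evapotranspiration and thermal-time tests."""

import datetime as dt
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquasrc import forcing
from aquasrc.canopy import RotationSchedule, RotationYear
from aquasrc.forcing import (
    SchemaError,
    SequencingError,
    SiteConfig,
    ThermalTime,
    WeatherDay,
    compute_et0,
    compute_gdd,
    load_weather,
    season_calendar,
)

from fao56_oracle import reference_et_daily


def _write_weather(tmp_path, rows, header="date,tmin,tmax,rhmin,rhmax,rs,u2,pr"):
    path = tmp_path / "weather.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def _row(date, **kw):
    vals = {"tmin": 5.0, "tmax": 15.0, "rhmin": 50.0, "rhmax": 90.0,
            "rs": 12.0, "u2": 2.0, "pr": 0.0}
    vals.update(kw)
    return f"{date},{vals['tmin']},{vals['tmax']},{vals['rhmin']},{vals['rhmax']},{vals['rs']},{vals['u2']},{vals['pr']}"


class TestLoadWeather:
    def test_well_formed_year_loads_fully(self, tmp_path):
        start = dt.date(2012, 1, 1)
        rows = [_row((start + dt.timedelta(days=i)).isoformat()) for i in range(365)]
        df = load_weather(_write_weather(tmp_path, rows))
        assert len(df) == 365
        assert list(df.columns) == list(forcing.WEATHER_COLUMNS)

    def test_skipped_date_names_the_gap(self, tmp_path):
        rows = [_row("2012-01-01"), _row("2012-01-02"), _row("2012-01-04")]
        with pytest.raises(SequencingError, match="2012-01-02.*2012-01-04"):
            load_weather(_write_weather(tmp_path, rows))

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("date,tmin,tmax,rhmin,rhmax,rs,u2\n"
                        "2012-01-01,5,15,50,90,12,2\n")
        with pytest.raises(SchemaError, match="pr"):
            load_weather(path)

    def test_schema_mapping_renames_columns(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("day,tn,tx,rhn,rhx,srad,wind,rain\n"
                        "2012-01-01,5,15,50,90,12,2,0\n"
                        "2012-01-02,5,15,50,90,12,2,0\n")
        df = load_weather(path, schema={"date": "day", "tmin": "tn", "tmax": "tx",
                                        "rhmin": "rhn", "rhmax": "rhx",
                                        "rs": "srad", "u2": "wind", "pr": "rain"})
        assert len(df) == 2

    def test_missing_values_error_unless_interpolated(self, tmp_path):
        rows = [_row("2012-01-01"), _row("2012-01-02").replace("12.0", "", 1),
                _row("2012-01-03")]
        path = _write_weather(tmp_path, rows)
        with pytest.raises(ValueError, match="missing"):
            load_weather(path)
        df = load_weather(path, interpolate_gaps=True)
        assert df["rs"].notna().all()


class TestET0:
    def test_matches_independent_oracle_on_random_days(self, site, rng):
        """FAO-56 daily ET0 agrees with an independently coded oracle to 0.01 mm."""
        worst = 0.0
        for _ in range(1000):
            tmin = rng.uniform(-10, 25)
            tmax = tmin + rng.uniform(0, 15)
            rhmin = rng.uniform(20, 80)
            rhmax = rng.uniform(rhmin, 100)
            rs = rng.uniform(0, 30)
            u2 = rng.uniform(0, 8)
            doy = int(rng.integers(1, 366))
            lat = rng.uniform(-65, 65)
            elev = rng.uniform(0, 1500)
            day = WeatherDay(dt.date(2013, 1, 1), tmin, tmax, rhmin, rhmax, rs, u2, 0.0)
            ours = compute_et0(day, SiteConfig(latitude=lat, elevation=elev), doy)
            ref = reference_et_daily(tmin, tmax, rhmin, rhmax, rs, u2, lat, elev, doy)
            worst = max(worst, abs(ours - ref))
        assert worst <= 0.01

    def test_belgian_midsummer_day(self, site):
        day = WeatherDay(dt.date(2013, 7, 15), 12.0, 22.0, 55.0, 95.0, 20.0, 2.0, 0.0)
        ours = compute_et0(day, site, 196)
        ref = reference_et_daily(12.0, 22.0, 55.0, 95.0, 20.0, 2.0,
                                 site.latitude, site.elevation, 196)
        assert ours == pytest.approx(ref, abs=0.01)
        assert 2.0 < ours < 6.0  # plausible temperate midsummer demand

    def test_degenerate_day_is_nonnegative(self, site):
        day = WeatherDay(dt.date(2013, 1, 5), 2.0, 2.0, 100.0, 100.0, 0.0, 0.0, 0.0)
        assert compute_et0(day, site, 5) >= 0.0

    def test_wind_increases_demand_under_vpd(self, site):
        base = WeatherDay(dt.date(2013, 7, 15), 15.0, 30.0, 20.0, 50.0, 25.0, 2.0, 0.0)
        windy = WeatherDay(dt.date(2013, 7, 15), 15.0, 30.0, 20.0, 50.0, 25.0, 4.0, 0.0)
        assert compute_et0(windy, site, 196) > compute_et0(base, site, 196)

    @settings(max_examples=200, deadline=None)
    @given(
        tmin=st.floats(-20, 30), dt_range=st.floats(0, 20),
        rhmin=st.floats(0, 100), drh=st.floats(0, 100),
        rs=st.floats(0, 35), u2=st.floats(0, 12),
        doy=st.integers(1, 366), lat=st.floats(-80, 80),
    )
    def test_et0_never_negative(self, tmin, dt_range, rhmin, drh, rs, u2, doy, lat):
        rhmax = min(100.0, rhmin + drh)
        rhmin = min(rhmin, rhmax)
        day = WeatherDay(dt.date(2013, 1, 1), tmin, tmin + dt_range,
                         rhmin, rhmax, rs, u2, 0.0)
        assert compute_et0(day, SiteConfig(latitude=lat), doy) >= 0.0


class TestGDD:
    @pytest.mark.parametrize(
        "tmin,tmax,expected",
        [(6.0, 14.0, 10.0),    # plain mean above base
         (24.0, 30.0, 25.0),   # clamped at the upper optimum
         (-8.0, -2.0, 0.0),    # floored at the base temperature
         (0.0, 0.0, 0.0)],
    )
    def test_daily_gdd_cases(self, tmin, tmax, expected):
        assert compute_gdd(tmin, tmax, tb=0.0, tu=25.0) == pytest.approx(expected)

    def test_accumulator_is_nondecreasing(self, rng):
        tt = ThermalTime(tb=0.0, tu=25.0)
        prev = 0.0
        for _ in range(200):
            tmin = rng.uniform(-15, 20)
            tt.add_day(tmin, tmin + rng.uniform(0, 12))
            assert tt.cumulative >= prev
            assert tt.cumulative - prev <= tt.tu - tt.tb
            prev = tt.cumulative

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            compute_gdd(10.0, 5.0)
        with pytest.raises(ValueError):
            ThermalTime(tb=25.0, tu=25.0)


def _constant_weather(start, days, tmin=5.0, tmax=15.0):
    dates = [start + dt.timedelta(days=i) for i in range(days)]
    return pd.DataFrame({
        "date": dates, "tmin": tmin, "tmax": tmax, "rhmin": 50.0,
        "rhmax": 90.0, "rs": 12.0, "u2": 2.0, "pr": 0.0,
    })


class TestSeasonCalendar:
    def test_constant_forcing_maturity_date(self, coppice_params):
        """At 10 GDD/day, 3151 GDD to maturity takes 316 days from emergence."""
        weather = _constant_weather(dt.date(2012, 1, 1), 366)
        year = RotationYear("R2.1", dt.date(2012, 1, 10), coppice_params)
        (win,) = season_calendar(RotationSchedule(years=[year]), weather)
        mat = win.milestones_date["mat"]
        assert (mat - win.emergence).days + 1 == 316

    def test_senescence_after_maturity_rejected(self, coppice_params):
        import dataclasses
        with pytest.raises(ValueError):
            dataclasses.replace(coppice_params, sen=3200.0, mat=3151.0)

    def test_resprout_year_starts_earlier_in_season(self, campaign):
        """Resprout years emerge 18 calendar days earlier than coppice years."""
        windows = {w.label: w for w in
                   season_calendar(campaign["schedule"], campaign["weather"])}
        for coppice, resprout in (("R2.1", "R2.2"), ("R3.1", "R3.2")):
            e1 = windows[coppice].emergence
            e2 = windows[resprout].emergence
            same_year_anchor = dt.date(e2.year, e1.month, e1.day)
            assert (same_year_anchor - e2).days == 18
            # windows are disjoint in time
            assert windows[coppice].end < e2

    def test_truncated_season_warns(self, coppice_params):
        weather = _constant_weather(dt.date(2012, 1, 1), 200)  # far short of Mat
        year = RotationYear("R2.1", dt.date(2012, 1, 10), coppice_params)
        with pytest.warns(UserWarning, match="mat"):
            (win,) = season_calendar(RotationSchedule(years=[year]), weather)
        assert win.milestones_date["mat"] is None

    def test_date_gdd_roundtrip_on_grid(self, campaign):
        """date -> cumulative GDD -> date round-trips on days with warming."""
        windows = season_calendar(campaign["schedule"], campaign["weather"])
        for win in windows:
            increasing = np.flatnonzero(np.diff(win.cum_gdd) > 0) + 1
            for i in increasing[:50]:
                date = win.dates[i]
                assert win.gdd_to_date(win.date_to_gdd(date)) == date
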