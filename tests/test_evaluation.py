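"""Skill statistics, annual aggregation, calibration and uncertainty tests."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aquasrc import evaluation as ev
from aquasrc.canopy import canopy_cover


def brute_force_skill(obs, sim):
    """Explicit-sum re-derivation of NRMSE / R2 / overall-F p-value."""
    obs = np.asarray(obs, float)
    sim = np.asarray(sim, float)
    n = len(obs)
    rmse = math.sqrt(sum((s - o) ** 2 for o, s in zip(obs, sim)) / n)
    nrmse = 100.0 * rmse / (max(obs) - min(obs))
    sx = sum(sim)
    sy = sum(obs)
    sxx = sum(x * x for x in sim)
    sxy = sum(x * y for x, y in zip(sim, obs))
    syy = sum(y * y for y in obs)
    ssxx = sxx - sx * sx / n
    ssyy = syy - sy * sy / n
    ssxy = sxy - sx * sy / n
    r2 = ssxy ** 2 / (ssxx * ssyy)
    f = r2 * (n - 2) / (1.0 - r2)
    p = stats.f.sf(f, 1, n - 2)
    return nrmse, r2, p


class TestSkill:
    def test_perfect_agreement(self):
        x = np.linspace(1, 10, 25)
        st = ev.skill(x, x)
        assert st.nrmse == 0.0
        assert st.r2 == pytest.approx(1.0)

    def test_constant_offset_closed_form(self):
        obs = np.linspace(2, 12, 40)  # range 10
        sim = obs - 0.5
        st = ev.skill(obs, sim)
        assert st.nrmse == pytest.approx(100.0 * 0.5 / 10.0, abs=1e-9)
        assert st.r2 == pytest.approx(1.0)

    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            sim = rng.normal(3.0, 1.0, n)
            obs = sim + rng.normal(0.0, 0.5, n)
            st = ev.skill(obs, sim)
            nrmse, r2, p = brute_force_skill(obs, sim)
            assert st.nrmse == pytest.approx(nrmse, abs=1e-12)
            assert st.r2 == pytest.approx(r2, abs=1e-12)
            assert st.f_pvalue == pytest.approx(p, rel=1e-9)

    def test_uncorrelated_noise_has_no_skill(self, rng):
        obs = rng.normal(0, 1, 500)
        sim = rng.normal(0, 1, 500)
        st = ev.skill(obs, sim)
        assert st.r2 < 0.05
        assert st.f_pvalue > 0.01

    def test_missing_pairs_dropped(self):
        obs = np.array([1.0, np.nan, 3.0, 4.0])
        sim = np.array([1.1, 2.0, np.nan, 4.2])
        assert ev.skill(obs, sim).n == 2

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.skill([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestAnnualSummary:
    def test_ratios_and_average_from_totals(self):
        totals = pd.DataFrame({
            "year": [2014], "et0_tot": [713.0], "et_tot": [491.0],
            "tr_tot": [328.0], "e_soil_tot": [163.0],
        })
        out = ev.summarize_totals(totals)
        assert out["et_over_et0"].iloc[0] == pytest.approx(491.0 / 713.0)
        assert round(float(out["et_over_et0"].iloc[0]), 2) == 0.69

    def test_simulated_campaign_ratios_bounded(self, campaign):
        ann = ev.annual_summary(campaign["truth"].daily)
        body = ann.iloc[:-1]  # exclude the Average row
        for col in ("et_over_et0", "tr_over_et", "e_soil_over_et"):
            assert ((body[col] >= 0) & (body[col] <= 1.05)).all()
        assert np.allclose(body["tr_tot"] + body["e_soil_tot"], body["et_tot"])

    def test_partial_year_rejected(self, campaign):
        truncated = campaign["truth"].daily.iloc[:500]
        with pytest.raises(ValueError, match="partial"):
            ev.annual_summary(truncated)
        ev.annual_summary(truncated, allow_partial=True)  # explicit opt-in


class TestYieldDeviation:
    @pytest.mark.parametrize(
        "obs,sim,dev,rel",
        [(6.61, 8.74, 2.13, 32.22),
         (10.25, 13.69, 3.44, 33.56),
         (5.0, 5.0, 0.0, 0.0)],
    )
    def test_deviation_sign_and_magnitude(self, obs, sim, dev, rel):
        d, r = ev.yield_deviation(obs, sim)
        assert d == pytest.approx(dev, abs=5e-3)
        assert r == pytest.approx(rel, abs=5e-3)

    def test_underestimation_is_negative(self):
        d, r = ev.yield_deviation(10.26, 10.20)
        assert d < 0 and r < 0


class TestKcTrx:
    def test_noise_free_ratio_recovered(self):
        lai = np.linspace(1.0, 6.0, 50)
        et0 = np.full(50, 4.0)
        et = 0.99 * et0
        mean, (lo, hi) = ev.estimate_kctrx(et, et0, lai)
        assert mean == pytest.approx(0.99, abs=1e-12)
        assert lo == pytest.approx(hi)

    def test_interval_covers_generating_mean(self, rng):
        """~90% of repetitions bracket the true crop coefficient."""
        hits = 0
        reps = 300
        for _ in range(reps):
            n = 30
            lai = rng.uniform(3.5, 5.0, n)
            et0 = rng.uniform(2.0, 6.0, n)
            et = et0 * rng.normal(0.99, 0.1, n)
            _, (lo, hi) = ev.estimate_kctrx(et, et0, lai)
            hits += lo <= 0.99 <= hi
        assert 0.84 <= hits / reps <= 0.96

    def test_no_mid_season_days_rejected(self):
        lai = np.full(20, 2.0)
        with pytest.raises(ValueError, match="LAI"):
            ev.estimate_kctrx(np.ones(20), np.ones(20), lai)


class TestCanopyCalibration:
    def test_noise_free_self_consistency(self, coppice_params):
        p = coppice_params
        gdd = np.linspace(50.0, p.mat, 20)
        cc = [canopy_cover(g, p) for g in gdd]
        start = dataclasses.replace(p, cgc=p.cgc * 1.8, cdc=p.cdc * 0.5)
        res = ev.calibrate_canopy(gdd, cc, start)
        assert res.fitted["cgc"] == pytest.approx(p.cgc, rel=1e-4)
        assert res.fitted["cdc"] == pytest.approx(p.cdc, rel=1e-4)

    def test_objective_trace_monotone(self, coppice_params, rng):
        p = coppice_params
        gdd = np.linspace(50.0, p.mat, 15)
        cc = np.array([canopy_cover(g, p) for g in gdd]) + rng.normal(0, 0.02, 15)
        res = ev.calibrate_canopy(gdd, np.clip(cc, 0, 1), p)
        assert all(b <= a + 1e-15 for a, b in zip(res.trace, res.trace[1:]))

    def test_too_few_observations_rejected(self, coppice_params):
        with pytest.raises(ValueError):
            ev.calibrate_canopy([500.0], [0.5], coppice_params)

    def test_wp_fit_is_analytic(self):
        # biomass is linear in WP: target B / (0.01 * sum(Tr/ET0))
        assert ev.calibrate_wp(16.0, 160.0) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            ev.calibrate_wp(16.0, 0.0)


class TestEnergyBalanceClosure:
    def test_perfect_closure(self, rng):
        avail = rng.uniform(20, 200, 100)
        fit = ev.energy_balance_closure(avail * 0.4, avail * 0.6, avail, np.zeros(100))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_constructed_partial_closure(self, rng):
        rn = rng.uniform(50, 250, 200)
        g = 0.1 * rn
        avail = rn - g
        h = 0.3 * avail
        le = 0.4 * avail
        fit = ev.energy_balance_closure(h, le, rn, g)
        assert fit.slope == pytest.approx(0.7, abs=1e-9)

    def test_degenerate_variance_rejected(self):
        ones = np.ones(10)
        with pytest.raises(ValueError):
            ev.energy_balance_closure(ones, ones, 2 * ones, ones * 0)


class TestRME:
    def test_filter_uses_demand_differences_only(self, rng):
        n = 400
        et = rng.uniform(0.5, 5.0, n)
        et0 = rng.uniform(2.0, 6.0, n)
        m1 = ev.estimate_rme(et, et0)
        m2 = ev.estimate_rme(et, et0 + 3.7)  # constant shift cannot change pairs
        assert m1.retained_fraction == m2.retained_fraction
        assert m1.n_pairs == m2.n_pairs

    def test_noise_free_series_flagged_degenerate(self):
        et = np.full(200, 2.0)
        et0 = np.full(200, 3.0)
        m = ev.estimate_rme(et, et0)
        assert m.degenerate
        with pytest.raises(ValueError):
            ev.rme_at(2.0, m)

    def test_everything_filtered_rejected(self):
        et0 = np.arange(100, dtype=float)  # every step is 1 mm > 0.6 mm
        et = np.ones(100)
        with pytest.raises(ValueError, match="retained"):
            ev.estimate_rme(et, et0)

    def test_rme_at_printed_coefficients(self):
        model = ev.RMEModel(a=0.0609, c=0.209, threshold=0.6,
                            retained_fraction=1.0, n_pairs=100,
                            bin_et=np.array([]), bin_mad=np.array([]))
        # root of the logarithmic form: zero error at ET = exp(-c)
        assert ev.rme_at(math.exp(-0.209), model) == pytest.approx(0.0, abs=1e-12)
        assert ev.rme_at(1.0, model) == pytest.approx(0.0609 * 0.209, abs=1e-9)
        assert ev.rme_at(1.0, model) == pytest.approx(0.01273, abs=5e-5)
        assert ev.rme_at(4.0, model) > ev.rme_at(2.0, model)

    def test_bin_count_and_sizes(self, rng):
        et = rng.uniform(0.5, 5.0, 200)
        et0 = np.full(200, 3.0)
        m = ev.estimate_rme(et, et0)
        assert len(m.bin_et) == 10
        assert m.n_pairs == 199
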