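"""Covariate engineering: thermal time, photothermal quotient, moisture,
nutrient masses, density clustering, and full-vector assembly."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tillerscope as ts
from tillerscope.covariates import (
    DegeneratePeriodError, MissingWeatherError, WeatherDay,
)
from conftest import make_weather

D0 = date(2020, 5, 1)


def day(t_min, t_max, **kw):
    kw.setdefault("radiation", 20.0)
    kw.setdefault("vpd", 1.0)
    kw.setdefault("precip", 0.0)
    return WeatherDay(date=D0, t_min=t_min, t_max=t_max, **kw)


class TestDailyGdd:
    @pytest.mark.parametrize("t_min,t_max,expected", [
        (20, 30, 15.0),     # plain mean-above-base
        (32, 38, 20.0),     # mean capped at 30
        (4, 12, 0.0),       # mean below base floors at zero
        (10, 30, 10.0),
        (0, 20, 0.0),       # mean exactly at base
    ])
    def test_examples(self, t_min, t_max, expected):
        assert ts.daily_gdd(day(t_min, t_max)) == expected

    def test_cap_on_tmax_variant(self):
        consts = ts.Constants(gdd_cap_on="tmax")
        # t_max capped to 30 before averaging: (20 + 30)/2 - 10 = 15
        assert ts.daily_gdd(day(20, 38), consts) == 15.0
        # under the default the mean (29) is under the cap: 19
        assert ts.daily_gdd(day(20, 38)) == 19.0

    @given(t_min=st.floats(-30, 45), spread=st.floats(0, 25))
    @settings(max_examples=200, derandomize=True)
    def test_bounded(self, t_min, spread):
        g = ts.daily_gdd(day(t_min, t_min + spread))
        assert 0.0 <= g <= 20.0


class TestCumulativeGdd:
    def test_additivity_constant_series(self):
        w = make_weather(D0, 11, t_min=20, t_max=30)   # daily GDD 15
        assert ts.cumulative_gdd(w, D0, D0 + timedelta(days=9)) == 150.0

    def test_degenerate_window_is_zero(self):
        w = make_weather(D0, 5)
        assert ts.cumulative_gdd(w, D0, D0) == 0.0

    def test_matches_per_day_oracle(self):
        rng = np.random.default_rng(3)
        n = 40
        t_min = rng.uniform(-5, 25, n)
        t_max = t_min + rng.uniform(0, 20, n)
        w = pd.DataFrame({
            "date": [D0 + timedelta(days=i) for i in range(n)],
            "t_min": t_min, "t_max": t_max, "radiation": 20.0,
            "vpd": 1.0, "precip": 0.0, "irrigation": 0.0,
        })
        end = D0 + timedelta(days=n - 1)
        expected = sum(
            max(0.0, min((lo + hi) / 2.0, 30.0) - 10.0)
            for lo, hi in zip(t_min, t_max)
        )
        assert ts.cumulative_gdd(w, D0, end) == pytest.approx(expected, rel=1e-12)

    def test_missing_day_names_date(self):
        w = make_weather(D0, 10)
        w = w[w["date"] != D0 + timedelta(days=4)]
        with pytest.raises(MissingWeatherError, match="2020-05-05"):
            ts.cumulative_gdd(w, D0, D0 + timedelta(days=9))

    def test_monotone_in_window_length(self):
        w = make_weather(D0, 30, t_min=5, t_max=35)
        vals = [ts.cumulative_gdd(w, D0, D0 + timedelta(days=k))
                for k in range(30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPhotothermalQuotient:
    def test_arithmetic(self):
        # mean radiation 22, mean temperature 21 -> 22 / 11 = 2.0
        w = make_weather(D0, 10, t_min=15, t_max=27, radiation=22.0)
        assert ts.photothermal_quotient(w, D0, D0 + timedelta(days=9)) == pytest.approx(2.0)

    def test_base_temperature_period_is_error(self):
        w = make_weather(D0, 10, t_min=5, t_max=15)   # mean exactly 10
        with pytest.raises(DegeneratePeriodError):
            ts.photothermal_quotient(w, D0, D0 + timedelta(days=9))

    def test_thirty_day_series_matches_hand_oracle(self):
        rng = np.random.default_rng(8)
        n = 30
        t_min = rng.uniform(8, 18, n)
        t_max = t_min + rng.uniform(5, 15, n)
        rad = rng.uniform(10, 30, n)
        w = pd.DataFrame({
            "date": [D0 + timedelta(days=i) for i in range(n)],
            "t_min": t_min, "t_max": t_max, "radiation": rad,
            "vpd": 1.0, "precip": 0.0, "irrigation": 0.0,
        })
        expected = rad.mean() / (((t_min + t_max) / 2).mean() - 10.0)
        got = ts.photothermal_quotient(w, D0, D0 + timedelta(days=n - 1))
        assert got == pytest.approx(expected, rel=1e-12)


class TestMoistureAndTemperature:
    def test_cumulative_vpd(self):
        w = make_weather(D0, 6, vpd=1.2)
        assert ts.cumulative_vpd(w, D0, D0 + timedelta(days=4)) == pytest.approx(6.0)

    def test_dryland_moisture_is_precip_sum(self):
        w = make_weather(D0 - timedelta(days=30), 160, precip=2.0, irrigation=0.0)
        sow = D0
        obs = D0 + timedelta(days=49)
        # closed window: 30 pre-sow days + 50 season days
        assert ts.cumulative_moisture(w, sow, obs) == pytest.approx(2.0 * 80)

    def test_irrigation_adds(self):
        w = make_weather(D0 - timedelta(days=30), 160, precip=2.0, irrigation=1.0)
        got = ts.cumulative_moisture(w, D0, D0 + timedelta(days=49))
        assert got == pytest.approx(3.0 * 80)

    def test_temp_means_amplitude(self):
        w = make_weather(D0, 20, t_min=10, t_max=24)
        lo, hi, amp = ts.temp_means(w, D0, D0 + timedelta(days=9))
        assert (lo, hi, amp) == (10.0, 24.0, 14.0)


class TestNutrientMass:
    def test_dimensional_analysis_oracle(self):
        # 26.8 mg/kg x 1.3 Mg/m3 x 0.6 m x 10 = 209.04 kg/ha
        assert ts.nutrient_mass(26.8, 1.3, 60.0) == pytest.approx(209.04)

    def test_zero_concentration(self):
        assert ts.nutrient_mass(0.0, 1.3, 60.0) == 0.0

    @given(conc=st.floats(0.01, 500), bd=st.floats(0.8, 2.0),
           depth=st.floats(1, 120))
    @settings(max_examples=100, derandomize=True)
    def test_linearity_and_roundtrip(self, conc, bd, depth):
        m = ts.nutrient_mass(conc, bd, depth)
        assert ts.nutrient_mass(conc, bd, 2 * depth) == pytest.approx(2 * m, rel=1e-12)
        back = m / (bd * depth / 100.0 * 10.0)
        assert back == pytest.approx(conc, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ts.nutrient_mass(10.0, 0.0, 60.0)
        with pytest.raises(ValueError):
            ts.nutrient_mass(10.0, 1.3, -5.0)


class TestClassifyPlantDensity:
    @pytest.mark.parametrize("pd_value,expected", [
        (30000, "A"),
        (41295, "B"),       # the study-wide mean realized density
        (33500, "A"),       # equidistant tie resolves to the lower target
        (51000, "B"),       # equidistant between 42000 and 60000
        (17514, "A"),
        (73807, "C"),
    ])
    def test_examples(self, pd_value, expected):
        assert ts.classify_plant_density(pd_value) == expected

    @given(x=st.floats(1, 500000))
    @settings(max_examples=200, derandomize=True)
    def test_total_and_idempotent(self, x):
        cls = ts.classify_plant_density(x)
        assert cls in ("A", "B", "C")
        assert ts.classify_plant_density(ts.PD_TARGETS[cls]) == cls

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ts.classify_plant_density(0)


class TestBuildCovariates:
    def _obs(self, offset_days=50, observed_pd=41000.0):
        return ts.ObservationRecord(
            site_year="S1 2020", genotype="P08", sow_date=D0,
            obs_date=D0 + timedelta(days=offset_days), stage="V10",
            target_pd=42000, observed_pd=observed_pd, tiller_density=30000.0)

    def test_componentwise_oracle(self, soil):
        w = make_weather(D0 - timedelta(days=30), 120, t_min=15, t_max=27,
                         radiation=22.0, vpd=1.2, precip=2.0)
        obs = self._obs(50)
        vec = ts.build_covariates(obs, w, soil)
        assert vec.gdd == pytest.approx(11.0 * 51)      # mean 21 - 10, 51 days
        assert vec.ptq == pytest.approx(2.0)
        assert vec.vpd_cum == pytest.approx(1.2 * 51)
        assert vec.cm == pytest.approx(2.0 * 81)
        assert vec.t_amp_mean == pytest.approx(12.0)
        assert vec.pd_class == "B"
        assert vec.no3_kg == pytest.approx(209.04)
        assert vec.p_kg == pytest.approx(52.1 * 1.3 * 0.15 * 10)

    def test_cumulative_monotone_across_stages(self, gdd_step_data):
        frame = gdd_step_data["frame"]
        order = {s: i for i, s in enumerate(ts.STAGES)}
        for _, grp in frame.groupby(["site_year", "observed_pd", "genotype"]):
            grp = grp.sort_values("stage", key=lambda s: s.map(order))
            for col in ("gdd", "vpd_cum", "cm"):
                assert (np.diff(grp[col].to_numpy()) >= -1e-9).all()

    def test_observation_at_sowing_is_error(self, soil):
        w = make_weather(D0 - timedelta(days=30), 120)
        with pytest.raises(ValueError):
            ts.ObservationRecord(
                site_year="S1 2020", genotype="P08", sow_date=D0, obs_date=D0,
                stage="V5", target_pd=42000, observed_pd=41000.0,
                tiller_density=0.0)

    def test_error_carries_observation_id(self, soil):
        w = make_weather(D0, 10)    # no pre-sowing coverage
        with pytest.raises(ValueError, match="S1 2020"):
            ts.build_covariates(self._obs(5), w, soil)


class TestTableAssembly:
    def test_missing_column_is_named(self):
        with pytest.raises(ValueError, match="missing column"):
            ts.build_covariate_table(
                pd.DataFrame({"site_year": ["a"]}),
                pd.DataFrame({"site_year": []}), pd.DataFrame({"site_year": []}))

    def test_roundtrip_through_csv(self, tmp_path, gdd_step_data):
        obs, weather, so = (gdd_step_data["observations"],
                            gdd_step_data["weather"], gdd_step_data["soil"])
        for name, df in (("o", obs), ("w", weather), ("s", so)):
            df.to_csv(tmp_path / f"{name}.csv", index=False)
        frame2 = ts.build_covariate_table(
            pd.read_csv(tmp_path / "o.csv"), pd.read_csv(tmp_path / "w.csv"),
            pd.read_csv(tmp_path / "s.csv"))
        frame1 = gdd_step_data["frame"].drop(columns="true_probability")
        pd.testing.assert_frame_equal(
            frame1.reset_index(drop=True), frame2, check_exact=False,
            rtol=1e-12)
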