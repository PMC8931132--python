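"""Daily crop model: phenology, growth, water bucket, weighting."""

import numpy as np
import pandas as pd
import pytest

from conftest import constant_weather_frame
from cropshift.climate import extraterrestrial_radiation, hargreaves_pet
from cropshift.cropsim import (
    CropSequence,
    SoilProfile,
    annual_yield_potential,
    initialize_soil_water,
    maize_cultivar,
    rice_cultivar,
    simulate_season,
    site_yield_potential,
)
from cropshift.synthetic import ClimateParams, WeatherSeries, generate_weather


class TestSimulateSeason:
    def test_abundant_rain_matches_irrigated(self, default_soil):
        frame = constant_weather_frame(200, tmean=26.0, rain=40.0)
        cultivar = rice_cultivar()
        irr = simulate_season(frame, cultivar, default_soil, "irrigated", 100.0)
        rf = simulate_season(frame, cultivar, default_soil, "rainfed", 100.0)
        assert rf.yield_t_ha == pytest.approx(irr.yield_t_ha, rel=1e-9)
        assert rf.water_stress_days == 0

    def test_closed_form_yield_with_full_canopy(self, default_soil):
        # hand-computed: 95 days at 17 degC-days/day, fPAR ~= 1, ftemp = 1
        # yield = HI * RUE * 0.5 * srad * days * 0.01 / (1 - moisture)
        cultivar = rice_cultivar(max_lai=2000.0)
        frame = constant_weather_frame(150, tmean=25.0, srad=20.0)
        result = simulate_season(frame, cultivar, default_soil, "irrigated", 0.0)
        assert result.season_length == 95
        assert result.yield_t_ha == pytest.approx(12.42732558139535, rel=1e-9)

    def test_zero_radiation_gives_zero_yield(self, default_soil):
        frame = constant_weather_frame(200, tmean=26.0)
        frame["srad_mj_m2"] = 0.0
        result = simulate_season(frame, rice_cultivar(), default_soil, "irrigated", 0.0)
        assert result.biomass_t_ha == 0.0
        assert result.yield_t_ha == 0.0

    def test_incomplete_season_warns(self, default_soil):
        frame = constant_weather_frame(30, tmean=25.0)
        with pytest.warns(UserWarning, match="maturity not reached"):
            result = simulate_season(frame, rice_cultivar(), default_soil, "irrigated", 0.0)
        assert not result.complete

    def test_rue_linearity_in_biomass(self, default_soil):
        frame = constant_weather_frame(200, tmean=26.0, rain=2.0)
        base = simulate_season(frame, rice_cultivar(), default_soil, "rainfed", 50.0)
        doubled = simulate_season(frame, rice_cultivar(rue=5.0), default_soil, "rainfed", 50.0)
        assert doubled.biomass_t_ha == pytest.approx(2.0 * base.biomass_t_ha, rel=1e-9)


def random_scenario(seed):
    rng = np.random.default_rng(seed)
    params = ClimateParams(
        mean_temp_base=float(rng.uniform(18, 30)),
        seasonal_amplitude=float(rng.uniform(0, 8)),
        annual_rain=float(rng.uniform(200, 2000)),
        rain_days_fraction=float(rng.uniform(0.1, 0.6)),
        interannual_sd=float(rng.uniform(0, 0.2)),
    )
    weather = generate_weather((int(rng.integers(0, 20)), 0), 1, params, seed=seed)
    sow = int(rng.integers(0, 120))
    frame = weather.frame.iloc[sow : sow + 220].reset_index(drop=True)
    cultivar = rice_cultivar(gdd_to_maturity=float(rng.uniform(1000, 1800)))
    soil = SoilProfile(paw_capacity_mm=float(rng.uniform(50, 250)))
    init = float(rng.uniform(0, soil.paw_capacity_mm))
    return frame, cultivar, soil, init


class TestWaterProperties:
    @pytest.mark.parametrize("seed", range(60))
    def test_dominance_monotonicity_and_budget(self, seed):
        frame, cultivar, soil, init = random_scenario(seed)
        irr = simulate_season(frame, cultivar, soil, "irrigated", init)
        rf = simulate_season(frame, cultivar, soil, "rainfed", init)
        assert irr.yield_t_ha >= rf.yield_t_ha - 1e-12  # irrigation dominance

        bigger = SoilProfile(paw_capacity_mm=soil.paw_capacity_mm + 60.0)
        rf_big = simulate_season(frame, cultivar, bigger, "rainfed", init)
        assert rf_big.yield_t_ha >= rf.yield_t_ha - 1e-9  # capacity monotonicity

        b = rf.water_budget  # closure of the bucket balance
        closure = b["rain_mm"] - b["overflow_mm"] - b["transpiration_mm"] - b["soil_evaporation_mm"]
        assert closure == pytest.approx(b["delta_storage_mm"], abs=1e-6)
        assert 0.0 <= rf.soil_water_end <= soil.paw_capacity_mm


class TestInitializeSoilWater:
    @pytest.mark.parametrize("fraction,expected", [(1.0, 150.0), (0.0, 0.0)])
    def test_fixed_fraction(self, default_soil, fraction, expected):
        frame = constant_weather_frame(10)
        value = initialize_soil_water("fixed_fraction", frame, default_soil, 5, fraction=fraction)
        assert value == pytest.approx(expected)

    def test_fixed_fraction_outside_unit_interval_rejected(self, default_soil):
        with pytest.raises(ValueError):
            initialize_soil_water("fixed_fraction", constant_weather_frame(5), default_soil, 2, fraction=1.2)

    def test_dry_spinup_matches_daily_bucket_oracle(self, default_soil):
        frame = constant_weather_frame(40, tmean=28.0, rain=0.0)
        start = 120.0
        result = initialize_soil_water(
            "fallow_spinup", frame, default_soil, sowing_index=40, start_storage=start, latitude=25.0
        )
        # independent day-by-day recomputation of the bare-soil bucket
        doy = pd.DatetimeIndex(frame["date"]).dayofyear.to_numpy()
        ra = extraterrestrial_radiation(25.0, doy)
        pet = hargreaves_pet(frame["tmin_c"].to_numpy(), frame["tmax_c"].to_numpy(), ra)
        storage = start
        for d in range(40):
            storage = min(max(storage - 0.6 * pet[d], 0.0), 150.0)
        assert result == pytest.approx(storage, abs=1e-9)
        assert result < start

    def test_spinup_with_heavy_rain_caps_at_capacity(self, default_soil):
        frame = constant_weather_frame(30, rain=50.0)
        result = initialize_soil_water("fallow_spinup", frame, default_soil, 30, start_storage=0.0)
        assert result == pytest.approx(default_soil.paw_capacity_mm)


class TestAnnualYield:
    @staticmethod
    def year_frame(tmean=26.0, srad=18.0, rain=6.0):
        return constant_weather_frame(365, tmean=tmean, srad=srad, rain=rain, start="2010-01-01")

    def test_single_crop_sequence_equals_season(self, default_soil):
        frame = self.year_frame()
        cultivar = rice_cultivar()
        seq = CropSequence(sowing_days=(50,), cultivars=(cultivar,))
        annual = annual_yield_potential(frame, seq, default_soil, "irrigated")
        season = simulate_season(frame.iloc[49:].reset_index(drop=True), cultivar, default_soil, "irrigated", 75.0)
        assert annual == pytest.approx(season.yield_t_ha, rel=1e-12)

    def test_double_cropping_doubles_yield_under_identical_forcing(self, default_soil):
        frame = self.year_frame()
        cultivar = rice_cultivar()
        double = CropSequence(sowing_days=(30, 210), cultivars=(cultivar, cultivar))
        single = CropSequence(sowing_days=(30,), cultivars=(cultivar,))
        total, seasons = annual_yield_potential(
            frame, double, default_soil, "irrigated", return_seasons=True
        )
        one = annual_yield_potential(frame, single, default_soil, "irrigated")
        assert len(seasons) == 2
        assert total == pytest.approx(2.0 * one, rel=1e-12)

    def test_overlapping_seasons_rejected(self, default_soil):
        frame = self.year_frame()
        cultivar = rice_cultivar()  # ~89 days to maturity at 26 degC
        seq = CropSequence(sowing_days=(30, 60), cultivars=(cultivar, cultivar))
        with pytest.raises(ValueError, match="before the previous crop matures"):
            annual_yield_potential(frame, seq, default_soil, "irrigated")


class TestSiteYield:
    @staticmethod
    def weather(seed=3, years=4):
        params = ClimateParams(seasonal_amplitude=2.0, interannual_sd=0.05)
        return generate_weather((4, 4), years, params, seed=seed)

    def test_single_soil_single_sequence_identity(self):
        weather = self.weather()
        soil = SoilProfile(paw_capacity_mm=140.0)
        seq = CropSequence(sowing_days=(60,), cultivars=(rice_cultivar(),))
        site = site_yield_potential(weather, [soil], [seq], "irrigated")
        per_year = [
            annual_yield_potential(weather.year_slice(y), seq, soil, "irrigated", latitude=weather.latitude)
            for y in weather.years
        ]
        np.testing.assert_allclose(site.yearly_annual_yield, per_year, rtol=1e-12)

    def test_equal_shares_average_two_soils(self):
        weather = self.weather()
        soils = [SoilProfile(70.0, 0.5), SoilProfile(220.0, 0.5)]
        seq = CropSequence(sowing_days=(60,), cultivars=(rice_cultivar(),))
        site = site_yield_potential(weather, soils, [seq], "rainfed")
        a = site_yield_potential(weather, [SoilProfile(70.0)], [seq], "rainfed")
        b = site_yield_potential(weather, [SoilProfile(220.0)], [seq], "rainfed")
        np.testing.assert_allclose(
            site.yearly_annual_yield,
            (a.yearly_annual_yield + b.yearly_annual_yield) / 2.0,
            rtol=1e-12,
        )

    def test_weighting_matches_exhaustive_combination_oracle(self):
        weather = self.weather(seed=8, years=3)
        rng = np.random.default_rng(1)
        soil_shares = rng.dirichlet(np.ones(3))
        seq_shares = rng.dirichlet(np.ones(2))
        soils = [SoilProfile(float(p), float(s)) for p, s in zip((80, 150, 230), soil_shares)]
        seqs = [
            CropSequence(sowing_days=(40,), cultivars=(rice_cultivar(),), area_share=float(seq_shares[0])),
            CropSequence(
                sowing_days=(40, 220),
                cultivars=(rice_cultivar(), rice_cultivar(gdd_to_maturity=1200.0)),
                area_share=float(seq_shares[1]),
            ),
        ]
        site = site_yield_potential(weather, soils, seqs, "rainfed")
        oracle = []
        for y in weather.years:
            frame = weather.year_slice(y)
            total = 0.0
            for soil in soils:
                for seq in seqs:
                    total += soil.area_share * seq.area_share * annual_yield_potential(
                        frame, seq, soil, "rainfed", latitude=weather.latitude
                    )
            oracle.append(total)
        np.testing.assert_allclose(site.yearly_annual_yield, oracle, rtol=1e-12)
        assert site.crop_intensity == pytest.approx(seq_shares[0] + 2 * seq_shares[1])

    def test_share_sum_violation_rejected(self):
        weather = self.weather(years=2)
        soils = [SoilProfile(100.0, 0.6), SoilProfile(200.0, 0.3)]
        seq = CropSequence(sowing_days=(60,), cultivars=(rice_cultivar(),))
        with pytest.raises(ValueError, match="sum to 1"):
            site_yield_potential(weather, soils, [seq], "rainfed")


class TestCultivars:
    def test_standard_moistures_match_reporting_conventions(self):
        assert rice_cultivar().standard_moisture == pytest.approx(0.14)
        assert maize_cultivar().standard_moisture == pytest.approx(0.155)

    def test_yield_biomass_moisture_identity(self, default_soil):
        frame = constant_weather_frame(200, tmean=26.0)
        c = maize_cultivar()
        r = simulate_season(frame, c, default_soil, "irrigated", 0.0)
        assert r.yield_t_ha == pytest.approx(
            r.biomass_t_ha * c.harvest_index / (1 - c.standard_moisture), rel=1e-12
        )
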