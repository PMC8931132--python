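import numpy as np
import pandas as pd
import pytest

from cropshift.synthetic import ClimateParams, LandscapeConfig, SoilProfile, generate_weather


@pytest.fixture
def quiet_params() -> ClimateParams:
    """Climate with every stochastic component switched off."""
    return ClimateParams(
        mean_temp_base=25.0,
        mean_temp_gradient=0.0,
        seasonal_amplitude=0.0,
        temp_daily_sd=0.0,
        annual_rain=1000.0,
        rain_days_fraction=1.0,
        rain_amount_cv=0.0,
        radiation_mean=18.0,
        radiation_amplitude=0.0,
        rad_daily_sd=0.0,
        interannual_sd=0.0,
    )


@pytest.fixture
def small_landscape() -> LandscapeConfig:
    return LandscapeConfig(
        grid_shape=(20, 20),
        urban_centers=(((4, 4), 50_000.0),),
        contraction_radius=2.0,
        expansion_region=(14, 20, 0, 20),
        expansion_total_ha=60_000.0,
        seed=7,
    )


@pytest.fixture
def default_soil() -> SoilProfile:
    return SoilProfile(paw_capacity_mm=150.0)


def constant_weather_frame(
    n_days: int,
    tmean: float = 25.0,
    diurnal: float = 8.0,
    srad: float = 20.0,
    rain: float = 0.0,
    start: str = "2010-01-01",
) -> pd.DataFrame:
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "tmin_c": np.full(n_days, tmean - diurnal / 2),
            "tmax_c": np.full(n_days, tmean + diurnal / 2),
            "srad_mj_m2": np.full(n_days, srad),
            "rain_mm": np.full(n_days, float(rain)),
        }
    )
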