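"""Daily crop growth model: radiation-use efficiency with a soil water bucket.

This is a deliberately simple summary model of annual yield potential, not a
process-level crop simulator.  It keeps the features the spatial analysis
depends on — thermal-time phenology driven by a single cultivar maturity
requirement, Beer's-law light interception, temperature and water-supply
growth factors, multi-season cropping with soil-water carry-over — while
omitting detailed physiology (photosynthesis/respiration partitioning, cold
sterility, submergence, nutrient limitation, pests).

Daily growth (g dry matter m-2):

    dB = RUE * PAR * fPAR * f_temp * f_water

with PAR = 0.5 x global radiation, fPAR = 1 - exp(-k * LAI) (k = 0.5), LAI a
logistic function of the thermal-time fraction, f_temp a piecewise-linear
temperature response, and f_water = 1 under irrigation or the supply/demand
ratio of a single-layer soil water bucket under rainfed conditions.  Grain
yield is biomass x harvest index, converted from dry matter to the crop's
commercial moisture standard (14% rice, 15.5% maize).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import extraterrestrial_radiation, hargreaves_pet
from .synthetic import SoilProfile, WeatherSeries

__all__ = [
    "Cultivar",
    "CropSequence",
    "SeasonResult",
    "SiteYield",
    "SoilProfile",
    "rice_cultivar",
    "maize_cultivar",
    "simulate_season",
    "initialize_soil_water",
    "annual_yield_potential",
    "site_yield_potential",
]

PAR_FRACTION = 0.5  # photosynthetically active fraction of global radiation
K_EXTINCTION = 0.5  # Beer's-law canopy extinction coefficient
SOIL_EVAP_FACTOR = 0.6  # bare-soil evaporation as a fraction of PET
LAI_LOGISTIC_STEEPNESS = 8.0
LAI_LOGISTIC_MIDPOINT = 0.35  # thermal-time fraction at half-maximum LAI


@dataclass(frozen=True)
class Cultivar:
    """Genotype parameters; one maturity requirement drives phenology."""

    name: str
    gdd_to_maturity: float  # degC-days emergence -> physiological maturity
    base_temp: float  # degC, thermal-time base
    rue: float  # g dry matter per MJ intercepted PAR
    max_lai: float
    harvest_index: float
    standard_moisture: float  # commercial reporting moisture fraction
    t_opt_lo: float = 18.0  # degC, start of optimal plateau
    t_opt_hi: float = 32.0  # degC, end of optimal plateau
    t_max: float = 42.0  # degC, growth ceases above

    def __post_init__(self) -> None:
        if min(self.gdd_to_maturity, self.rue, self.max_lai) <= 0:
            raise ValueError("gdd_to_maturity, rue, max_lai must be positive")
        if not 0 < self.harvest_index < 1:
            raise ValueError("harvest_index must lie in (0, 1)")
        if not 0 <= self.standard_moisture <= 0.2:
            raise ValueError("standard_moisture must lie in [0, 0.2]")
        if not self.base_temp < self.t_opt_lo <= self.t_opt_hi < self.t_max:
            raise ValueError("temperature response thresholds must be ordered")

    def temperature_factor(self, tmean: float | np.ndarray) -> np.ndarray:
        """Piecewise-linear growth response: 0 below base, ramp to 1 at
        t_opt_lo, plateau to t_opt_hi, decline to 0 at t_max."""
        t = np.asarray(tmean, dtype=float)
        up = (t - self.base_temp) / (self.t_opt_lo - self.base_temp)
        down = (self.t_max - t) / (self.t_max - self.t_opt_hi)
        return np.clip(np.minimum(up, down), 0.0, 1.0)


def rice_cultivar(gdd_to_maturity: float = 1600.0, **overrides) -> Cultivar:
    """Default lowland rice genotype; yields reported at 14% moisture."""
    params = dict(
        name="rice-default",
        gdd_to_maturity=gdd_to_maturity,
        base_temp=8.0,
        rue=2.5,
        max_lai=6.0,
        harvest_index=0.45,
        standard_moisture=0.14,
        t_opt_lo=22.0,
        t_opt_hi=30.0,
        t_max=42.0,
    )
    params.update(overrides)
    return Cultivar(**params)


def maize_cultivar(gdd_to_maturity: float = 1500.0, **overrides) -> Cultivar:
    """Default maize hybrid; yields reported at 15.5% moisture."""
    params = dict(
        name="maize-default",
        gdd_to_maturity=gdd_to_maturity,
        base_temp=10.0,
        rue=3.3,
        max_lai=5.0,
        harvest_index=0.50,
        standard_moisture=0.155,
        t_opt_lo=18.0,
        t_opt_hi=32.0,
        t_max=44.0,
    )
    params.update(overrides)
    return Cultivar(**params)


@dataclass(frozen=True)
class CropSequence:
    """Crops grown on the same land within one year (single/double/triple)."""

    sowing_days: tuple[int, ...]  # day of year per crop slot, ascending
    cultivars: tuple[Cultivar, ...]
    area_share: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.sowing_days) <= 3:
            raise ValueError("a sequence holds 1-3 crops per year")
        if len(self.sowing_days) != len(self.cultivars):
            raise ValueError("one cultivar per sowing day required")
        if list(self.sowing_days) != sorted(set(self.sowing_days)):
            raise ValueError("sowing days must be strictly increasing")
        if not 0 < self.area_share <= 1:
            raise ValueError("area_share must lie in (0, 1]")

    @property
    def crops_per_year(self) -> int:
        return len(self.sowing_days)


@dataclass(frozen=True)
class SeasonResult:
    """One simulated crop cycle."""

    yield_t_ha: float  # grain at the cultivar's standard moisture
    biomass_t_ha: float  # total above-ground dry matter
    water_stress_days: int
    season_length: int  # days sowing -> maturity
    complete: bool
    end_index: int  # index into the weather slice of the day after maturity
    soil_water_end: float  # mm, bucket content at harvest
    water_budget: dict[str, float] = field(compare=False, default_factory=dict)


@dataclass
class SiteYield:
    """Soil x sequence weighted annual yield potential series for one site."""

    yearly_annual_yield: np.ndarray  # t ha-1 yr-1, one entry per weather year
    mean_annual_yield: float
    cv_percent: float  # inter-annual CV (sample SD / mean x 100)
    crop_intensity: float  # share-weighted crops per year
    buffer_id: int | None = None
    cz_id: int | None = None
    irrigated_share: float = 0.0
    net_balance_ha: float = 0.0
    flag: str = "none"  # contracting | expanding | none


def _daily_pet(frame: pd.DataFrame, latitude: float) -> np.ndarray:
    doy = pd.DatetimeIndex(frame["date"]).dayofyear.to_numpy()
    ra = extraterrestrial_radiation(latitude, doy)
    return hargreaves_pet(frame["tmin_c"].to_numpy(), frame["tmax_c"].to_numpy(), ra)


def simulate_season(
    weather: pd.DataFrame,
    cultivar: Cultivar,
    soil: SoilProfile,
    water_regime: str,
    initial_soil_water: float = 0.0,
    latitude: float = 25.0,
) -> SeasonResult:
    """Simulate one crop cycle starting on the first row of ``weather``.

    The slice must extend from sowing at least to maturity; if thermal time
    runs out before maturity the season is flagged incomplete and the yield
    to date is reported with a warning.

    Under irrigation the water-supply factor is pinned at 1.  Under rainfed
    conditions a single-layer bucket of capacity ``soil.paw_capacity_mm``
    receives rain, loses crop transpiration (PET x fPAR, supply-limited) and
    bare-soil evaporation (PET x (1 - fPAR) x 0.6, supply-limited), and
    spills overflow beyond capacity; the day's stress factor is the
    transpiration supply/demand ratio.
    """
    if water_regime not in ("irrigated", "rainfed"):
        raise ValueError(f"unknown water regime: {water_regime}")
    if len(weather) == 0:
        raise ValueError("empty weather slice")
    tmean = ((weather["tmin_c"] + weather["tmax_c"]) / 2.0).to_numpy()
    srad = weather["srad_mj_m2"].to_numpy()
    rain = weather["rain_mm"].to_numpy()
    rainfed = water_regime == "rainfed"
    pet = _daily_pet(weather, latitude) if rainfed else None

    storage = float(np.clip(initial_soil_water, 0.0, soil.paw_capacity_mm))
    storage0 = storage
    tt = 0.0
    biomass = 0.0
    stress_days = 0
    transp_total = evap_total = overflow_total = rain_total = 0.0
    day = 0
    n = len(weather)
    while day < n and tt < cultivar.gdd_to_maturity:
        f = tt / cultivar.gdd_to_maturity
        lai = cultivar.max_lai / (1.0 + np.exp(-LAI_LOGISTIC_STEEPNESS * (f - LAI_LOGISTIC_MIDPOINT)))
        fpar = 1.0 - np.exp(-K_EXTINCTION * lai)
        ftemp = float(cultivar.temperature_factor(tmean[day]))

        if rainfed:
            water = storage + rain[day]
            rain_total += rain[day]
            demand = pet[day] * fpar
            transp = min(demand, water)
            water -= transp
            evap_demand = pet[day] * (1.0 - fpar) * SOIL_EVAP_FACTOR
            evap = min(evap_demand, water)
            water -= evap
            overflow = max(0.0, water - soil.paw_capacity_mm)
            storage = water - overflow
            fwater = 1.0 if demand <= 0 else transp / demand
            transp_total += transp
            evap_total += evap
            overflow_total += overflow
            if fwater < 1.0 - 1e-12:
                stress_days += 1
        else:
            fwater = 1.0

        biomass += cultivar.rue * PAR_FRACTION * srad[day] * fpar * ftemp * fwater
        tt += max(0.0, tmean[day] - cultivar.base_temp)
        day += 1

    complete = tt >= cultivar.gdd_to_maturity
    if not complete:
        warnings.warn(
            f"{cultivar.name}: maturity not reached ({tt:.0f}/{cultivar.gdd_to_maturity:.0f} "
            "degC-days) before weather slice ended; reporting yield to date",
            stacklevel=2,
        )
    biomass_t_ha = biomass * 0.01  # g m-2 -> t ha-1
    yield_t_ha = biomass_t_ha * cultivar.harvest_index / (1.0 - cultivar.standard_moisture)
    budget = {
        "rain_mm": rain_total,
        "transpiration_mm": transp_total,
        "soil_evaporation_mm": evap_total,
        "overflow_mm": overflow_total,
        "delta_storage_mm": storage - storage0,
    }
    return SeasonResult(
        yield_t_ha=float(yield_t_ha),
        biomass_t_ha=float(biomass_t_ha),
        water_stress_days=stress_days,
        season_length=day,
        complete=complete,
        end_index=day,
        soil_water_end=float(storage),
        water_budget=budget,
    )


def initialize_soil_water(
    mode: str,
    weather: pd.DataFrame,
    soil: SoilProfile,
    sowing_index: int,
    fraction: float | None = None,
    start_index: int = 0,
    start_storage: float | None = None,
    latitude: float = 25.0,
) -> float:
    """Soil water content (mm) at sowing.

    ``fixed_fraction`` returns ``fraction x paw_capacity``.  ``fallow_spinup``
    runs the bucket without a crop (rain in, bare-soil evaporation out,
    overflow beyond capacity) from ``start_index`` (previous harvest) to
    ``sowing_index``; the fallow starts at ``start_storage`` (default half
    capacity).
    """
    if mode == "fixed_fraction":
        if fraction is None or not 0.0 <= fraction <= 1.0:
            raise ValueError("fixed_fraction mode needs fraction in [0, 1]")
        return fraction * soil.paw_capacity_mm
    if mode != "fallow_spinup":
        raise ValueError(f"unknown initialization mode: {mode}")
    if not 0 <= start_index <= sowing_index <= len(weather):
        raise ValueError("invalid fallow window")
    storage = 0.5 * soil.paw_capacity_mm if start_storage is None else float(start_storage)
    storage = float(np.clip(storage, 0.0, soil.paw_capacity_mm))
    if sowing_index == start_index:
        return storage
    window = weather.iloc[start_index:sowing_index]
    rain = window["rain_mm"].to_numpy()
    pet = _daily_pet(window, latitude)
    for d in range(len(window)):
        water = storage + rain[d]
        evap = min(SOIL_EVAP_FACTOR * pet[d], water)
        water -= evap
        storage = min(water, soil.paw_capacity_mm)
    return float(storage)


def annual_yield_potential(
    weather_year: pd.DataFrame,
    sequence: CropSequence,
    soil: SoilProfile,
    water_regime: str,
    init_mode: str = "fixed_fraction",
    init_fraction: float = 0.5,
    latitude: float = 25.0,
    return_seasons: bool = False,
):
    """Annual yield potential (t ha-1 yr-1): sum over the sequence's crop
    slots within one weather year, carrying soil water between seasons via a
    fallow spin-up of the bucket.

    Raises ``ValueError`` if a season has not matured by the next slot's
    sowing day (overlapping seasons).
    """
    doy = pd.DatetimeIndex(weather_year["date"]).dayofyear.to_numpy()
    first_doy = int(doy[0])
    results: list[SeasonResult] = []
    storage: float | None = None
    prev_end_index = 0
    for slot, (sowing_day, cultivar) in enumerate(zip(sequence.sowing_days, sequence.cultivars)):
        sow_idx = int(sowing_day - first_doy)
        if not 0 <= sow_idx < len(weather_year):
            raise ValueError(f"sowing day {sowing_day} outside the weather year")
        if slot > 0 and sow_idx < prev_end_index:
            raise ValueError(
                f"slot {slot} sows on day {sowing_day} before the previous crop matures"
            )
        if slot == 0:
            init = initialize_soil_water(
                init_mode,
                weather_year,
                soil,
                sowing_index=sow_idx,
                fraction=init_fraction,
                start_index=0,
                latitude=latitude,
            )
        else:
            init = initialize_soil_water(
                "fallow_spinup",
                weather_year,
                soil,
                sowing_index=sow_idx,
                start_index=prev_end_index,
                start_storage=storage,
                latitude=latitude,
            )
        season = simulate_season(
            weather_year.iloc[sow_idx:].reset_index(drop=True),
            cultivar,
            soil,
            water_regime,
            initial_soil_water=init,
            latitude=latitude,
        )
        results.append(season)
        prev_end_index = sow_idx + season.end_index
        storage = season.soil_water_end
    total = float(sum(s.yield_t_ha for s in results))
    if return_seasons:
        return total, results
    return total


def site_yield_potential(
    weather: WeatherSeries,
    soils: list[SoilProfile],
    sequences: list[CropSequence],
    water_regime: str,
    init_mode: str = "fixed_fraction",
    init_fraction: float = 0.5,
) -> SiteYield:
    """Soil x crop-sequence weighted annual yield potential for one site.

    For each weather year, the annual yield is the double sum over soil types
    and crop sequences of share_soil x share_sequence x annual yield for that
    combination.  Shares within each set must sum to 1 (tolerance 1e-6).
    """
    soil_sum = sum(s.area_share for s in soils)
    seq_sum = sum(q.area_share for q in sequences)
    if abs(soil_sum - 1.0) > 1e-6 or abs(seq_sum - 1.0) > 1e-6:
        raise ValueError(
            f"area shares must sum to 1 (soils: {soil_sum:.8f}, sequences: {seq_sum:.8f})"
        )
    yearly = []
    for year in weather.years:
        frame = weather.year_slice(year)
        total = 0.0
        for soil in soils:
            for seq in sequences:
                total += soil.area_share * seq.area_share * annual_yield_potential(
                    frame,
                    seq,
                    soil,
                    water_regime,
                    init_mode=init_mode,
                    init_fraction=init_fraction,
                    latitude=weather.latitude,
                )
        yearly.append(total)
    series = np.asarray(yearly, dtype=float)
    mean = float(series.mean())
    cv = float(series.std(ddof=1) / mean * 100.0) if len(series) > 1 and mean > 0 else 0.0
    intensity = float(sum(q.area_share * q.crops_per_year for q in sequences))
    return SiteYield(
        yearly_annual_yield=series,
        mean_annual_yield=mean,
        cv_percent=cv,
        crop_intensity=intensity,
        irrigated_share=1.0 if water_regime == "irrigated" else 0.0,
    )
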