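"""Synthetic landscapes, weather, stations, and soils.

Everything here is seeded: a single integer seed fans out to independent
per-component child generators via :class:`numpy.random.SeedSequence`, so the
same seed and configuration always reproduce the same bytes.

The spatial model is an abstract equal-area lattice: cells are squares of
``cell_km`` edge length holding ``cell_area_ha`` hectares of land, indexed
0-based row-major.  Georeferencing is deliberately reduced to a latitude
mapping (``ClimateParams.ref_latitude`` + ``lat_per_row``) because the
analysis consumes areas and distances, not projections.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeConfig",
    "ClimateParams",
    "CropAreaGrid",
    "WeatherSeries",
    "SoilProfile",
    "generate_area_grids",
    "generate_weather",
    "generate_stations",
    "generate_soils",
    "contraction_kernel",
]

# stream ids for SeedSequence fan-out; fixed so adding components never
# perturbs existing streams
_STREAM_AREA = 1
_STREAM_WEATHER = 2
_STREAM_STATIONS = 3
_STREAM_SOILS = 4


def child_rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    """Independent generator for component ``stream`` under a global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream), *map(int, extra)]))


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of a synthetic two-epoch harvested-area landscape.

    ``urban_centers`` is a list of ``((row, col), loss_ha)`` pairs: each
    center removes a total of ``loss_ha`` hectares between the epochs,
    distributed over surrounding cells with an exponential-decay kernel of
    e-folding length ``contraction_radius`` (cells), truncated at three
    e-folding lengths.  ``expansion_region`` is a half-open box
    ``(row0, row1, col0, col1)`` that gains ``expansion_total_ha`` spread
    uniformly over its cells.
    """

    grid_shape: tuple[int, int]
    cell_area_ha: float = 10_000.0
    cell_km: float = 10.0
    urban_centers: tuple[tuple[tuple[int, int], float], ...] = ()
    contraction_radius: float = 3.0
    expansion_region: tuple[int, int, int, int] | None = None
    expansion_total_ha: float = 0.0
    crop: str = "rice"
    water_regimes: tuple[str, ...] = ("irrigated",)
    irrigated_share: float = 1.0
    base_area_mean: float = 3_000.0
    base_area_cv: float = 0.35
    base_smoothing: int = 2
    year_noise_cv: float = 0.02
    epoch_years: tuple[tuple[int, ...], tuple[int, ...]] = (
        (1999, 2000, 2001),
        (2009, 2010, 2011),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_area_ha <= 0:
            raise ValueError("cell_area_ha must be positive")
        if self.contraction_radius < 0:
            raise ValueError("contraction_radius must be non-negative")
        if not set(self.water_regimes) <= {"irrigated", "rainfed"}:
            raise ValueError(f"unknown water regimes: {self.water_regimes}")
        nr, nc = self.grid_shape
        for (r, c), loss in self.urban_centers:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValueError(f"urban center {(r, c)} outside grid {self.grid_shape}")
            if loss < 0:
                raise ValueError("urban loss must be non-negative")
        if self.expansion_region is not None:
            r0, r1, c0, c1 = self.expansion_region
            if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
                raise ValueError("expansion_region box outside grid or empty")


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic climate surface and daily weather.

    The deterministic climatology of a cell in row ``r`` is

    * mean temperature ``mean_temp_base + mean_temp_gradient * r`` plus a
      sinusoidal seasonal cycle of amplitude ``seasonal_amplitude``,
    * annual rainfall ``annual_rain + rain_gradient * r`` spread over a
      Bernoulli(``rain_days_fraction``) subset of days,
    * shortwave radiation ``radiation_mean`` plus a seasonal cycle of
      amplitude ``radiation_amplitude``.

    Stochastic components: per-year rainfall multipliers with standard
    deviation ``interannual_sd``; daily temperature noise ``temp_daily_sd``;
    daily radiation noise ``rad_daily_sd``; rain-day amounts drawn from a
    gamma distribution with coefficient of variation ``rain_amount_cv``
    (1.0 reproduces the classic exponential rain-amount model; 0 makes
    amounts deterministic).
    """

    mean_temp_base: float = 26.0
    mean_temp_gradient: float = -0.15  # degC per row southward->northward cooling
    seasonal_amplitude: float = 6.0
    diurnal_range: float = 8.0
    temp_daily_sd: float = 1.5
    annual_rain: float = 1200.0
    rain_gradient: float = 0.0  # mm per row
    rain_days_fraction: float = 0.35
    rain_amount_cv: float = 1.0
    radiation_mean: float = 17.0
    radiation_amplitude: float = 4.0
    rad_daily_sd: float = 2.0
    interannual_sd: float = 0.10
    peak_doy: int = 196  # day of year of the warm/wet season peak
    ref_latitude: float = 25.0
    lat_per_row: float = 0.09  # degrees latitude gained per row northward

    def __post_init__(self) -> None:
        if self.annual_rain < 0:
            raise ValueError("annual_rain must be non-negative")
        if not 0.0 <= self.rain_days_fraction <= 1.0:
            raise ValueError("rain_days_fraction must lie in [0, 1]")

    def row_mean_temp(self, row: int | np.ndarray) -> np.ndarray:
        return self.mean_temp_base + self.mean_temp_gradient * np.asarray(row, dtype=float)

    def row_annual_rain(self, row: int | np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.annual_rain + self.rain_gradient * np.asarray(row, dtype=float))

    def row_latitude(self, row: int | np.ndarray) -> np.ndarray:
        return self.ref_latitude + self.lat_per_row * np.asarray(row, dtype=float)


@dataclass(frozen=True)
class CropAreaGrid:
    """Stack of yearly harvested-area grids for one crop x water regime.

    ``data`` has shape ``(n_years, rows, cols)`` in hectares per cell.
    """

    data: np.ndarray
    years: tuple[int, ...]
    crop: str
    water_regime: str
    cell_area_ha: float = 10_000.0
    cell_km: float = 10.0

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[0] != len(self.years):
            raise ValueError("data must be (n_years, rows, cols) matching years")
        if np.any(self.data < 0):
            raise ValueError("harvested area must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def epoch_mean(self) -> np.ndarray:
        """Cell-wise arithmetic mean over the stacked years."""
        return self.data.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (row, col, year, crop, water_regime, area_ha)."""
        ny, nr, nc = self.data.shape
        years = np.repeat(self.years, nr * nc)
        rows = np.tile(np.repeat(np.arange(nr), nc), ny)
        cols = np.tile(np.arange(nc), ny * nr)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "year": years,
                "crop": self.crop,
                "water_regime": self.water_regime,
                "area_ha": self.data.reshape(-1),
            }
        )


@dataclass(frozen=True)
class WeatherSeries:
    """Multi-year daily weather record at one station.

    ``frame`` columns: date, tmin_c, tmax_c, srad_mj_m2, rain_mm.
    """

    frame: pd.DataFrame
    station_cell: tuple[int, int]
    latitude: float

    def __post_init__(self) -> None:
        missing = {"date", "tmin_c", "tmax_c", "srad_mj_m2", "rain_mm"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"weather frame missing columns: {sorted(missing)}")

    @property
    def tmean(self) -> pd.Series:
        return (self.frame["tmin_c"] + self.frame["tmax_c"]) / 2.0

    def year_slice(self, year: int) -> pd.DataFrame:
        dates = pd.DatetimeIndex(self.frame["date"])
        return self.frame.loc[dates.year == year].reset_index(drop=True)

    @property
    def years(self) -> list[int]:
        return sorted(pd.DatetimeIndex(self.frame["date"]).year.unique().tolist())


@dataclass(frozen=True)
class SoilProfile:
    """Single-layer soil: plant-available water capacity and its area share."""

    paw_capacity_mm: float
    area_share: float = 1.0

    def __post_init__(self) -> None:
        if self.paw_capacity_mm <= 0:
            raise ValueError("paw_capacity_mm must be positive")
        if not 0 < self.area_share <= 1:
            raise ValueError("area_share must lie in (0, 1]")


def contraction_kernel(
    shape: tuple[int, int], center: tuple[int, int], radius: float
) -> np.ndarray:
    """Normalized exponential-decay loss kernel around an urban center.

    Weight of cell i is exp(-d_i / radius) for center distances d_i up to
    3*radius (grid units), zero beyond, normalized to sum to 1.  A zero
    radius collapses all loss onto the center cell.
    """
    nr, nc = shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    if radius == 0:
        w = (d == 0).astype(float)
    else:
        w = np.where(d <= 3.0 * radius, np.exp(-d / radius), 0.0)
    return w / w.sum()


def _base_area_field(config: LandscapeConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive base harvested-area surface (ha per cell)."""
    nr, nc = config.grid_shape
    field_ = rng.lognormal(
        mean=0.0, sigma=np.sqrt(np.log(1.0 + config.base_area_cv**2)), size=(nr, nc)
    )
    # cheap box smoothing keeps the surface spatially coherent
    for _ in range(config.base_smoothing):
        padded = np.pad(field_, 1, mode="edge")
        field_ = (
            padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:] + padded[1:-1, 1:-1]
        ) / 5.0
    field_ *= config.base_area_mean / field_.mean()
    return np.minimum(field_, config.cell_area_ha)


def _expansion_mask(config: LandscapeConfig) -> np.ndarray:
    nr, nc = config.grid_shape
    mask = np.zeros((nr, nc), dtype=bool)
    if config.expansion_region is not None:
        r0, r1, c0, c1 = config.expansion_region
        mask[r0:r1, c0:c1] = True
    return mask


def generate_area_grids(
    config: LandscapeConfig,
) -> tuple[dict[str, CropAreaGrid], dict[str, CropAreaGrid]]:
    """Generate two 3-year harvested-area epochs per water regime.

    Epoch 2 differs from epoch 1 by exponential-kernel losses around each
    urban center (urban conversion) and a uniform gain inside the expansion
    box (frontier expansion).  Yearly grids within an epoch are the epoch
    surface perturbed by multiplicative noise of CV ``year_noise_cv``.

    Raises ``ValueError`` if the expansion box intersects the truncated
    contraction kernel of any urban center (the two change processes must
    act on disjoint cells so their totals are separately recoverable).
    """
    exp_mask = _expansion_mask(config)
    if exp_mask.any() and config.urban_centers:
        nr, nc = config.grid_shape
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        for (r, c), _loss in config.urban_centers:
            d = np.hypot(rr - r, cc - c)
            reach = d <= max(3.0 * config.contraction_radius, 0.0)
            if (reach & exp_mask).any():
                raise ValueError("contraction and expansion descriptors overlap")

    rng = child_rng(config.seed, _STREAM_AREA)
    epoch1: dict[str, CropAreaGrid] = {}
    epoch2: dict[str, CropAreaGrid] = {}
    for regime in config.water_regimes:
        share = config.irrigated_share if regime == "irrigated" else 1.0 - config.irrigated_share
        if len(config.water_regimes) == 1:
            share = 1.0
        base = _base_area_field(config, rng) * share

        loss = np.zeros_like(base)
        for center, total_loss in config.urban_centers:
            loss += total_loss * share * contraction_kernel(config.grid_shape, center, config.contraction_radius)
        loss = np.minimum(loss, base)  # cannot lose more area than a cell holds

        gain = np.zeros_like(base)
        if exp_mask.any() and config.expansion_total_ha > 0:
            gain[exp_mask] = config.expansion_total_ha * share / exp_mask.sum()

        surface1 = base
        surface2 = np.clip(base - loss + gain, 0.0, config.cell_area_ha)

        stacks = []
        for surface, years in zip((surface1, surface2), config.epoch_years):
            noise = rng.normal(0.0, config.year_noise_cv, size=(len(years),) + surface.shape)
            yearly = np.maximum(0.0, surface[None, :, :] * (1.0 + noise))
            stacks.append(
                CropAreaGrid(
                    data=yearly,
                    years=tuple(years),
                    crop=config.crop,
                    water_regime=regime,
                    cell_area_ha=config.cell_area_ha,
                    cell_km=config.cell_km,
                )
            )
        epoch1[regime], epoch2[regime] = stacks
    return epoch1, epoch2


def _calendar_dates(start_year: int, years: int) -> pd.DatetimeIndex:
    return pd.date_range(
        start=f"{start_year}-01-01", end=f"{start_year + years - 1}-12-31", freq="D"
    )


def generate_weather(
    station_cell: tuple[int, int],
    years: int,
    params: ClimateParams,
    seed: int,
    start_year: int = 2001,
) -> WeatherSeries:
    """Generate a complete multi-year daily weather record for one station.

    Guarantees: no missing days, tmax >= tmin everywhere, radiation > 0,
    rain >= 0, and the expected annual rainfall equals the row's configured
    annual total.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    row = int(station_cell[0])
    rng = child_rng(seed, _STREAM_WEATHER, row, int(station_cell[1]))
    dates = _calendar_dates(start_year, years)
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    season = np.sin(2.0 * np.pi * (doy - (params.peak_doy - 365.25 / 4.0)) / 365.25)

    tmean = (
        params.row_mean_temp(row)
        + params.seasonal_amplitude * season
        + params.temp_daily_sd * rng.standard_normal(n)
    )
    tmin = tmean - params.diurnal_range / 2.0
    tmax = tmean + params.diurnal_range / 2.0

    srad = (
        params.radiation_mean
        + params.radiation_amplitude * season
        + params.rad_daily_sd * rng.standard_normal(n)
    )
    srad = np.maximum(srad, 0.5)

    annual_rain = float(params.row_annual_rain(row))
    year_index = dates.year.to_numpy() - start_year
    year_mult = np.maximum(0.0, 1.0 + params.interannual_sd * rng.standard_normal(years))
    is_rain_day = rng.random(n) < params.rain_days_fraction
    if params.rain_days_fraction > 0:
        mean_amount = annual_rain / (365.25 * params.rain_days_fraction)
    else:
        mean_amount = 0.0
    if params.rain_amount_cv > 0:
        shape = 1.0 / params.rain_amount_cv**2
        amounts = rng.gamma(shape, scale=mean_amount / shape, size=n)
    else:
        amounts = np.full(n, mean_amount)
    rain = np.where(is_rain_day, amounts, 0.0) * year_mult[year_index]

    frame = pd.DataFrame(
        {
            "date": dates,
            "tmin_c": tmin,
            "tmax_c": tmax,
            "srad_mj_m2": srad,
            "rain_mm": rain,
        }
    )
    return WeatherSeries(
        frame=frame,
        station_cell=(int(station_cell[0]), int(station_cell[1])),
        latitude=float(params.row_latitude(row)),
    )


def generate_stations(
    area_grid: np.ndarray | CropAreaGrid, n: int, seed: int
) -> list[tuple[int, int]]:
    """Sample ``n`` distinct station cells with probability ~ harvested area.

    Mirrors real weather-station networks, which concentrate where
    agriculture (and people) are.  Raises if ``n`` exceeds the number of
    cells with nonzero area.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = area_grid.epoch_mean() if isinstance(area_grid, CropAreaGrid) else np.asarray(area_grid, dtype=float)
    flat = grid.reshape(-1)
    nonzero = int((flat > 0).sum())
    if n > nonzero:
        raise ValueError(f"requested {n} stations but only {nonzero} cells have crop area")
    rng = child_rng(seed, _STREAM_STATIONS)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    nc = grid.shape[1]
    cells = sorted((int(i // nc), int(i % nc)) for i in idx)
    return cells


def generate_soils(
    buffer_count: int,
    seed: int,
    n_soils: tuple[int, int] = (2, 3),
    paw_range: tuple[float, float] = (50.0, 250.0),
) -> list[list[SoilProfile]]:
    """Draw 2-3 dominant soil types per buffer with area shares summing to 1.

    Plant-available water capacities are uniform on ``paw_range`` mm; shares
    come from a flat Dirichlet, so they are each in (0, 1] and sum to one by
    construction.
    """
    rng = child_rng(seed, _STREAM_SOILS)
    out: list[list[SoilProfile]] = []
    for _ in range(buffer_count):
        k = int(rng.integers(n_soils[0], n_soils[1] + 1))
        paw = rng.uniform(*paw_range, size=k)
        shares = rng.dirichlet(np.ones(k))
        shares = shares / shares.sum()
        out.append(
            [SoilProfile(paw_capacity_mm=float(p), area_share=float(s)) for p, s in zip(paw, shares)]
        )
    return out
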