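"""Climate-zone variables and zonation.

Zones are delimited by binning three agro-climatic variables per cell:
growing degree days (annual thermal-time accumulation), temperature
seasonality (standard deviation of the twelve climatological monthly mean
temperatures), and the aridity index (annual precipitation over annual
potential evapotranspiration).  Cells sharing the same bin triple share a
zone.

PET uses the Hargreaves-Samani equation with FAO-56 extraterrestrial
radiation: it needs only daily temperature extremes and latitude, which is
all a sparse station network reliably provides.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ClimateParams, WeatherSeries

__all__ = [
    "ClimateMetrics",
    "ClimateZoneMap",
    "growing_degree_days",
    "temperature_seasonality",
    "extraterrestrial_radiation",
    "hargreaves_pet",
    "potential_evapotranspiration",
    "aridity_index",
    "delimit_zones",
    "grid_climate_metrics",
    "DEFAULT_GDD_BIN_WIDTH",
    "DEFAULT_SEASONALITY_BIN_WIDTH",
    "DEFAULT_ARIDITY_EDGES",
]

# Default bin geometry. Published climate-zone schemes use calibrated edges;
# these defaults preserve the mechanism and are fully configurable.
DEFAULT_GDD_BIN_WIDTH = 1000.0  # degC-days
DEFAULT_SEASONALITY_BIN_WIDTH = 5.0  # degC
DEFAULT_ARIDITY_EDGES = (0.2, 0.5, 0.65, 1.0)

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
_MJ_TO_MM = 0.408  # latent-heat conversion, FAO-56


@dataclass(frozen=True)
class ClimateMetrics:
    """The three zonation variables for one cell or station."""

    gdd: float
    seasonality: float
    aridity: float

    def __post_init__(self) -> None:
        if self.gdd < 0 or self.seasonality < 0 or self.aridity < 0:
            raise ValueError("climate metrics must be non-negative")


@dataclass(frozen=True)
class ClimateZoneMap:
    """Integer zone label per cell plus the bin edges that define the zoning."""

    zone_id: np.ndarray
    bin_edges: dict[str, np.ndarray]
    zone_triples: dict[int, tuple[int, int, int]]

    @property
    def n_zones(self) -> int:
        return len(self.zone_triples)


def growing_degree_days(
    daily_mean_temp: np.ndarray | pd.Series,
    base_temp: float,
    cap: float | None = None,
) -> float:
    """Thermal time: sum over days of max(0, min(T, cap) - base), degC-days."""
    t = np.asarray(daily_mean_temp, dtype=float)
    if t.size == 0:
        raise ValueError("temperature series is empty")
    if cap is not None:
        if cap < base_temp:
            raise ValueError("cap must be >= base_temp")
        t = np.minimum(t, cap)
    return float(np.maximum(0.0, t - base_temp).sum())


def temperature_seasonality(
    dates: pd.DatetimeIndex | pd.Series, daily_mean_temp: np.ndarray | pd.Series
) -> float:
    """SD (population) of the 12 climatological monthly mean temperatures.

    Requires every calendar month to be represented and every contributing
    (year, month) block to be complete; partial months would bias the
    climatology and are rejected.
    """
    dates = pd.DatetimeIndex(dates)
    t = np.asarray(daily_mean_temp, dtype=float)
    if len(dates) != len(t):
        raise ValueError("dates and temperatures differ in length")
    frame = pd.DataFrame({"t": t, "year": dates.year, "month": dates.month})
    sizes = frame.groupby(["year", "month"]).size()
    for (year, month), n_days in sizes.items():
        if n_days != calendar.monthrange(int(year), int(month))[1]:
            raise ValueError(f"incomplete month {year}-{month:02d}: {n_days} days")
    monthly = frame.groupby(["year", "month"])["t"].mean()
    climatology = monthly.groupby(level="month").mean()
    if len(climatology) != 12:
        raise ValueError("need all 12 calendar months to compute seasonality")
    return float(np.std(climatology.to_numpy(), ddof=0))


def extraterrestrial_radiation(latitude_deg: float, doy: np.ndarray | int) -> np.ndarray:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1), FAO-56 eq. 21."""
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    omega_s = np.arccos(x)
    ra = (
        24.0 * 60.0 / np.pi
        * _SOLAR_CONSTANT
        * dr
        * (omega_s * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(omega_s))
    )
    return np.maximum(ra, 0.0)


def hargreaves_pet(
    tmin: np.ndarray, tmax: np.ndarray, ra: np.ndarray
) -> np.ndarray:
    """Hargreaves-Samani reference evapotranspiration, mm per day.

    ET0 = 0.0023 * Ra[mm] * (Tmean + 17.8) * sqrt(Tmax - Tmin).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    ra = np.asarray(ra, dtype=float)
    if np.any(np.isnan(tmin)) or np.any(np.isnan(tmax)) or np.any(np.isnan(ra)):
        raise ValueError("missing temperature or radiation values")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin encountered")
    tmean = (tmin + tmax) / 2.0
    pet = 0.0023 * ra * _MJ_TO_MM * (tmean + 17.8) * np.sqrt(tmax - tmin)
    return np.maximum(pet, 0.0)


def potential_evapotranspiration(weather: WeatherSeries) -> pd.Series:
    """Daily Hargreaves PET series (mm) for a station record."""
    dates = pd.DatetimeIndex(weather.frame["date"])
    ra = extraterrestrial_radiation(weather.latitude, dates.dayofyear.to_numpy())
    pet = hargreaves_pet(
        weather.frame["tmin_c"].to_numpy(), weather.frame["tmax_c"].to_numpy(), ra
    )
    return pd.Series(pet, index=weather.frame.index, name="pet_mm")


def aridity_index(annual_precip: float, annual_pet: float) -> float:
    """Annual precipitation over annual PET (dimensionless, >= 0)."""
    if annual_pet <= 0:
        raise ValueError("annual_pet must be positive")
    if annual_precip < 0:
        raise ValueError("annual_precip must be non-negative")
    return float(annual_precip) / float(annual_pet)


def _check_edges(edges: np.ndarray, name: str) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
        raise ValueError(f"{name} bin edges must be strictly increasing 1-D")
    return edges


def default_bin_edges(
    gdd_max: float = 12_000.0, seasonality_max: float = 30.0
) -> dict[str, np.ndarray]:
    return {
        "gdd": np.arange(DEFAULT_GDD_BIN_WIDTH, gdd_max, DEFAULT_GDD_BIN_WIDTH),
        "seasonality": np.arange(
            DEFAULT_SEASONALITY_BIN_WIDTH, seasonality_max, DEFAULT_SEASONALITY_BIN_WIDTH
        ),
        "aridity": np.asarray(DEFAULT_ARIDITY_EDGES, dtype=float),
    }


def delimit_zones(
    gdd: np.ndarray,
    seasonality: np.ndarray,
    aridity: np.ndarray,
    bin_edges: dict[str, np.ndarray] | None = None,
) -> ClimateZoneMap:
    """Bin the three metrics per cell and label zones by distinct bin triples.

    Zone ids are assigned by lexicographic order of the (gdd bin,
    seasonality bin, aridity bin) triples, so the labelling is a pure
    function of the metric values and edges, independent of cell order.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    gdd = np.asarray(gdd, dtype=float)
    seasonality = np.asarray(seasonality, dtype=float)
    aridity = np.asarray(aridity, dtype=float)
    if not (gdd.shape == seasonality.shape == aridity.shape):
        raise ValueError("metric grids must share a shape")
    if not (np.all(np.isfinite(gdd)) and np.all(np.isfinite(seasonality)) and np.all(np.isfinite(aridity))):
        raise ValueError("metrics must be finite")
    edges = {k: _check_edges(bin_edges[k], k) for k in ("gdd", "seasonality", "aridity")}

    bins = np.stack(
        [
            np.digitize(gdd, edges["gdd"]),
            np.digitize(seasonality, edges["seasonality"]),
            np.digitize(aridity, edges["aridity"]),
        ],
        axis=-1,
    )
    flat = bins.reshape(-1, 3)
    triples = sorted({tuple(int(v) for v in row) for row in flat})
    lookup = {t: i for i, t in enumerate(triples)}
    zone_id = np.array([lookup[tuple(int(v) for v in row)] for row in flat]).reshape(gdd.shape)
    return ClimateZoneMap(
        zone_id=zone_id,
        bin_edges=edges,
        zone_triples={i: t for t, i in lookup.items()},
    )


def grid_climate_metrics(
    grid_shape: tuple[int, int],
    params: ClimateParams,
    base_temp: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell GDD, seasonality, and aridity from the deterministic climatology.

    The synthetic climate varies only along rows (a latitudinal gradient),
    so metrics are computed on the 365-day noise-free seasonal cycle per row
    and broadcast across columns.  Zonation on the expected climate rather
    than on one noisy realization mirrors gridded climate surfaces, which
    are long-term normals.
    """
    nr, nc = grid_shape
    doy = np.arange(1, 366, dtype=float)
    season = np.sin(2.0 * np.pi * (doy - (params.peak_doy - 365.25 / 4.0)) / 365.25)
    rows = np.arange(nr)
    tmean = params.row_mean_temp(rows)[:, None] + params.seasonal_amplitude * season[None, :]

    gdd = np.maximum(0.0, tmean - base_temp).sum(axis=1)

    # monthly climatology from the noise-free cycle (non-leap calendar)
    month_len = np.array([calendar.monthrange(2001, m)[1] for m in range(1, 13)])
    month_of_doy = np.repeat(np.arange(12), month_len)
    monthly = np.stack([tmean[:, month_of_doy == m].mean(axis=1) for m in range(12)], axis=1)
    seasonality = monthly.std(axis=1, ddof=0)

    tmin = tmean - params.diurnal_range / 2.0
    tmax = tmean + params.diurnal_range / 2.0
    lat = params.row_latitude(rows)
    annual_pet = np.array(
        [
            hargreaves_pet(tmin[i], tmax[i], extraterrestrial_radiation(lat[i], doy)).sum()
            for i in range(nr)
        ]
    )
    annual_rain = params.row_annual_rain(rows)
    aridity = np.array(
        [aridity_index(float(annual_rain[i]), float(annual_pet[i])) for i in range(nr)]
    )

    tile = lambda v: np.repeat(v[:, None], nc, axis=1)  # noqa: E731
    return tile(gdd), tile(seasonality), tile(aridity)
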