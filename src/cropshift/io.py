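"""Reading and writing pipeline artifacts.

CSV (long format) is the primary interchange; area-grid stacks and zone maps
can additionally be exported as multi-band TIFF with a JSON sidecar holding
the lattice metadata (cell size, years, crop, regime).  All text artifacts
are deterministic for a fixed seed and configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

from .synthetic import CropAreaGrid, WeatherSeries

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import PipelineResult

__all__ = [
    "write_area_grid_csv",
    "read_area_grid_csv",
    "write_area_grid_tiff",
    "read_area_grid_tiff",
    "write_weather_csv",
    "read_weather_csv",
    "write_zone_map_csv",
]

_FLOAT_FMT = "%.6f"


def write_area_grid_csv(grid: CropAreaGrid, path: str | Path) -> Path:
    path = Path(path)
    grid.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_area_grid_csv(path: str | Path) -> CropAreaGrid:
    frame = pd.read_csv(path)
    years = tuple(sorted(frame["year"].unique()))
    nr = int(frame["row"].max()) + 1
    nc = int(frame["col"].max()) + 1
    data = np.zeros((len(years), nr, nc))
    for i, year in enumerate(years):
        sub = frame[frame["year"] == year]
        data[i, sub["row"].to_numpy(), sub["col"].to_numpy()] = sub["area_ha"].to_numpy()
    return CropAreaGrid(
        data=data,
        years=years,
        crop=str(frame["crop"].iloc[0]),
        water_regime=str(frame["water_regime"].iloc[0]),
    )


def write_area_grid_tiff(grid: CropAreaGrid, path: str | Path) -> Path:
    """One TIFF band per year; lattice metadata in a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, grid.data.astype(np.float32), photometric="minisblack")
    sidecar = {
        "years": list(grid.years),
        "crop": grid.crop,
        "water_regime": grid.water_regime,
        "cell_area_ha": grid.cell_area_ha,
        "cell_km": grid.cell_km,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_area_grid_tiff(path: str | Path) -> CropAreaGrid:
    import tifffile

    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return CropAreaGrid(
        data=data,
        years=tuple(meta["years"]),
        crop=meta["crop"],
        water_regime=meta["water_regime"],
        cell_area_ha=meta["cell_area_ha"],
        cell_km=meta["cell_km"],
    )


def write_weather_csv(weather: WeatherSeries, path: str | Path) -> Path:
    path = Path(path)
    frame = weather.frame.copy()
    frame["date"] = pd.DatetimeIndex(frame["date"]).strftime("%Y-%m-%d")
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"station_cell": list(weather.station_cell), "latitude": weather.latitude}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))
    return path


def read_weather_csv(path: str | Path) -> WeatherSeries:
    path = Path(path)
    frame = pd.read_csv(path, parse_dates=["date"])
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return WeatherSeries(
        frame=frame, station_cell=tuple(meta["station_cell"]), latitude=meta["latitude"]
    )


def write_zone_map_csv(zone_id: np.ndarray, path: str | Path) -> Path:
    nr, nc = zone_id.shape
    frame = pd.DataFrame(
        {
            "row": np.repeat(np.arange(nr), nc),
            "col": np.tile(np.arange(nc), nr),
            "zone_id": zone_id.reshape(-1),
        }
    )
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def _outdir(outdir: str | Path) -> Path:
    path = Path(outdir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def write_stage_generate(outdir: str | Path, result: "PipelineResult") -> None:
    out = _outdir(outdir)
    write_area_grid_csv(result.epoch1, out / "area_epoch1.csv")
    write_area_grid_csv(result.epoch2, out / "area_epoch2.csv")
    pd.DataFrame(result.stations, columns=["row", "col"]).to_csv(
        out / "stations.csv", index=False
    )
    config_dump = {
        "seed": result.config.seed,
        "crop": result.config.landscape.crop,
        "water_regime": result.config.water_regime,
        "grid_shape": list(result.config.landscape.grid_shape),
        "weather_years": result.config.weather_years,
    }
    (out / "run_config.yaml").write_text(yaml.safe_dump(config_dump, sort_keys=True))


def write_stage_zones(
    outdir: str | Path,
    result: "PipelineResult",
    gdd: np.ndarray,
    seasonality: np.ndarray,
    aridity: np.ndarray,
) -> None:
    out = _outdir(outdir)
    write_zone_map_csv(result.zones.zone_id, out / "zones.csv")
    nr, nc = gdd.shape
    pd.DataFrame(
        {
            "row": np.repeat(np.arange(nr), nc),
            "col": np.tile(np.arange(nc), nr),
            "gdd": gdd.reshape(-1),
            "seasonality": seasonality.reshape(-1),
            "aridity": aridity.reshape(-1),
        }
    ).to_csv(out / "climate_metrics.csv", index=False, float_format=_FLOAT_FMT)


def write_stage_buffers(outdir: str | Path, result: "PipelineResult") -> None:
    out = _outdir(outdir)
    rows = []
    for buf in result.selected:
        for r, c in sorted(buf.member_cells):
            rows.append({"station_id": buf.station_id, "row": r, "col": c, "cz_id": buf.cz_id})
    pd.DataFrame(rows, columns=["station_id", "row", "col", "cz_id"]).to_csv(
        out / "buffer_membership.csv", index=False
    )
    result.selection_trace.to_csv(out / "selection_trace.csv", index=False, float_format=_FLOAT_FMT)


def write_stage_change(outdir: str | Path, result: "PipelineResult") -> None:
    out = _outdir(outdir)
    delta = result.change.delta
    nr, nc = delta.shape
    pd.DataFrame(
        {
            "row": np.repeat(np.arange(nr), nc),
            "col": np.tile(np.arange(nc), nr),
            "delta_ha": delta.reshape(-1),
            "displayed": result.change.display_mask.reshape(-1),
            "change_class": result.change.change_class.reshape(-1),
        }
    ).to_csv(out / "area_change.csv", index=False, float_format=_FLOAT_FMT)


def write_stage_simulate(outdir: str | Path, result: "PipelineResult") -> None:
    out = _outdir(outdir)
    result.sites_frame().to_csv(out / "site_yields.csv", index=False, float_format=_FLOAT_FMT)
    rows = []
    for s in result.sites:
        for year_idx, y in enumerate(s.yearly_annual_yield):
            rows.append({"buffer_id": s.buffer_id, "year_index": year_idx, "annual_yield_t_ha": y})
    pd.DataFrame(rows, columns=["buffer_id", "year_index", "annual_yield_t_ha"]).to_csv(
        out / "site_yearly_yields.csv", index=False, float_format=_FLOAT_FMT
    )


def write_stage_report(outdir: str | Path, result: "PipelineResult") -> None:
    out = _outdir(outdir)
    result.report.to_frame().to_csv(out / "report.csv", index=False, float_format=_FLOAT_FMT)
    (out / "report.txt").write_text(result.report.to_text())
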