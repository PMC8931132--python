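"""End-to-end pipeline: synthetic landscape -> climate zones -> buffers ->
crop simulation -> area change -> national yield-ratio report.

Every stage is seeded from the single pipeline seed, so a fixed seed and
configuration reproduce the report bit-for-bit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as _io
from .aggregate import YieldRatioReport, build_report
from .buffers import (
    BufferZone,
    SelectionConfig,
    filter_zones_by_share,
    make_clipped_buffer,
    select_buffers,
)
from .change import ChangeGrid, buffer_net_balance, classify_change, flag_significant, net_change
from .climate import ClimateZoneMap, delimit_zones, grid_climate_metrics
from .cropsim import CropSequence, SiteYield, SoilProfile, site_yield_potential
from .synthetic import (
    ClimateParams,
    CropAreaGrid,
    LandscapeConfig,
    generate_area_grids,
    generate_soils,
    generate_stations,
    generate_weather,
)

__all__ = ["SequenceRule", "PipelineConfig", "PipelineResult", "run_pipeline", "STAGES"]

logger = logging.getLogger("cropshift")

STAGES = ("generate", "zones", "buffers", "change", "simulate", "report")


@dataclass(frozen=True)
class SequenceRule:
    """Cropping-system assignment by row band (half-open [row_min, row_max)).

    Stands in for per-site cropping-system surveys: which sequences are
    grown, and on what share of the area, is an input of the analysis, not
    something the model predicts.
    """

    row_min: int
    row_max: int
    sequences: tuple[CropSequence, ...]


@dataclass(frozen=True)
class PipelineConfig:
    landscape: LandscapeConfig
    climate: ClimateParams = field(default_factory=ClimateParams)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    water_regime: str = "irrigated"
    weather_years: int = 12
    weather_start_year: int = 2009
    n_stations: int = 12
    sequence_rules: tuple[SequenceRule, ...] = ()
    default_sequences: tuple[CropSequence, ...] = ()
    fixed_soil: SoilProfile | None = None
    init_mode: str = "fixed_fraction"
    init_fraction: float = 0.5
    zone_bin_edges: dict | None = None
    zone_base_temp: float = 0.0
    seed: int = 0

    def sequences_for_row(self, row: int) -> tuple[CropSequence, ...]:
        for rule in self.sequence_rules:
            if rule.row_min <= row < rule.row_max:
                return rule.sequences
        if not self.default_sequences:
            raise ValueError(f"no sequence rule covers row {row} and no default set")
        return self.default_sequences

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, landscape=replace(self.landscape, seed=seed))


@dataclass
class PipelineResult:
    config: PipelineConfig
    epoch1: CropAreaGrid | None = None
    epoch2: CropAreaGrid | None = None
    stations: list[tuple[int, int]] | None = None
    zones: ClimateZoneMap | None = None
    candidates: list[BufferZone] | None = None
    selected: list[BufferZone] | None = None
    selection_trace: pd.DataFrame | None = None
    national_area: float | None = None
    change: ChangeGrid | None = None
    sites: list[SiteYield] | None = None
    cz_area_shares: dict[int, float] | None = None
    report: YieldRatioReport | None = None

    def sites_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites or []:
            rows.append(
                {
                    "buffer_id": s.buffer_id,
                    "cz_id": s.cz_id,
                    "mean_annual_yield_t_ha": s.mean_annual_yield,
                    "cv_percent": s.cv_percent,
                    "crop_intensity": s.crop_intensity,
                    "irrigated_share": s.irrigated_share,
                    "net_balance_ha": s.net_balance_ha,
                    "flag": s.flag,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "buffer_id",
                "cz_id",
                "mean_annual_yield_t_ha",
                "cv_percent",
                "crop_intensity",
                "irrigated_share",
                "net_balance_ha",
                "flag",
            ],
        )


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-9s done in %.2f s", name, t1 - t0)
    return t1


def run_pipeline(
    config: PipelineConfig, outdir: str | None = None, upto: str = "report"
) -> PipelineResult:
    """Run the analysis chain up to stage ``upto``.

    Stages, in order: generate, zones, buffers, change, simulate, report.
    If ``outdir`` is given, each completed stage writes its artifacts there
    as CSV/text; stage timings go to the ``cropshift`` logger.
    """
    if upto not in STAGES:
        raise ValueError(f"upto must be one of {STAGES}")
    upto_idx = STAGES.index(upto)
    result = PipelineResult(config=config)
    regime = config.water_regime
    t0 = time.perf_counter()

    try:
        # --- generate: area grids, stations ---
        epoch1_all, epoch2_all = generate_area_grids(config.landscape)
        if regime not in epoch1_all:
            raise ValueError(f"landscape does not include water regime {regime!r}")
        result.epoch1, result.epoch2 = epoch1_all[regime], epoch2_all[regime]
        e1_mean = result.epoch1.epoch_mean()
        result.national_area = float(e1_mean.sum())
        result.stations = generate_stations(e1_mean, config.n_stations, config.seed)
        t0 = _stage("generate", t0)
        if outdir is not None:
            _io.write_stage_generate(outdir, result)
        if upto_idx < 1:
            return result

        # --- zones ---
        gdd, seas, arid = grid_climate_metrics(
            config.landscape.grid_shape, config.climate, base_temp=config.zone_base_temp
        )
        result.zones = delimit_zones(gdd, seas, arid, config.zone_bin_edges)
        shares = {}
        for cz in result.zones.zone_triples:
            shares[cz] = float(e1_mean[result.zones.zone_id == cz].sum()) / result.national_area
        result.cz_area_shares = shares
        t0 = _stage("zones", t0)
        if outdir is not None:
            _io.write_stage_zones(outdir, result, gdd, seas, arid)
        if upto_idx < 2:
            return result

        # --- buffers ---
        cz_area = {cz: share * result.national_area for cz, share in shares.items()}
        candidates = [
            make_clipped_buffer(
                station_id=i,
                station_cell=cell,
                radius_km=config.selection.radius_km,
                cz_map=result.zones,
                area_grid=e1_mean,
                cell_km=config.landscape.cell_km,
                national_area=result.national_area,
            )
            for i, cell in enumerate(result.stations)
        ]
        result.candidates = candidates
        eligible = filter_zones_by_share(
            candidates, cz_area, result.national_area, config.selection.min_cz_share
        )
        result.selected, result.selection_trace = select_buffers(
            eligible, result.national_area, config.selection
        )
        t0 = _stage("buffers", t0)
        if outdir is not None:
            _io.write_stage_buffers(outdir, result)
        if upto_idx < 3:
            return result

        # --- change ---
        delta = net_change(result.epoch2.epoch_mean(), e1_mean)
        result.change = classify_change(delta, e1_mean)
        t0 = _stage("change", t0)
        if outdir is not None:
            _io.write_stage_change(outdir, result)
        if upto_idx < 4:
            return result

        # --- simulate ---
        sites: list[SiteYield] = []
        for buf in result.selected:
            weather = generate_weather(
                buf.station_cell,
                config.weather_years,
                config.climate,
                config.seed,
                start_year=config.weather_start_year,
            )
            if config.fixed_soil is not None:
                soils = [config.fixed_soil]
            else:
                soils = generate_soils(1, seed=config.seed * 100_003 + buf.station_id)[0]
            sequences = list(config.sequences_for_row(buf.station_cell[0]))
            site = site_yield_potential(
                weather,
                soils,
                sequences,
                regime,
                init_mode=config.init_mode,
                init_fraction=config.init_fraction,
            )
            site.buffer_id = buf.station_id
            site.cz_id = buf.cz_id
            balance = buffer_net_balance(delta, buf)
            site.net_balance_ha = balance
            site.flag = flag_significant(balance, config.landscape.crop)
            sites.append(site)
        result.sites = sites
        t0 = _stage("simulate", t0)
        if outdir is not None:
            _io.write_stage_simulate(outdir, result)
        if upto_idx < 5:
            return result

        # --- report ---
        flagged = [s for s in sites if s.flag in ("contracting", "expanding")]
        result.report = build_report(flagged, shares, crop=config.landscape.crop)
        _stage("report", t0)
        if outdir is not None:
            _io.write_stage_report(outdir, result)
        return result
    except Exception as exc:  # tag failures with the stage for diagnostics
        done = sum(
            x is not None
            for x in (result.epoch1, result.zones, result.selected, result.change, result.sites)
        )
        stage = STAGES[min(done, len(STAGES) - 1)]
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
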