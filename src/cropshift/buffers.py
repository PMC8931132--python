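"""Weather-station buffer zones and the sequential selection algorithm.

A buffer ("site") is the set of grid cells whose centers lie within a fixed
radius (default 100 km) of a weather station AND share the station's climate
zone — clipping by zone borders keeps temperature and rainfall regimes
relatively uniform within the buffer.  Buffers are then selected greedily by
harvested area, subject to a minimum national area share and a maximum
pairwise overlap, until roughly half the national harvested area is covered.

Conventions the selection depends on (stated because the rules leave them
open): the overlap fraction is measured relative to the candidate being
tested, which is the stricter and order-consistent reading; coverage stops
at the first crossing of the target; ties in harvested area break by
ascending station id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateZoneMap

__all__ = [
    "BufferZone",
    "SelectionConfig",
    "make_clipped_buffer",
    "overlap_fraction",
    "select_buffers",
    "national_coverage",
    "filter_zones_by_share",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the buffer-selection procedure (fractions of national area)."""

    min_cz_share: float = 0.05
    min_buffer_share: float = 0.01
    max_overlap: float = 0.20
    coverage_target: float = 0.50
    radius_km: float = 100.0

    def __post_init__(self) -> None:
        for name in ("min_cz_share", "min_buffer_share", "max_overlap", "coverage_target"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.radius_km <= 0:
            raise ValueError("radius_km must be positive")


@dataclass(frozen=True)
class BufferZone:
    """A station buffer clipped to the station's climate zone."""

    station_id: int
    station_cell: Cell
    cz_id: int
    member_cells: frozenset[Cell]
    cell_areas: dict[Cell, float] = field(compare=False)
    harvested_area: float = 0.0
    national_share: float = 0.0

    def __post_init__(self) -> None:
        if self.harvested_area < 0:
            raise ValueError("harvested_area must be non-negative")
        if not 0 <= self.national_share <= 1:
            raise ValueError("national_share must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.member_cells)


def make_clipped_buffer(
    station_id: int,
    station_cell: Cell,
    radius_km: float,
    cz_map: ClimateZoneMap,
    area_grid: np.ndarray,
    cell_km: float = 10.0,
    national_area: float | None = None,
) -> BufferZone:
    """Build one buffer: disc of ``radius_km`` around the station, clipped to
    the station's climate zone.

    Distances are Euclidean between cell centers on the equal-area lattice
    (grid offsets times ``cell_km``).  Harvested area is summed over member
    cells of ``area_grid`` (ha per cell).
    """
    area_grid = np.asarray(area_grid, dtype=float)
    nr, nc = area_grid.shape
    r0, c0 = station_cell
    if not (0 <= r0 < nr and 0 <= c0 < nc):
        raise ValueError(f"station {station_cell} outside grid {area_grid.shape}")
    zone = int(cz_map.zone_id[r0, c0])

    radius_cells = radius_km / cell_km
    reach = int(np.floor(radius_cells))
    rr = np.arange(max(0, r0 - reach), min(nr, r0 + reach + 1))
    cc = np.arange(max(0, c0 - reach), min(nc, c0 + reach + 1))
    rmesh, cmesh = np.meshgrid(rr, cc, indexing="ij")
    dist = np.hypot(rmesh - r0, cmesh - c0)
    inside = (dist <= radius_cells) & (cz_map.zone_id[np.ix_(rr, cc)] == zone)

    cells = frozenset((int(r), int(c)) for r, c in zip(rmesh[inside], cmesh[inside]))
    cell_areas = {cell: float(area_grid[cell]) for cell in cells}
    harvested = float(sum(cell_areas.values()))
    share = harvested / national_area if national_area else 0.0
    return BufferZone(
        station_id=int(station_id),
        station_cell=(int(r0), int(c0)),
        cz_id=zone,
        member_cells=cells,
        cell_areas=cell_areas,
        harvested_area=harvested,
        national_share=float(share),
    )


def overlap_fraction(candidate: BufferZone, other: BufferZone) -> float:
    """Shared cells as a fraction of the *candidate's* cell count."""
    if not candidate.member_cells:
        return 0.0
    shared = len(candidate.member_cells & other.member_cells)
    return shared / len(candidate.member_cells)


def filter_zones_by_share(
    candidates: list[BufferZone],
    cz_area: dict[int, float],
    national_area: float,
    min_cz_share: float = 0.05,
) -> list[BufferZone]:
    """Keep only candidates in climate zones holding > ``min_cz_share`` of
    national harvested area (crop- and regime-specific)."""
    if national_area <= 0:
        raise ValueError("national_area must be positive")
    eligible = {cz for cz, a in cz_area.items() if a / national_area > min_cz_share}
    return [b for b in candidates if b.cz_id in eligible]


def select_buffers(
    candidates: list[BufferZone],
    national_area: float,
    config: SelectionConfig | None = None,
) -> tuple[list[BufferZone], pd.DataFrame]:
    """Greedy sequential buffer selection.

    Candidates are visited by descending harvested area (ties by ascending
    station id).  A candidate is accepted iff its national share exceeds
    ``min_buffer_share`` and its overlap with every already-selected buffer
    stays below ``max_overlap``.  The loop stops at the first crossing of
    ``coverage_target`` (unique-cell harvested-area coverage) or when
    candidates run out.  Returns the selection and a per-candidate trace
    with the decision and reason.
    """
    if config is None:
        config = SelectionConfig()
    if national_area <= 0:
        raise ValueError("national_area must be positive")

    order = sorted(candidates, key=lambda b: (-b.harvested_area, b.station_id))
    selected: list[BufferZone] = []
    union_areas: dict[Cell, float] = {}
    rows = []
    coverage = 0.0
    for cand in order:
        if coverage >= config.coverage_target:
            decision, reason = "skipped", "coverage target already reached"
        elif cand.national_share <= config.min_buffer_share:
            decision, reason = "rejected", (
                f"national share {cand.national_share:.4f} <= {config.min_buffer_share}"
            )
        else:
            overlaps = [overlap_fraction(cand, s) for s in selected]
            worst = max(overlaps, default=0.0)
            if worst >= config.max_overlap:
                decision, reason = "rejected", f"overlap {worst:.3f} >= {config.max_overlap}"
            else:
                decision, reason = "accepted", "meets share and overlap rules"
                selected.append(cand)
                for cell, area in cand.cell_areas.items():
                    union_areas.setdefault(cell, area)  # count each cell once
                coverage = sum(union_areas.values()) / national_area
        rows.append(
            {
                "station_id": cand.station_id,
                "cz_id": cand.cz_id,
                "harvested_area_ha": cand.harvested_area,
                "national_share": cand.national_share,
                "decision": decision,
                "reason": reason,
                "coverage_after": coverage,
            }
        )
    trace = pd.DataFrame(
        rows,
        columns=[
            "station_id",
            "cz_id",
            "harvested_area_ha",
            "national_share",
            "decision",
            "reason",
            "coverage_after",
        ],
    )
    return selected, trace


def national_coverage(selected: list[BufferZone], national_area: float) -> float:
    """Harvested area of the union of selected member cells over the national
    total — no double counting of overlapping cells."""
    if national_area <= 0:
        raise ValueError("national_area must be positive")
    union_areas: dict[Cell, float] = {}
    for b in selected:
        for cell, area in b.cell_areas.items():
            union_areas.setdefault(cell, area)
    return sum(union_areas.values()) / national_area
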