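"""Upscaling site yields to climate-zone and national level, and the
contracting-vs-expanding yield-ratio report.

Aggregation follows two weighting stages: within a climate zone, site mean
annual yields are weighted by the absolute net area balance of their buffers
(sites losing more area dominate the "converted land" estimate, sites
gaining more dominate the "new land" estimate); across zones, zone values
are weighted by each zone's share of national harvested area, renormalized
over the zones represented on that side.  The national yield ratio is the
contracting-side weighted yield over the expanding-side weighted yield: a
ratio above one means the land being brought into production is less
productive than the land being lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cropsim import SiteYield

__all__ = [
    "YieldRatioReport",
    "cz_weighted_yield",
    "national_weighted_yield",
    "national_yield_ratio",
    "yield_stability_cv",
    "current_yield_summary",
    "build_report",
]


@dataclass
class SideSummary:
    """Balance-weighted aggregates for one side (contracting or expanding)."""

    weighted_yield: float
    crop_intensity: float
    irrigated_share: float
    cv_percent: float
    n_sites: int
    total_balance_ha: float
    cz_yields: dict[int, float] = field(default_factory=dict)


@dataclass
class YieldRatioReport:
    """National yield-ratio report in the layout of a country summary table."""

    contracting: SideSummary | None
    expanding: SideSummary | None
    yield_ratio: float | None  # full precision; display at 1 decimal
    ratio_defined: bool
    crop: str = ""
    note: str = ""

    @property
    def yield_ratio_1dp(self) -> float | None:
        return None if self.yield_ratio is None else round(self.yield_ratio, 1)

    def to_frame(self) -> pd.DataFrame:
        def col(side: SideSummary | None) -> list:
            if side is None:
                return [np.nan] * 5
            return [
                side.crop_intensity,
                side.irrigated_share * 100.0,
                side.weighted_yield,
                np.nan,
                side.cv_percent,
            ]

        frame = pd.DataFrame(
            {
                "parameter": [
                    "Crop intensity (crops/year)",
                    "Irrigation proportion (%)",
                    "Annual yield potential (t/ha)",
                    "Yield ratio",
                    "Yield stability (CV in %)",
                ],
                "converted": col(self.contracting),
                "new": col(self.expanding),
            }
        )
        if self.ratio_defined:
            frame.loc[frame["parameter"] == "Yield ratio", "converted"] = self.yield_ratio_1dp
        return frame

    def to_text(self) -> str:
        frame = self.to_frame()
        lines = [f"Yield ratio report — crop: {self.crop or 'n/a'}"]
        header = f"{'Parameter':<34}{'Converted':>12}{'New':>12}"
        lines.append(header)
        lines.append("-" * len(header))
        for _, row in frame.iterrows():
            conv = "–" if pd.isna(row["converted"]) else f"{row['converted']:.1f}"
            new = "–" if pd.isna(row["new"]) else f"{row['new']:.1f}"
            lines.append(f"{row['parameter']:<34}{conv:>12}{new:>12}")
        if not self.ratio_defined:
            lines.append("Yield ratio undefined: " + (self.note or "one side has no sites"))
        return "\n".join(lines) + "\n"


def cz_weighted_yield(sites: list[SiteYield]) -> float:
    """Net-balance-weighted mean annual yield of sites in one climate zone
    and on one side: sum(|balance| * yield) / sum(|balance|)."""
    if not sites:
        raise ValueError("need at least one site")
    flags = {s.flag for s in sites}
    if len(flags) != 1 or flags == {"none"}:
        raise ValueError(f"sites must share a contracting/expanding flag, got {flags}")
    weights = np.array([abs(s.net_balance_ha) for s in sites], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("zero total net-balance weight")
    yields = np.array([s.mean_annual_yield for s in sites], dtype=float)
    return float(np.average(yields, weights=weights))


def national_weighted_yield(
    cz_values: dict[int, float], cz_area_shares: dict[int, float]
) -> float:
    """Area-share-weighted mean of climate-zone yields, shares renormalized
    over the zones present in ``cz_values``."""
    if not cz_values:
        raise ValueError("empty climate-zone set")
    missing = set(cz_values) - set(cz_area_shares)
    if missing:
        raise ValueError(f"no area share for zones {sorted(missing)}")
    shares = np.array([cz_area_shares[cz] for cz in cz_values], dtype=float)
    if np.any(shares <= 0):
        raise ValueError("included zones must have positive area shares")
    values = np.array(list(cz_values.values()), dtype=float)
    return float(np.average(values, weights=shares))


def national_yield_ratio(contracting_yield: float, expanding_yield: float) -> float:
    """Contracting-side over expanding-side weighted yield.

    A value above one means proportionally more new land is needed to
    replace the productive capacity of each hectare lost.
    """
    if expanding_yield <= 0:
        raise ValueError("expanding_yield must be positive")
    return float(contracting_yield) / float(expanding_yield)


def yield_stability_cv(yearly_series: np.ndarray) -> float:
    """Inter-annual coefficient of variation, % (sample SD over mean)."""
    series = np.asarray(yearly_series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least two years")
    mean = series.mean()
    if mean <= 0:
        raise ValueError("mean yield must be positive")
    return float(series.std(ddof=1) / mean * 100.0)


def current_yield_summary(
    admin_yields: pd.DataFrame, window: int = 5
) -> pd.Series:
    """Recent current yield per buffer from administrative statistics.

    ``admin_yields`` columns: buffer_id, admin_unit, year, yield_t_ha,
    area_ha.  Per admin unit, the mean over its most recent ``window`` years;
    per buffer, the area-weighted mean over its admin units.
    """
    required = {"buffer_id", "admin_unit", "year", "yield_t_ha", "area_ha"}
    missing = required - set(admin_yields.columns)
    if missing:
        raise ValueError(f"admin_yields missing columns: {sorted(missing)}")
    out = {}
    for buffer_id, buf in admin_yields.groupby("buffer_id"):
        unit_means, unit_areas = [], []
        for _, unit in buf.groupby("admin_unit"):
            recent = unit.sort_values("year").tail(window)
            if recent.empty:
                raise ValueError(f"empty yield window for buffer {buffer_id}")
            unit_means.append(recent["yield_t_ha"].mean())
            unit_areas.append(recent["area_ha"].iloc[-1])
        out[buffer_id] = float(np.average(unit_means, weights=unit_areas))
    if not out:
        raise ValueError("no buffers in admin_yields")
    return pd.Series(out, name="current_yield_t_ha").sort_index()


def _side_summary(
    sites: list[SiteYield], cz_area_shares: dict[int, float]
) -> SideSummary | None:
    if not sites:
        return None
    by_cz: dict[int, list[SiteYield]] = {}
    for s in sites:
        by_cz.setdefault(s.cz_id, []).append(s)
    cz_yields = {cz: cz_weighted_yield(group) for cz, group in sorted(by_cz.items())}
    national = national_weighted_yield(cz_yields, cz_area_shares)
    weights = np.array([abs(s.net_balance_ha) for s in sites], dtype=float)
    intensity = float(np.average([s.crop_intensity for s in sites], weights=weights))
    irrigated = float(np.average([s.irrigated_share for s in sites], weights=weights))
    cv = float(np.average([s.cv_percent for s in sites], weights=weights))
    return SideSummary(
        weighted_yield=national,
        crop_intensity=intensity,
        irrigated_share=irrigated,
        cv_percent=cv,
        n_sites=len(sites),
        total_balance_ha=float(sum(s.net_balance_ha for s in sites)),
        cz_yields=cz_yields,
    )


def build_report(
    sites: list[SiteYield],
    cz_area_shares: dict[int, float],
    crop: str = "",
) -> YieldRatioReport:
    """Assemble the national yield-ratio report from flagged site yields.

    Sites flagged "none" are excluded.  If either side has no sites the
    report is still emitted with the ratio undefined and an explicit note.
    """
    contracting = _side_summary([s for s in sites if s.flag == "contracting"], cz_area_shares)
    expanding = _side_summary([s for s in sites if s.flag == "expanding"], cz_area_shares)
    if contracting is not None and expanding is not None:
        ratio = national_yield_ratio(contracting.weighted_yield, expanding.weighted_yield)
        return YieldRatioReport(contracting, expanding, ratio, True, crop=crop)
    empty = [
        name
        for name, side in (("contracting", contracting), ("expanding", expanding))
        if side is None
    ]
    return YieldRatioReport(
        contracting,
        expanding,
        None,
        False,
        crop=crop,
        note=f"no sites on side(s): {', '.join(empty)}",
    )
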