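"""Ready-made study configurations.

``demo_config``
    A small gradient landscape: urban-adjacent contraction in the warm
    south where double cropping is possible, frontier expansion into the
    cooler north — the qualitative situation of irrigated rice in a large
    rice-producing country.

``recovery_config``
    A designed parameter-recovery experiment: climate is spatially uniform
    and per-season yields statistically identical everywhere, while
    contracting-side sites grow a sequence mix with intensity k crops/year
    (a share k-1 of the area double-cropped) against single-cropped
    expanding sites.  The expected national yield ratio is then exactly k,
    so the full pipeline should recover k from the generated landscape.

``intensity_config``
    The limiting case of the same design: fully double-cropped contracting
    sites versus single-cropped expanding sites with equal per-season
    yields, expected ratio 2 — cropping intensity alone can reverse the
    apparent productivity comparison between lost and new land.
"""

from __future__ import annotations

from .buffers import SelectionConfig
from .cropsim import CropSequence, SoilProfile, rice_cultivar
from .pipeline import PipelineConfig, SequenceRule
from .synthetic import ClimateParams, LandscapeConfig

__all__ = ["demo_config", "recovery_config", "intensity_config", "scenario_config"]


def _single(sowing_day: int = 120) -> CropSequence:
    return CropSequence(sowing_days=(sowing_day,), cultivars=(rice_cultivar(),), area_share=1.0)


def _double_single_mix(double_share: float) -> tuple[CropSequence, ...]:
    """Sequence mix with a given double-cropped area share (intensity 1+share)."""
    if double_share >= 1.0:
        return (
            CropSequence(
                sowing_days=(32, 180),
                cultivars=(rice_cultivar(), rice_cultivar()),
                area_share=1.0,
            ),
        )
    if double_share <= 0.0:
        return (CropSequence(sowing_days=(32,), cultivars=(rice_cultivar(),), area_share=1.0),)
    double = CropSequence(
        sowing_days=(32, 180),
        cultivars=(rice_cultivar(), rice_cultivar()),
        area_share=double_share,
    )
    single = CropSequence(
        sowing_days=(32,), cultivars=(rice_cultivar(),), area_share=1.0 - double_share
    )
    return (double, single)


def demo_config(seed: int = 0) -> PipelineConfig:
    """Gradient landscape: warm double-cropping south loses area to cities,
    cool single-cropping north gains frontier cropland.

    The cool north grows a shorter-duration cultivar sown late (fitting the
    shorter thermal season), so the annual productivity contrast between the
    sides comes mostly from cropping intensity — the mechanism behind
    national yield ratios above one for irrigated rice.
    """
    landscape = LandscapeConfig(
        grid_shape=(40, 40),
        urban_centers=(((8, 10), 120_000.0), ((10, 30), 90_000.0)),
        contraction_radius=3.0,
        expansion_region=(28, 40, 0, 40),
        expansion_total_ha=220_000.0,
        crop="rice",
        base_area_mean=3_000.0,
        seed=seed,
    )
    climate = ClimateParams(
        mean_temp_base=27.0,
        mean_temp_gradient=-0.35,
        seasonal_amplitude=9.0,
        annual_rain=1400.0,
        rain_gradient=-12.0,
        interannual_sd=0.08,
    )
    north_cultivar = rice_cultivar(gdd_to_maturity=1350.0)
    warm = SequenceRule(0, 16, _double_single_mix(0.6))
    mid = SequenceRule(16, 28, (_single(sowing_day=110),))
    cool = SequenceRule(
        28,
        40,
        (CropSequence(sowing_days=(130,), cultivars=(north_cultivar,), area_share=1.0),),
    )
    return PipelineConfig(
        landscape=landscape,
        climate=climate,
        selection=SelectionConfig(coverage_target=0.6),
        water_regime="irrigated",
        weather_years=12,
        n_stations=16,
        sequence_rules=(warm, mid, cool),
        default_sequences=(_single(),),
        seed=seed,
    )


def _uniform_climate() -> ClimateParams:
    """Spatially and seasonally uniform warm climate: per-season yield
    potential is statistically identical everywhere on the grid."""
    return ClimateParams(
        mean_temp_base=26.0,
        mean_temp_gradient=0.0,
        seasonal_amplitude=0.0,
        temp_daily_sd=0.8,
        annual_rain=1400.0,
        rain_gradient=0.0,
        radiation_mean=17.0,
        radiation_amplitude=0.0,
        rad_daily_sd=1.5,
        interannual_sd=0.05,
        lat_per_row=0.0,
    )


def recovery_config(k: float = 1.3, seed: int = 0) -> PipelineConfig:
    """Designed experiment recovering a known national yield ratio ``k``.

    Requires 1 <= k <= 2: the contracting side grows a (k-1) double / (2-k)
    single area mix, the expanding side single crops, under identical
    climate, so the expected ratio equals the intensity ratio k.
    """
    if not 1.0 <= k <= 2.0:
        raise ValueError("recovery design supports k in [1, 2]")
    landscape = LandscapeConfig(
        grid_shape=(50, 50),
        urban_centers=(((7, 12), 180_000.0), ((8, 36), 180_000.0)),
        contraction_radius=3.0,
        expansion_region=(35, 50, 0, 50),
        expansion_total_ha=360_000.0,
        crop="rice",
        base_area_mean=3_000.0,
        seed=seed,
    )
    contracting_rows = SequenceRule(0, 25, _double_single_mix(k - 1.0))
    expanding_rows = SequenceRule(25, 50, _double_single_mix(0.0))
    return PipelineConfig(
        landscape=landscape,
        climate=_uniform_climate(),
        selection=SelectionConfig(coverage_target=0.85),
        water_regime="irrigated",
        weather_years=10,
        n_stations=24,
        sequence_rules=(contracting_rows, expanding_rows),
        fixed_soil=SoilProfile(paw_capacity_mm=150.0),
        seed=seed,
    )


def intensity_config(seed: int = 0) -> PipelineConfig:
    """Double- vs single-cropping contrast with equal per-season yields."""
    return recovery_config(k=2.0, seed=seed)


def scenario_config(name: str, seed: int = 0) -> PipelineConfig:
    builders = {"demo": demo_config, "recovery": recovery_config, "intensity": intensity_config}
    try:
        return builders[name](seed=seed)
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(builders)}") from None
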