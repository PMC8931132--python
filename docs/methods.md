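# Methods

This document describes the models implemented in `cropshift`, the default
parameter values and why they were chosen, the behaviour of the synthetic
data generators, and the numerical conventions that affect results. Nothing
here asserts an empirical result that the package does not itself compute;
all quoted example numbers come from the test suite or the shipped scenarios.

## 1. Pipeline overview

The pipeline (`cropshift.pipeline.run_pipeline`) runs six stages on one
country-scale landscape:

1. **generate** — synthetic two-epoch harvested-area grids, weather-station
   placement, daily weather, soils.
2. **zones** — climate metrics on the grid and climate-zone (CZ)
   delimitation.
3. **buffers** — station buffers clipped to CZs and greedy site selection.
4. **change** — epoch-to-epoch net area change, cell classification, and
   per-buffer net balances.
5. **simulate** — daily crop growth at each selected site over all weather
   years, soil types, and crop sequences.
6. **report** — flagging of contracting/expanding sites, climate-zone and
   national weighting, and the national yield ratio.

Each stage can be run from the CLI; later stages deterministically recompute
earlier ones from the configuration and seed, so stage outputs are always
mutually consistent.

## 2. Synthetic landscape generator

### What it emulates

* An equal-area lattice of grid cells, by default 10 km × 10 km
  (10 000 ha), standing in for an equal-area projection of a national crop
  mask.
* A smooth base harvested-area surface (`base_area_mean`, optional
  log-normal cell noise with `base_area_cv`, optional boxcar smoothing).
* **Contraction** around urban centres: each centre removes a fixed total
  area, distributed over nearby cells with an exponential kernel
  (e-folding distance `contraction_radius` cells, truncated at 3× the
  radius, normalized to sum to one). Losses are clipped so no cell goes
  negative.
* **Expansion** at a frontier: a fixed total gain spread uniformly over a
  rectangular region.
* **Two epochs of 3 annual snapshots** each: the epoch means differ by the
  contraction/expansion signal; individual years add multiplicative noise
  (`year_noise_cv`, default 2 %) emulating year-to-year reporting and price
  variation. Three-year epoch means are used downstream precisely to damp
  this noise.
* Weather stations are drawn without replacement from distinct cells with
  probability proportional to epoch-1 harvested area, so stations sit where
  the crop is.

### What it does not emulate

* Real geography: no coastlines, elevation, rivers, or administrative
  units; climate varies only with grid row (a single latitude-like
  gradient).
* Cropland competition between crops or regimes; each water regime gets an
  independent surface.
* Spatially correlated weather between stations (each station's daily
  series is an independent draw from the same row-dependent climatology),
  land abandonment dynamics, or multi-step urbanization.

The generator rejects configurations where an urban kernel footprint
overlaps the expansion rectangle, so "contracting" and "expanding" signals
cannot contaminate each other by construction.

### Weather generator

Daily series per station over `weather_years` calendar years (default 12;
sensible values are 10–15, enough for a stable inter-annual CV while keeping
runtime low):

* Temperature: sinusoidal seasonal cycle (`seasonal_amplitude`, peak at
  `peak_doy`) around a row-dependent mean (`mean_temp_base` +
  `mean_temp_gradient` × row), Gaussian daily noise (`temp_daily_sd`),
  fixed diurnal range splitting tmean into tmin/tmax.
* Radiation: sinusoidal cycle around `radiation_mean` (MJ m⁻² d⁻¹) with
  Gaussian noise, clipped non-negative.
* Rain: Bernoulli wet days (`rain_days_fraction`) with gamma-distributed
  amounts whose mean reproduces the row's annual total (`annual_rain` +
  `rain_gradient` × row); a per-year multiplicative factor
  (`interannual_sd`) creates wet and dry years. Setting `rain_amount_cv=0`
  and the noise SDs to 0 yields a fully deterministic climatology, which the
  tests use for degenerate-variance checks.

All randomness derives from `numpy.random.SeedSequence([seed, stream, …])`
fan-out, so each component (areas, weather, stations, soils) has an
independent stream and results are bit-reproducible for a given seed — the
acceptance suite checks byte-identical artifacts across two runs.

## 3. Climate zonation

Metrics are computed from the noise-free per-row climatology (analogous to
gridded climate normals), not from the stochastic station weather:

* **Growing degree days**: Σ max(0, min(T, cap) − T_base) over the year,
  default base 0 °C.
* **Temperature seasonality**: population standard deviation of the 12
  climatological monthly mean temperatures. Incomplete (year, month) blocks
  are rejected rather than silently averaged.
* **Aridity index**: annual precipitation / annual PET, with PET from
  Hargreaves–Samani, ET₀ = 0.0023 · 0.408 · Ra · (Tmean + 17.8) · √(Tmax −
  Tmin), and extraterrestrial radiation Ra from the FAO-56 formulas
  (solar constant 0.0820 MJ m⁻² min⁻¹). Hargreaves is chosen because it
  needs only temperature, matching the synthetic weather's variables.

A zone is a distinct triple of bin indices. Defaults: GDD bins 1000 °C·d
wide, seasonality bins 5 °C wide, aridity edges (0.2, 0.5, 0.65, 1.0) —
the conventional hyper-arid→humid breaks. Zone ids are assigned by
lexicographic order of the triples, so ids are stable across runs.

## 4. Buffer framework

* A candidate buffer is the set of cells whose centres lie within
  `radius_km` (default 100 km) of the station cell centre **and** share the
  station's climate zone.
* Only zones holding more than `min_cz_share` (default 5 %) of national
  harvested area produce candidates.
* Greedy selection: candidates sorted by harvested area descending, ties
  broken by ascending station id. A candidate is
  * *rejected* if its national share is ≤ `min_buffer_share` (1 %) — the
    thresholds are strict: exactly 1 % does not qualify;
  * *rejected* if its overlap with any already-selected buffer is ≥
    `max_overlap` (20 %), where overlap is |shared cells| / |candidate's
    cells| — the **candidate's** cell count is the denominator, an explicit
    design decision recorded below;
  * *accepted* otherwise.
* Selection stops at the first candidate whose acceptance carries the
  covered share past `coverage_target` (default 0.50), i.e. the target is
  crossed, not approached from below. Coverage is computed on the **union**
  of member cells — a cell counted once keeps its first-recorded area even
  if later buffers also contain it, so overlapping buffers never double
  count.

Every candidate decision (accepted / rejected / skipped once the target is
met) is recorded in a trace table with the reason and running coverage.

## 5. Crop simulator

A daily, single-layer water-balance crop model:

* **Light**: PAR = 0.5 × incident shortwave; fPAR = 1 − exp(−k·LAI) with
  extinction k = 0.5; LAI follows a logistic curve in thermal-time fraction
  (steepness 8, midpoint 0.35), reaching the cultivar's `max_lai`.
* **Growth**: ΔB = RUE × PAR × fPAR × f_T × f_W (g DM m⁻² d⁻¹).
* **Temperature factor** f_T: piecewise linear from the cultivar base
  temperature up to an optimal plateau and down to a lethal maximum.
* **Water factor** f_W: transpiration demand = fPAR × ET₀ (Hargreaves);
  supply = min(demand, available water). Irrigated sites have f_W = 1; the
  bucket still runs so water budgets are always reported. Soil evaporation
  drains (1 − fPAR) × ET₀ × 0.6; water above the plant-available capacity
  (PAW, mm) leaves as overflow. The budget rain − overflow − transpiration
  − evaporation = Δstorage closes to < 10⁻⁶ mm over a season (enforced by
  the acceptance suite across 1000 randomized scenarios, together with
  irrigated-dominates-rainfed and yield-monotone-in-PAW properties).
* **Phenology**: a season ends when accumulated GDD (above the cultivar
  base) reaches `gdd_to_maturity`; if the weather runs out first the season
  is flagged incomplete and yields zero with a warning.
* **Yield**: grain = biomass × harvest index / (1 − standard moisture),
  reported at 14 % moisture for rice and 15.5 % for maize (commercial
  standard moisture contents).

Default cultivars (generic, parameterized from common crop-model ranges):

| parameter | rice | maize | units |
|---|---|---|---|
| base temperature | 8 | 10 | °C |
| GDD to maturity | 1600 | 1500 | °C·d |
| RUE | 2.5 | 3.3 | g DM MJ⁻¹ PAR |
| max LAI | 6 | 5 | – |
| harvest index | 0.45 | 0.50 | – |
| optimal plateau | 22–30 | 18–32 | °C |
| lethal max | 42 | 44 | °C |
| standard moisture | 0.14 | 0.155 | – |

**Annual yield potential** of a crop sequence (1–3 crops/year, sowing days
strictly increasing, later sowings rejected if before the previous crop's
maturity) is the sum of its season yields within each calendar year, so a
double-cropped site is credited with both harvests. Between seasons the soil
bucket is carried through a bare-soil fallow spin-up, which also initializes
the first season when `init_mode="fallow_spinup"` (default in the pipeline
is `fixed_fraction`, 50 % of PAW).

**Site yield** averages annual yields over every soil × sequence
combination weighted by their area shares (shares must sum to 1 within
10⁻⁶). Sites use 2–3 dominant soil types by default. **Yield stability** is
the inter-annual coefficient of variation (sample SD, ddof = 1, ≥ 2 years)
of the site's annual yield, in percent. **Crop intensity** is the
share-weighted mean number of crops per year.

## 6. Area change and site flagging

* Net change per cell = epoch-2 mean − epoch-1 mean (3-year means).
* Display mask: cells with ≥ 50 ha in the epoch-1 mean (smaller areas are
  considered below the reliable display threshold).
* Cell classes: contracting if Δ < −250 ha, expanding if Δ > +250 ha,
  stable otherwise; inequalities are strict, so a change of exactly 250 ha
  is stable.
* Site net balance: sum of Δ over the buffer's member cells. A site is
  flagged *contracting*/*expanding* when |balance| exceeds 15 000 ha (rice)
  or 10 000 ha (maize), again strictly; otherwise it carries flag "none"
  and is excluded from upscaling.

## 7. Upscaling and the yield ratio

Within a climate zone, flagged sites of one side (contracting or expanding)
are averaged with weights |net balance|; mixing flags in one call is an
error. Across zones, the national value weights each zone's value by its
share of national harvested area, **renormalized over the zones that
actually contain flagged sites on that side** — zones without sites do not
drag the average toward zero. The national yield ratio is the contracting
national value divided by the expanding one; it is reported at one decimal
and is undefined (with a note in the report) if either side has no flagged
sites.

## 8. Numerical conventions and design decisions

* **Strict thresholds everywhere** (display, cell change, site
  significance, buffer share, overlap): boundary cases fail the test. This
  is the least surprising reading of "more than"/"less than" rules and is
  pinned by unit tests.
* **Overlap denominator**: the candidate under consideration, not the
  already-selected buffer or the union. Alternatives change which marginal
  candidates pass; the chosen rule makes the decision independent of how
  many buffers were selected before.
* **Tie-break** in selection: ascending station id after descending area,
  making selection a total order and the pipeline byte-deterministic.
* **Coverage crossing**: the last accepted buffer may push coverage past
  the target; it is kept. Stopping *before* the target would systematically
  undershoot "about half the national area".
* **Epoch-1 conventions**: national harvested area, station placement
  probabilities, and display masks all use the epoch-1 mean, representing
  the situation before the change being measured.
* **CV uses the sample SD** (ddof = 1): with 10–15 years the population SD
  would bias stability low.
* **Zone metrics from climatology, not station draws**: zones should not
  move with the weather seed; only yields do.
* **Soil seeds** combine the run seed and station id through a
  `SeedSequence`, so adding a station never reshuffles other stations'
  soils.
* Grid sizes in the shipped scenarios (24×24 to 50×50 cells, 8–24
  stations) are the package's own choices, small enough for the full chain
  and test suite to run in seconds while leaving dozens of cells per buffer.

## 9. Open design decisions and limitations

* The temperature factor is multiplicative and daily; no explicit
  heat-sterility around flowering or frost-kill event model.
* One soil layer; no runoff/infiltration split, groundwater, or salinity.
  "Irrigated" means unlimited water, not an irrigation schedule.
* fPAR drives both light interception and transpiration demand; there is no
  separate crop coefficient curve.
* Buffers use Euclidean cell-centre distance on the equal-area lattice; on
  a real projection a geodesic buffer would differ near the 100-km radius
  boundary.
* Climate varies only by row, so zones are horizontal bands; real zonation
  mosaics are patchier, which would exercise the clipping rules harder than
  the synthetic landscapes do.
* Yield-ratio recovery in the acceptance suite uses engineered scenarios
  (uniform climate, known intensity mix) where the expected ratio is exact;
  on heterogeneous landscapes the ratio also absorbs climate-driven yield
  differences, as the demo scenario shows.
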