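# cropshift

Spatial cropland change rarely swaps like for like: the hectares lost at the
edges of growing cities usually sit on good soils in warm climates with
irrigation and double cropping, while the hectares gained at the agricultural
frontier are often cooler, drier, or flood-prone and support a single crop
per year. `cropshift` quantifies what such a swap does to a country's
capacity to produce a staple crop. It is aimed at agronomists and land-use
analysts who want to reproduce — or stress-test on fully synthetic
landscapes — the national *yield ratio* methodology used in crop yield-gap
assessments.

## The method

1. **Two-epoch harvested-area grids.** Crop area per ~10 000 ha grid cell at
   two epochs, each a 3-year mean to damp price- and weather-driven noise.
   The net change Δ per cell (positive = expansion) classifies cells as
   contracting (Δ < −250 ha), expanding (Δ > +250 ha), or neither, on cells
   with ≥ 50 ha of cropland.
2. **Climate zones (CZ).** Cells are binned on growing degree days,
   temperature seasonality (SD of the 12 climatological monthly mean
   temperatures), and the aridity index P/PET (Hargreaves PET); a zone is a
   distinct bin triple.
3. **Station buffers ("sites").** 100-km discs around weather stations,
   clipped to the station's CZ. Within CZs holding > 5 % of national
   harvested area, buffers are selected greedily by harvested area — each
   must hold > 1 % of national area and overlap already-selected buffers by
   < 20 % — until ~half the national harvested area is covered.
4. **Annual yield potential per site.** A daily crop model (radiation-use
   efficiency × Beer's-law light interception × temperature factor × water
   supply/demand factor from a single-layer soil bucket) is run over 10–15
   weather years for every combination of dominant soil type and crop
   sequence, and averaged with their area shares. Summing over the crops
   grown per year on the same land credits double/triple cropping. Yields
   are reported at commercial moisture (14 % rice, 15.5 % maize). Yield
   stability is the inter-annual CV of annual yield potential.
5. **Upscaling and the yield ratio.** A site's net area balance over the
   decade flags it contracting (< −15 000 ha rice / −10 000 ha maize) or
   expanding (> +15 000 / +10 000 ha). Within each CZ, site yields are
   weighted by |net balance|; across CZs, by the zone's share of national
   harvested area. The headline statistic is

   ```
   national yield ratio = weighted yield in contracting CZ
                          ─────────────────────────────────
                          weighted yield in expanding CZ
   ```

   A ratio above one means each hectare lost needs proportionally more than
   one new hectare to replace its production potential.

All inputs can be generated synthetically (seeded landscapes with
urban-adjacent contraction, frontier expansion, climate gradients, daily
weather), so the whole chain runs without any external data.

## Worked example

```bash
cropshift run-all --scenario demo --seed 0 -o demo_out
```

runs the full chain on a 40×40-cell landscape where a warm,
partly-double-cropped south loses rice area around two cities and a cool,
single-cropped north gains frontier area, and prints:

```
Yield ratio report — crop: rice
Parameter                            Converted         New
----------------------------------------------------------
Crop intensity (crops/year)                1.6         1.0
Irrigation proportion (%)                100.0       100.0
Annual yield potential (t/ha)             11.0         9.1
Yield ratio                                1.2           –
Yield stability (CV in %)                  1.6         1.5
```

Converted (contracting) sites average 1.6 rice crops per year against 1.0 on
new land, so even though a single cool-climate crop yields respectably, each
converted hectare out-produces a new one: the national yield ratio of 1.2
means ~1.2 ha of new land are needed per hectare lost. Per-stage artifacts
(area grids, zone map, buffer membership, selection trace with acceptance
reasons, per-site yields, the report) are written to `demo_out/` as CSV.

The same pipeline is exposed as a library:

```python
from cropshift import run_pipeline
from cropshift.scenarios import demo_config

result = run_pipeline(demo_config(seed=0))
print(result.report.yield_ratio_1dp)   # 1.2
print(result.sites_frame())            # per-site yields, balances, flags
```

Stage subcommands (`generate`, `zones`, `buffers`, `change`, `simulate`,
`report`) write the artifacts of a single stage; a YAML file passed with
`--config` overrides any scenario field.

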