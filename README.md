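# biomeshift

Area-weighted change, migration-feasibility and fragmentation statistics for
categorical biome raster time series on regular latitude–longitude grids.

Given a series of 20-year biome maps (netCDF or GeoTIFF, 0.5° standard grid),
an optional high-resolution anthrome (human land use) raster, and the packaged
26-biome → 9-megabiome classification table, the pipeline computes:

1. **Change fractions** — area-weighted fraction of terrestrial area coded
   differently than the previous slice and than the 2000–2020 baseline,
   globally and within low (<30°), mid (30–60°) and high (≥60°) latitude bands;
2. **Suitable area per biome** per slice (km², spherical-zone cell areas);
3. **Overlap proportions** — per biome, the share of its current area that was
   suitable in the previous slice — and **non-adjacent fractions**, the share
   lying in cells not even touching previous-slice area (long-distance
   migration proxy; 4/8-connectivity, optional antimeridian wrap);
4. **Centroid tracks** — area-weighted 3-D-mean centroids with great-circle
   step distance and initial bearing;
5. **Patch counts** — connected components per biome.

Human land use is handled by disaggregating biome cells to the anthrome
resolution (factor 6 for 0.5° → 1/12°) and masking at two severities:
`urban` (remove urban + dense settlement) and `non_wild` (keep only wild +
semi-natural). A synthetic-scenario generator with controllable change rate,
poleward drift, patchiness and ocean fraction makes every stage testable
without the real model outputs, and an anomaly (delta) downscaling utility is
included for users preparing their own coarse climate fields.

## CLI

```sh
biomeshift simulate  --config config.yml --out-dir sim/     # synthetic inputs
biomeshift run       --config config.yml                    # full pipeline
biomeshift metrics   --input series.nc --out-dir out/       # one series, no mask
biomeshift aggregate --input series.nc --output mega.nc     # biome → megabiome
biomeshift mask      --input series.nc --anthromes a.tif --tier non_wild --output masked.nc
biomeshift downscale --future f.nc --preindustrial p.nc --reference r.nc \
                     --variable temperature --out fine.nc
```

Example `config.yml`:

```yaml
scenarios:
  rcp_like:
    synthetic:
      geometry: {n_lat: 18, n_lon: 36, lat_step: 10.0, lon_step: 10.0, origin: [85.0, -175.0]}
      zonal_layout: [23, 10, 7, 21, 1, 21, 7, 10, 23]
      n_slices: 25
      per_slice_change_rate: 0.12
      ocean_fraction: 0.3
      patchiness: 1.5
      seed: 3
  # or, to read an existing netCDF series:  rcp26: {path: series.nc}
anthromes:
  synthetic:
    geometry: {n_lat: 54, n_lon: 108, lat_step: 3.3333333, lon_step: 3.3333333, origin: [86.666667, -176.666667]}
    class_fractions: {urban: 0.1, cropland: 0.4, semi-natural: 0.2, wild: 0.3}
    clustering: 2.0
    seed: 5
tiers: [none, urban, non_wild]
levels: [biome, megabiome]
connectivity: 8
wrap: true
output_dir: out
```

Outputs land in `output_dir` as tidy CSVs (`change_fractions.csv`,
`biome_areas.csv`, `overlap.csv`, `non_adjacent.csv`, `patch_counts.csv`,
`centroid_tracks.csv`) plus `manifest.json` recording the configuration hash
and every decision flag. Reruns of an identical configuration are
byte-identical.

## Conventions

- Cell-center registration; row 0 is the northernmost row; the first
  longitude column center lies in [−180, 180). 0–360 longitude rasters are
  normalized on read.
- Sentinel code −1 marks non-terrestrial cells (ocean/ice/barren or removed
  by masking); all statistics run over non-sentinel cells only. In grid
  comparisons, cells sentinel in either grid are excluded from both numerator
  and denominator.
- Cell areas use the exact spherical-zone formula
  `R² · Δλ · (sin φ_N − sin φ_S)` with R = 6371 km (configurable); a 0.5°
  equatorial cell is ≈3091 km² and the full grid totals 4πR².
- A cell-center latitude of exactly ±30° falls in the mid band, ±60° in high.
- Patch counting and adjacency default to 8-connectivity with longitudinal
  wrap; both are flags and are recorded in the run manifest.

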