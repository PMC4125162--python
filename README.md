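# heightscape

Height-structured habitat metrics and avian species-richness modeling for
gridded canopy-height landscapes.

The package implements an end-to-end analysis pipeline:

1. **Synthetic data** (`heightscape.synthetic`) — canopy-height rasters as
   thresholded Gaussian random fields with controllable spatial
   autocorrelation and clustering of tall pixels, plus stop-level survey
   detection tables whose true richness is a linear function of standardized
   habitat metrics with species-specific detection probabilities.
2. **Segmentation** (`heightscape.segmentation`) — circular landscape
   buffers (19 km default), global-threshold height classification,
   contiguity-based patch labeling (8-neighbor) and depth-weighted vertical
   edge tables (4-neighbor faces).
3. **Habitat metrics** (`heightscape.habitat_metrics`) — 26 metrics in four
   sets: summary height statistics (A), traditional patch metrics on the
   binary vegetation map (B), height-structured patch metrics including
   contrast-weighted edge density, edge contrast index and Shannon class
   diversity (C), and
4. **Texture metrics** (`heightscape.texture`) — whole-window grey-level
   co-occurrence statistics (entropy, contrast, ASM, homogeneity,
   dissimilarity) on min–max quantized heights (set D).
5. **Richness** (`heightscape.richness`) — survey filtering (unacceptable
   records, first-year observers), first-order jackknife richness
   `S_obs + f1(k-1)/k` per route-year and guild, averaged over a year
   window (1998–2002 default).
6. **Modeling** (`heightscape.modeling`) — Pearson correlation screening,
   selection of the four best-performing height-structured metrics (2 each
   from sets C and D), six linear model configurations with 95% BCa
   bootstrap intervals for adjusted-r² and AIC (3000 replicates default),
   and a parallel random-forest suite (2000 trees, OOB explained variance,
   %IncMSE permutation importance) including the all-inclusive 26-metric
   model.
7. **Pipeline / CLI** (`heightscape.pipeline`, `heightscape.cli`) —
   orchestration with YAML config, per-stage CSV outputs, provenance JSON
   and caching.

## CLI

```bash
heightscape all --config config.yaml          # every stage in order
heightscape simulate --output-dir runs/demo   # synthetic rasters + surveys
heightscape metrics --config config.yaml      # 26 metrics per route buffer
heightscape richness --config config.yaml     # jackknife route richness
heightscape model --config config.yaml        # linear + RF model suite
```

A minimal `config.yaml`:

```yaml
output_dir: runs/demo
n_routes: 60
buffer_radius: 19000        # meters
thresholds: [5, 10, 15, 25] # height class boundaries, meters
n_boot: 3000
n_trees: 2000
seed: 1
landscape: {grid_rows: 64, grid_cols: 64}
survey:
  effect_metrics: [entropy, C.CWED]
  effect_sizes: [10.0, 8.0]
```

Outputs land in `output_dir`: `metrics.csv` (route × 26 metrics),
`richness.csv` (route × guild jackknife means), `models.csv` (6 linear + 7
RF rows per guild with CIs), `importance.csv` (%IncMSE), `correlations.csv`,
`bphm.json` and one provenance JSON per stage. Reruns with the same seed are
byte-identical; existing stage outputs are reused unless `--force`.

## Conventions

- Grids are row-major, 0-based, cell-center registered; planar equal-area
  coordinates with y decreasing along rows.
- Rasters are read/written as ESRI ASCII grids (optionally float32 TIFF via
  `tifffile`); tables are CSV.
- FRAGSTATS definitions for patch metrics: areas in hectares, edge density
  m/ha, population standard deviations, `FRAC = 2 ln(0.25 P)/ln(A)`.
- Buffers keep cells whose centers lie within the radius; window-boundary
  and nodata faces are never edges; densities use the valid (non-nodata)
  landscape area.
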