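# fucusstat

Analysis pipeline for the status of *Fucus* (bladder/narrow wrack) in a
coastal survey design: habitat-potential classification from Secchi-derived
light limits, per-water-body occurrence rates, detection of the *Fucus*
belt and its lower depth limit on dive transects, environmental raster
statistics, and two regression models — a hurdle model (binomial
presence/absence + truncated beta regression for positive occurrence rates)
and a log-linear GLM for the lower limit of the *Fucus* zone. A synthetic
survey generator with embedded ground truth makes the whole pipeline
testable offline and drives parameter-recovery experiments.

## Layout

| Module | Role |
| --- | --- |
| `fucusstat.synthetic` | zones, environmental grids, survey points, zone outcomes and transects with known truth |
| `fucusstat.habitat` | photic/light-limit conversion, potential-site classification, per-zone occurrence rates, layer validation |
| `fucusstat.zones` | belt detection (two consecutive ≥10% covers), lower limit, substrate-continuation filter |
| `fucusstat.envstats` | ESRI ASCII grid I/O, point extraction, zonal means, Pearson correlation + collinearity screen |
| `fucusstat.hurdle` | logistic and mean–precision beta-regression MLEs, backward interaction pruning, merged prediction |
| `fucusstat.lowerlimit` | OLS of ln(lower limit) with pruning, Shapiro–Wilk / Breusch–Pagan diagnostics |
| `fucusstat.pipeline` | end-to-end orchestration, manifest, recovery experiments |

## CLI

```bash
fucus simulate  --out-dir out/                         # synthetic dataset + truth.json
fucus run-all   --out-dir out/ --seed 1                # every stage end to end
fucus run-all   --out-dir out/ --mode data --data-paths inputs.json
fucus potential --points survey_points.csv --secchi secchi.asc --out-dir out/
fucus zones     --transects transects.csv --threshold 10
fucus envstats  --grids salinity.asc --grids secchi.asc --zones zones.geojson
fucus hurdle    --covariates zone_covariates.csv --rates zone_summaries.csv
fucus lowerlimit --limits lower_limits.csv --covariates transect_covariates.csv
fucus recover   --replicates 200 --out recovery.json
```

Configuration is a single JSON/YAML file mirroring
`fucusstat.synthetic.SimulationConfig`; `--seed` overrides the config seed.
All randomness flows from that one seed through named substreams, so
identical config + seed reproduce outputs byte for byte (checked by the
manifest hash).

## Data formats

Survey points and transects are plain CSV (11 substrate-class columns,
`fucus_cover_pct`, coordinates, depth); environmental grids are ESRI ASCII
(`.asc`) at their native resolutions; water-body zones are GeoJSON polygons.
Synthetic runs also emit `truth.json` with the generating coefficients,
per-zone outcomes and per-transect true lower limits.

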