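# taluscape

An analysis pipeline for climate-driven extirpation studies of talus-dwelling
species, built around four stages plus a synthetic-data generator:

1. **Radiocarbon calibration** (`taluscape.calibration`) — converts fecal-pellet
   Fraction-Modern (Fm ± 1σ) measurements into normalised calendar-age densities
   against an appended pre-bomb/post-bomb calibration curve, with multi-interval
   95% highest-density ranges (the bomb spike maps one Fm value onto a
   rising-limb and a falling-limb solution).
2. **Climate record** (`taluscape.climate`) — QC of a daily station record
   (missing-day counting before imputation, <15 missing days/year for annual
   temperature, <10 for June–August), linear imputation of interior gaps, annual
   MAT/MST/April-snow summaries, OLS trends, epoch contrasts (Welch t,
   Mann–Whitney, Spearman, two-proportion z), slope comparison, and delta-method
   offsets for reconstructing historical temperature grids.
3. **Refugial occupancy** (`taluscape.occupancy`) — site predictors (minimum
   "refugial" mean summer temperature within 1–5 km, log talus area within
   1 km), 250-m spatial thinning, hand-written logistic likelihood maximised
   with BFGS, AICc ranking of the 10 candidate models, the 0.5-probability
   temperature threshold, exact binomial / Poisson-binomial extirpation tests
   and classification rates against an external model's predictions.
4. **Habitat projection** (`taluscape.projection`) — uniform warming offsets,
   strict-inequality refugial masks, distance-transform suitability within a
   dispersal radius, and km² area accounting with percent declines.

`taluscape.synthetic` generates every input the pipeline consumes (bomb-spike
curve, daily weather with trend/noise/clustered gaps, lapse-rate temperature
rasters, talus polygons, logistic occupancy with known coefficients) from a
single seeded generator, so the whole chain is testable offline.

Rasters are plain-text ESRI ASCII grids in a projected metric CRS
(`taluscape.grids`); talus polygons are GeoJSON via shapely.

## CLI

```sh
taluscape simulate --seed 3 --out bundle/          # synthetic input bundle
taluscape calibrate --curve bundle/curve.csv --measurements meas.csv --mass 0.95
taluscape trends --daily bundle/daily_weather.csv --split-year 1955
taluscape occupancy --sites bundle/sites.csv --grid bundle/mst_grid.asc \
    --talus bundle/talus.geojson --radii 1,2,3,4,5
taluscape project --grid bundle/mst_grid.asc --threshold 14.2 --dispersal-km 4 \
    --scenarios "historical:-1.45,current:0,2030:1.33,2050:2.74"
taluscape run --config pipeline.yaml --out report.json
```

Exit codes: 0 success, 2 validation error, 3 computation error.

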