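# File formats

All interchange formats are plain text (JSON or UTF-8 comma-separated CSV
with a required header).

## Layout config (JSON)

Validating example (two wells; the shipped 96-well default lives at
`src/chipcode/data/default_layout_96.json`):

```json
{
 "n_rows": 1,
 "n_cols": 2,
 "origin": [10, 10],
 "pitch": [20, 20],
 "roi": {"shape": "disk", "size": 3},
 "ordering_id": "DC-asc.cond-asc.RGB",
 "wells": [
  {"well": "A1", "sensor": "DC1", "condition": 1, "role": "control", "pair": "P01"},
  {"well": "A2", "sensor": "DC1", "condition": 1, "role": "analyte", "pair": "P01"}
 ]
}
```

* `origin` — pixel coordinates `[x, y]` of the center of well A1 (0-based,
  origin top-left, x rightward, y downward).
* `pitch` — `[dx, dy]` pixels between adjacent well centers. The ROI
  diameter must be smaller than the pitch.
* `roi.shape` — `disk` (size = radius px) or `square` (size = half-width px).
* `wells` — only listed wells are analyzed. Every pair id must name exactly
  one control and one analyte well sharing sensor and condition.
* Code length = n_sensors × n_conditions × 3; digits are ordered sensors
  ascending, conditions ascending, channels R, G, B.

## well_totals.csv

```
well,row,col,sensor,condition,role,pair,red_total,green_total,blue_total,pixel_count
```

Exact integer channel sums over the ROI, one row per mapped well.

## differences.csv

```
pair,sensor,condition,channel,delta
```

`delta` is signed: control total − analyte total.

## replicates.csv (calibration input)

```
concentration_mM,plate,assay,sensor,condition,channel,delta
```

## Code library (JSON)

```json
[
 {"analyte": "ketamine", "concentration_mM": 100, "code": "0110...", "ordering_id": "DC-asc.cond-asc.RGB"}
]
```

`concentration_mM` may be null. All codes must share one length and
ordering_id.

## Standard curve (JSON)

```json
{"slot": ["DC1", 1, "G"], "slope": 49.96, "intercept": 7.58, "r": 0.9999,
 "residual_se": 15.34,
 "points": [{"concentration_mM": 10, "mean_delta": 501.2, "sd_delta": 48.1, "n": 9}]}
```

## Spectra CSV (long format)

```
sample_id,analyte,concentration_mM,wavelength_nm,absorbance
```

One spectrum per `sample_id`; rows are sorted by wavelength on read, and a
duplicated (sample, wavelength) pair is an error.

## Scenario (JSON)

Two top-level keys, `plate` and `spectrum`; the shipped ketamine defaults
are at `src/chipcode/data/ketamine_scenario.json`.

```json
{
 "plate": {
  "responses": [{"sensor": "DC1", "condition": 1, "channel": "G", "slope": 50.0}],
  "baseline": [180, 140, 160],
  "pixel_noise_sd": 2.0,
  "concentrations_mM": [10, 25, 50, 62.5, 80, 100],
  "seed": 0
 },
 "spectrum": {
  "peaks": {"ketamine": {"lambda0_nm": 516.0, "lambda_slope_nm_per_mM": 0.0444,
                          "a0_AU": 1.05, "a_slope_AU_per_mM": -0.00433, "width_nm": 30.0}},
  "noise_sd_AU": 0.01,
  "grid_nm": [400.0, 700.0, 1.0],
  "seed": 0
 }
}
```
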