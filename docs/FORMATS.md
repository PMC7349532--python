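# On-disk formats

All formats are plain text, diffable, and written with `%.17g` float
precision so that a write/read cycle is bit-exact.

## Session directory

One 6MWT session is a directory containing three files.

### `meta.json`

```json
{
  "patient_id": "P001",
  "session_index": 1,
  "phase_times": {
    "rest_start": 0.0,
    "walk_start": 300.0,
    "walk_end": 660.0,
    "record_end": 960.0
  },
  "anthropometrics": {
    "age": 62.0,
    "height_m": 1.75,
    "weight_kg": 84.0,
    "sex": "M"
  },
  "six_mwd_measured": 415.0
}
```

- Phase boundaries are seconds from recording start; phases are half-open
  intervals `[start, end)`: rest `[rest_start, walk_start)`, walk
  `[walk_start, walk_end)`, recovery `[walk_end, record_end)`.
- `six_mwd_measured` (meters) is **omitted entirely** when the walking
  distance was not recorded. Sentinel values (0, -1, NaN) are never used.
- `sex` is `"M"` or `"F"`.

### `r_peaks.tsv`

Tab-separated, one header line, one column:

| column | unit | constraint |
|--------|------|------------|
| `t`    | s    | strictly increasing |

### `accel.tsv`

Tab-separated, one header line, four columns at a nominal 32 Hz:

| column | unit | constraint |
|--------|------|------------|
| `t`    | s    | non-decreasing |
| `x`, `y`, `z` | g | finite |

## Cohort feature table (`features.csv`)

Comma-separated with header; one row per `(patient_id, session_index)`
(this pair must be unique). Columns, in order:

| column | unit / type |
|--------|-------------|
| `patient_id` | string |
| `session_index` | integer >= 1 |
| `hr_rest`, `hr_max`, `hr_avg`, `chronotropic_response` | bpm |
| `time_to_hr_max` | s from walk start |
| `time_to_recuperation` | s from 5 s after walk end; empty when not reached |
| `recuperation_reached` | boolean |
| `effort_win1`, `effort_win2`, `effort_win3`, `effort_total` | g²·samples |
| `n_artifacts_removed` | count |
| `age` | years |
| `height_m` | m |
| `weight_kg` | kg |
| `sex` | `M` / `F` |
| `six_mwd_measured` | m; empty when absent |

## Ground-truth table (`ground_truth.csv`)

Written next to simulated sessions; comma-separated with header
`patient_id, session, hr_rest_true, hr_plateau_true, chronotropic_true,
effort_scale_true, six_mwd_true` (bpm / dimensionless / meters).

## Simulator config (`cardiowalk simulate --config`)

Plain `key = value` lines; `#` starts a comment. Keys are the
`CohortConfig` fields (e.g. `n_patients`, `n_sessions`, `outcome_noise_sd`,
`responder_fraction`, `hrv_sd`, `ectopic_rate`); two-parameter
distributions take `mean,sd` (e.g. `improvement_per_session = 0.19,0.05`).
The `--seed` option always overrides `rng_seed`.

## Embedding table (`embedding.csv`)

`patient_id, session_index, dim1, dim2, dim3` — dimensionless composite
coordinates; the axes carry no physical unit.
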