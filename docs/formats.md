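# File formats

## Event table (CSV, version 1)

One row per dose or observation record, NONMEM dialect. Written with a
`# mdzpopkit event-table v1` header comment; `read_event_table` /
`write_event_table` round-trip byte-identically.

| column | meaning |
|--------|---------|
| ID     | subject identifier (int) |
| OCC    | occasion number within subject, 1-based; clock restarts at 0 |
| TIME   | time within the occasion [h] |
| EVID   | 1 = dose record, 0 = observation |
| AMT    | dose amount [mg] (0 for observations) |
| ROUTE  | `oral` / `iv` for doses, `.` otherwise |
| CMT    | analyte of an observation: `MDZ` or `OHMDZ`; `.` for doses |
| DV     | observed concentration [nM]; retained even when BLQ |
| MDV    | 1 = not used in estimation (doses, BLQ rows) |
| BLQ    | 1 = below the limit of quantification |
| LLOQ   | quantification limit applied to the row [nM] |
| WT     | body weight [kg] |
| AGE    | age [y] |
| SEX    | `M` / `F` |
| TRT    | treatment category: `constitutive`, `reversible_inhibition`, `irreversible_inhibition`, `induction` |

A `*.manifest.json` written beside a simulated dataset records the design,
seed and package version.

## Population configuration (YAML)

Blocks `population` (typical values, covariate exponents, residual-error
terms), `random_effects` (`omega2`, `corr_Vc_Vmet`, `iov2`) and optional
`treatment_effects` (per-category deltas). Shipped defaults:
`table3_final.yaml`, `table3_interaction.yaml`. Unknown keys are rejected.

## Other artifacts

- `fit.json` — estimates, fixed values, OFV, convergence, subject count.
- `ebes.csv` — per subject × occasion × parameter: eta, kappa, shrunken value.
- `cutpoints.json` — `CutPointModel` (parameter, thresholds, labels,
  training accuracy); `paper_cutpoints.json` ships the published 16.4 /
  41.8 L/h thresholds.
- `vpc.csv` — per (arm, analyte, time bin): observed percentiles and 90%
  simulation intervals; `vpc.png` the semi-log panel plot.
- `confusion.csv` — 3×3 actual × predicted counts.
- `manifest.json` — command, full configuration, SHA-256 of inputs,
  package version; every stochastic run is reproducible from it.

## Run configuration (YAML)

Keys: `seed`, `out`, `params`, `design`, `n_sim`, `n_subjects`, `free`,
`dataset`, `cutpoints`, `schema_version` (currently 1). CLI flags override
file values; unknown keys are rejected.
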