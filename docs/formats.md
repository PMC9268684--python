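# File formats

All files are plain text with mandatory headers.  Times are seconds,
waveform samples μV, voltages mV, currents pA.  Floats are written with 12
significant digits (`%.12g`), which makes write→read the identity up to
that precision and runs byte-reproducible.

## Inputs (sorted-unit tables)

**spikes.csv** — long format, one row per spike:

| column  | type  | description              |
|---------|-------|--------------------------|
| unit_id | str   | sorted-unit identifier   |
| time_s  | float | spike time in seconds    |

**waveforms.csv** — wide format, one row per unit's mean waveform:

| column           | type  | description                       |
|------------------|-------|-----------------------------------|
| unit_id          | str   | sorted-unit identifier            |
| sampling_rate_hz | float | waveform sampling rate (20000)    |
| s0 … sN          | float | samples in μV (N ≥ 15)            |

**metadata.csv** — one row per unit:

| column     | type  | description                                |
|------------|-------|--------------------------------------------|
| unit_id    | str   | sorted-unit identifier                     |
| animal_id  | str   | animal the unit was recorded from          |
| group      | str   | experimental group (e.g. ND/Res/Sus)       |
| duration_s | float | recording span (optional; else inferred)   |

**behavior.csv** — one row per animal:

| column     | type  | description                          |
|------------|-------|--------------------------------------|
| animal_id  | str   |                                      |
| group      | str   |                                      |
| defeated   | bool  | underwent the defeat paradigm        |
| phase1_s   | float | phase-1 interaction-zone time (s)    |
| phase2_s   | float | phase-2 interaction-zone time (s)    |
| sucrose_ml | float | optional                             |
| water_ml   | float | optional                             |

**Intracellular sweeps** — per sweep a CSV with `time_s, voltage_mv`
columns plus a sidecar JSON listing `injected_current_pa`, `step_start_s`,
`step_duration_s` per sweep file (the library API accepts arrays directly).

## Outputs

* `features.tsv` — unit_id, ttp_ms, burst_index (may be `inf`),
  ahp_uv_per_ms, rate_hz, flags (semicolon-joined:
  `few_spikes`, `infinite_burst_index`, `degenerate_waveform`,
  `inverted_polarity`).
* `labels.tsv` — features plus `cell_class` (putative_PV,
  wide_interneuron, putative_mossy, putative_granule, unclassifiable),
  `ahp_threshold_used`, animal_id, group.
* `class_counts.json` — per-class counts (summing to the input size), the
  AHP threshold used, warnings.
* `stats.tsv` — tidy rows: cell_class, comparison (`omnibus` or
  `A vs B`), test_name, statistic, p, p_adj.
* `behavior_scored.csv` — input behavior columns plus si_ratio, phenotype
  (susceptible / resilient / not_applicable / excluded), sucrose_pref_pct.
* `manifest.json` — tool version, config hash (scientific fields only),
  seed, per-stage record counts, all warnings.
* `config.json` — the fully resolved run configuration.
* `truth.csv` (synthetic runs) — unit_id, true_class, true_ttp_ms,
  true_rate_hz, true_ahp_slope_uv_per_ms, animal_id, group.

## Run configuration (JSON or YAML)

```yaml
synthetic:              # exactly one of synthetic / inputs
  animals_per_group: 5
  units_per_class_per_animal: 2
  duration_s: 300.0
  behavior_n_per_group: 10
# inputs:
#   spikes: path/spikes.csv
#   waveforms: path/waveforms.csv
#   metadata: path/metadata.csv
#   behavior: path/behavior.csv   # optional
classifier:
  ttp_threshold_ms: 0.4
  bi_threshold: 1.8
  ahp_threshold_uv_per_ms: 70
  precedence: latency_first
  ahp_threshold_mode: fixed
alpha: 0.05
seed: 42
out_dir: run_out
```
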