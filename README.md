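# cellwatch

Smart-sensor monitoring toolkit for bioreactor cell-expansion batch runs.

`cellwatch` turns the raw multichannel time series of one expansion run
(temperature, dissolved oxygen, pH, gas flow, glucose, lactate, exhaust
O2/CO2) into six higher-level alert streams and a consensus verdict:

| Smart sensor    | Inputs        | Idea |
|-----------------|---------------|------|
| `SDI`           | Glu + Lac     | simultaneous sub-sigma drops in both metabolites (non-biological "bubbles"); alert at 3+ drops per 30 min window |
| `Boll_Glucose`  | Glu           | moving average ± K·sigma envelope (K = 8); alert when the value sits within 25% of a band |
| `Boll_Lactate`  | Lac           | same, 20% threshold |
| `WWA_SP`        | Glu, O2, CO2, T, GasFL | gated, weighted mean distance from setpoints; alert above 0.1 |
| `WWA_NSP`       | Lac, pH, DO   | same for reference-value sensors; alert above 0.35 |
| `Fuzzy`         | Glu           | complementary "normal"/"alert" piecewise-linear memberships over the setpoint distance; alert above grade 0.45 |

A **consensus event** is a (merged) interval where at least three of the
six streams alert simultaneously. The `consensus` module also derives
the coincidence summary (per-sensor and per-run detected/undetected
counts and consensus percentages).

Because real runs are proprietary, `cellwatch.synthetic` generates runs
with the same qualitative structure (pre-stabilization, glucose
convergence, lactate drift, DO/pH decline, tight temperature
oscillation) plus injectable disturbances: metabolite "bubbles",
temperature dips, channel dropouts, and a full shutdown with decline
and recovery. Shipped profiles `run1_like` … `run5_like` mirror the
five historical run archetypes.

## CLI

```sh
# generate a synthetic 6-day run (CSV: time_days,T,DO,pH,GasFL,Glu,Lac,O2,CO2)
cellwatch simulate --profile run3_like --seed 1 --out run3.csv

# run all six smart sensors; writes per-sensor tables + alert_matrix.csv
cellwatch monitor --in run3.csv --run-preset run3_like --outdir out/

# consensus events + per-sensor coincidence from the alert matrix
cellwatch consensus --matrix out/alert_matrix.csv --outdir out/

# derive the undetected-count summary from a coincidence-count table
cellwatch summary --table5 counts.csv --out summary.json
```

All thresholds, windows, weights and reference schedules live in
`PipelineConfig` (YAML-serialisable via `--config`); nothing is
hard-coded in the sensors.

## Library sketch

```python
import cellwatch as cw

run = cw.generate_run(cw.get_profile("run3_like", seed=1))
cfg = cw.PipelineConfig(run_preset="run3_like")
result = cw.monitor(run, cfg)                      # six alert streams
out = cw.consensus_from_matrix(result.matrix, cfg) # events + coincidence
```

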