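# metascope

Aerobic-scope ecology toolkit: estimates Arrhenius metabolic traits from
respirometry, converts environmental monitoring data into a metabolic index
(phi = pO2 supply / temperature-dependent O2 demand), fits binomial smooth
models of binary fitness outcomes (rearing occupancy, migration success,
predation) against phi or temperature, and locates ecological thresholds
(phi_crit, phi_stable) by two-breakpoint segmented regression on log-odds
prediction curves. A seeded synthetic-data module emulates all five input
streams so the whole pipeline is testable offline.

## Layout

| module | role |
| --- | --- |
| `metascope.envio` | DO->pO2 conversion, inverse temperature, water-year calendar, quantile QC, wild-fry classification, telemetry exposure windows |
| `metascope.traits` | O2crit from SMR/MMR, temperature/mass standardization, fixed- and mixed-effects Arrhenius fits (A, E) with bootstrap CIs |
| `metascope.phi` | phi arithmetic and series, robust seasonal smooth, threshold classification, exposure fractions, predator surplus |
| `metascope.fitmodels` | penalized binomial smooths: spline bases + curvature penalties, REML-type smoothing selection, ridge random intercepts, prediction CIs, concurvity, BIC |
| `metascope.thresholds` | two-breakpoint segmented regression (iterative linearization + brute-force oracle), phi_crit/phi_stable extraction |
| `metascope.predation` | within-group z-scoring, predation-probability models, predator/prey seasonal alignment |
| `metascope.synthetic_data` | seeded generators for respirometry, environment, fitness outcomes and predation deployments |
| `metascope.pipeline` / `metascope.cli` | end-to-end orchestration, JSON artifacts, `metascope` command line |

## Command line

```sh
# synthesize all five input streams
metascope synth all --seed 42 --outdir data/

# convert dissolved oxygen to partial pressure; quantile QC
metascope env convert --in data/environment.csv --out env_po2.csv
metascope env qc --in env_po2.csv --out env_qc.csv --q 0.005

# Arrhenius traits from respirometry (fixed or mixed effects)
metascope traits fit --in data/respirometry.csv --model lmer --seed 1 --out traits.json

# daily phi series and threshold classification
metascope phi compute --traits traits.json --env env_qc.csv --label smolt --out phi.csv

# fitness models and thresholds
metascope fit --kind rearing --driver phi --in data/rearing.csv --out model.json
metascope thresholds --kind rearing --in data/rearing.csv --out thresholds.json

# predation model; full pipeline
metascope predation fit --in data/predation.csv --out predation.json
metascope run --seed 7 --outdir out/
```

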