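# ricerisk

Province-week grading and forecasting of dietary heavy-metal safety risk
in rice.

National market surveillance of rice measures cadmium, chromium and
inorganic arsenic in hundreds of thousands of samples a year. Regulators
need that stream condensed into a question they can act on: *which
provinces, in which weeks, will be at elevated dietary risk?* `ricerisk`
implements the full chain for analysts working on such surveillance data:

1. **Risk indicators** — each province-week is summarised by the Nemerow
   integrated pollution index (NIPI), the target hazard quotient (THQ) and
   the total carcinogenic risk (TCR):

   `P_j = C_j/S_j`,  `NIPI = sqrt((max_j P_j² + mean_j P_j²)/2)`

   `THQ = Σ_j F50·C_j/(RfD_j·W)`,  `TCR = Σ_j EF·ED·CSF_j·EDI_j/ATC`,
   `EDI_j = F50·C_j/W`

   with the Chinese national limits `S`, JECFA/EPA reference doses `RfD`,
   EPA cancer slope factors `CSF`, body weight `W = 60` kg and non-detects
   imputed at half the limit of detection.
2. **Risk grading** — the 3-D indicator points are min-max normalised and
   clustered with randomised-swap K-medoids; the cluster count (2–7) is
   chosen by mean silhouette, and clusters are ordered into Low / Medium /
   High by distance of their centers from the origin.
3. **Forecasting** — each indicator series is forecast 21 weeks ahead with
   a ProbSparse-attention encoder–decoder (distilling encoder stacks,
   masked generative decoder), pooled across provinces, on the package's
   own numpy autodiff engine. A persistence baseline anchors the
   comparison.
4. **Level prediction** — forecast triplets are assigned to the nearest
   risk-level center, and evaluated with RMSE/MAE per indicator plus
   precision/recall/F1 per level.

Because the national sampling dataset is access-restricted, the package
ships a synthetic-data generator (`ricerisk.simulate`) that reproduces its
statistical shape — lognormal concentrations with metal-specific
left-censoring, province baselines, seasonal elevation in the new-rice
weeks, and latent low/medium/high regimes — so every stage is testable
end to end. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import pandas as pd
from ricerisk import (
    SimulationConfig, simulate_dataset, build_indicator_series,
    RiskGradingModel, InformerModel, ForecastConfig,
)
from ricerisk.evaluate import evaluate_pipeline

samples, consumption, _ = simulate_dataset(SimulationConfig(seed=1))
series = build_indicator_series(samples, consumption)

grading = RiskGradingModel(series).fit(seed=1)
print(grading.summary())
```

```
Risk level space (K-medoids, min-max normalised indicators)
selected k = 3  (mean silhouette 0.9132, cost 91.4799)

silhouette by k: 2:0.8881, 3:0.9132, 4:0.8954, 5:0.8394, 6:0.8317, 7:0.4806

level        n        NIPI       THQ         TCR  (original units)
Low       2279     0.16484   0.71219   1.125e-03
Medium     583     1.29827   5.79393   9.094e-03
High       318     4.64939  21.69978   3.387e-02
```

The silhouette peaks at k = 3; the three centers — actual dataset
province-weeks — have strictly increasing indicators, so they are read as
Low < Medium < High. Low-risk weeks sit well inside the safety thresholds
(NIPI < 1, THQ < 1); High-risk weeks exceed them several-fold.

```python
fc = InformerModel(series, ForecastConfig(seed=1), value_col="nipi").fit(138)
pred = fc.predict().rename(columns={"value": "nipi"})
```

Training prints nothing by default; `fc.summary()` reports the loss
trajectory (here 0.854 → 0.121 over 25 epochs). Joining forecasts for all
three indicators and scoring against the held-out weeks 139–159:

```
Indicator forecast errors
  nipi   RMSE 0.153404   MAE 0.0688118
  thq    RMSE 0.659729   MAE 0.293497
  tcr    RMSE 0.00114592   MAE 0.0005246

Level           P%      R%     F1%    TP    FP    FN
Low         100.00   99.32   99.66   292     0     2
Medium       96.92  100.00   98.44    63     2     0
High        100.00  100.00  100.00    63     0     0
```

The forecaster halves the persistence baseline's RMSE on every indicator
(persistence: NIPI 0.309, THQ 1.394, TCR 0.00204), and nearly every
forecast week lands in the correct risk level.

The same pipeline is available from the shell:

```sh
ricerisk --seed 1 --out-dir runs/demo all
```

which writes `samples.csv`, `indicators.csv`, `level_space.json`,
`predictions.csv` and `evaluation.json` stage by stage, logging a config
hash and seed for each.

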