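# emeq

Enteric methane prediction equations for dairy cattle, and their combination
into a single mixed-model equation.

Published equations that predict enteric methane emissions (EME) from diet
disagree substantially: the same ration can yield anywhere from ~12 to ~34
g CH4 per kg of dry matter depending on which equation is applied, which
makes emissions incomparable across farms and studies. `emeq` packages a
registry of 32 published prediction equations (from 5 source publications),
evaluates them over dairy rations with full unit handling, quantifies the
between-equation spread, and derives a **combined equation** — the average
relationship across the published literature — by treating the long
equation × diet prediction table as clustered data.

## The model

Each equation *i* applied to diet *j* gives a prediction
*y<sub>ij</sub>* (g CH4/kg DM), modelled as a random-intercept linear
mixed model:

y<sub>ij</sub> = β₀ + β₁·ME<sub>ij</sub> + β₂·NDF<sub>ij</sub> + u<sub>i</sub> + ε<sub>ij</sub>,  u<sub>i</sub> ~ N(0, σ²<sub>equation</sub>),  ε<sub>ij</sub> ~ N(0, σ²)

where ME is metabolisable energy concentration (MJ/kg DM), NDF is neutral
detergent fibre (% of DM), u<sub>i</sub> is an equation-level random
intercept absorbing between-equation heterogeneity, and estimation is by
REML. Predictors are centred and scaled before fitting; slopes are
back-transformed to raw units via β<sub>j,raw</sub> = β*<sub>j</sub>/SD(X<sub>j</sub>) and
β<sub>0,raw</sub> = β*<sub>0</sub> − Σ<sub>j</sub> β*<sub>j</sub>·X̄<sub>j</sub>/SD(X<sub>j</sub>).
Candidate predictor subsets are screened for collinearity (Pearson r, VIF)
and compared on R², RMSE and residual variance, with slopes called
significant when |t| > 2. Validation is by leave-one-diet-out
cross-validation and leave-one-equation-out sensitivity refits.

The package ships the reference combined equation

CH4 (g/kg DM) = 0.33·ME + 0.31·NDF + 3.47

and a 15-ration fixture set of UK dairy diets (13 lactating, 2 dry-cow).
The diets' dry matter intakes, energy concentrations and ash are not public;
`emeq.synth` completes them from seeded, documented assumptions (see
`docs/methods.md`), so fitted coefficients on the packaged data are
conditional on that completion.

## Worked example

```python
from emeq import predict_combined
predict_combined(11.5, 32.5)   # ME 11.5 MJ/kg DM, NDF 32.5 % DM -> 17.34
```

The reference equation gives 0.33·11.5 + 0.31·32.5 + 3.47 = 17.34 g CH4/kg
DM: a typical early-lactation ration emits ~17 g of methane per kg of feed
dry matter.

The full pipeline (completion → 480 predictions → candidate fits → selection
→ back-transformation → CV → sensitivity):

```python
from emeq.evaluate import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(seed=0), out_dir="runs/demo")
print(res.selection.results.summary())
```

prints (seed 0):

```
Combined methane equation fit (model 1)
  predictors: ME + NDF  (standardized)
  R^2 = 0.7479   RMSE = 1.6811 g CH4/kg DM   residual variance = 3.0341
  between-equation variance = 5.4348 (SD = 2.3313)

Random-intercept linear mixed model (REML)
  observations: 480   groups: 32   fixed effects: 3
  ...
  raw scale: CH4 (g/kg DM) = 0.7139*ME + 0.3755*NDF + -3.4375
```

Reading this: the parsimonious ME+NDF candidate (model 1) wins the
selection; ME and NDF explain ~75 % of the variation in the 480 predictions
once each equation's baseline shift is absorbed by its random intercept,
and equations still disagree by a between-equation SD of ~2.3 g CH4/kg DM
at identical diet composition. Because the packaged diets' intakes are
synthesised, these coefficients differ from the reference equation; the
NDF slope (0.38 per % NDF) is close, the energy terms are conditional on
the completion.

The same run reports VIF 1.86 for both predictors (low collinearity),
per-diet prediction extremes spanning 13.2–35.7 g CH4/kg DM,
cross-validated R² of 0.61 on average across held-out diets, and
leave-one-equation-out NDF coefficients confined to [0.36, 0.38] — no
single published equation drives the combined fit.

A thin CLI wraps the same calls: `emeq run --out runs/demo`,
`emeq predict --me 11.5 --ndf 32.5`, `emeq cv`, `emeq sensitivity`,
`emeq diets export`, `emeq equations list`.

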