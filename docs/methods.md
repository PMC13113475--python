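# Methods

## Problem and scope

Published enteric methane prediction equations for dairy cattle are linear
(or linear-times-intake) functions of feed intake and diet composition.
Applied to the same ration they disagree, both in level and in how strongly
they respond to composition. `emeq` quantifies that disagreement over a set
of dairy rations and derives a *combined equation*: the mean relationship
between diet composition and predicted methane across the published
equations, with the between-equation heterogeneity modelled explicitly
rather than averaged away.

The package covers five stages — diet data model, synthetic completion,
equation registry and evaluation, mixed-model combination, and validation —
each usable on its own through the library API or the `emeq` CLI.

## Equation registry

The registry (`emeq/data/registry.yaml`) holds 32 equations from 5 source
publications as declarative records: intercept, terms of
(coefficient, variable, unit), a shape flag for formulas that multiply the
whole linear part by DMI, and an output unit. Sources reporting methane as
energy are converted at 55.65 kJ/g CH4 (0.05565 MJ per gram). One
published duplicate pair (two identical DMI+NDF rows from the same source)
is retained deliberately: dropping one would change the ensemble weighting
of that functional form.

The source publications do not always state per-variable units, so units
were assigned per record from the publication conventions and audited by
magnitude: under the default completion, every equation's output must fall
in a broad plausibility window of 5–45 g CH4/kg DM (the observed envelope
across published per-diet summaries is 12.49–34.27). Records whose units
remain uncertain are flagged `unit_uncertain` in the registry. Two
assignment choices deserve note:

- Fibre terms in the energy-output equations are daily intakes (kg/day),
  while the concentration-style equations use % of DM; only these choices
  give plausible magnitudes.
- One record is published without outer parentheses, converting only its
  fibre term from energy to mass. It is encoded literally (a per-term
  `energy_divisor`), because dividing the whole expression by 0.05565
  produces ~89 g CH4/kg DM, far outside the plausibility window, while the
  literal form lands near the published per-diet minima.

Negative predictions (possible for one equation with a large negative
intercept at extreme inputs) are returned with a warning, never clamped:
clamping would bias ensemble statistics.

## Diets and synthetic completion

A ration is described by MEI (MJ/day) and composition as % of DM (CP, FA,
EE, NDF, ADF, forage). The packaged fixture holds 15 UK dairy rations
(ids "1"–"15"; the last two dry-cow). Percentages are stored as printed
(32.5 means 32.5 % DM). ADF in the fixture is an affine function of NDF
(≈ 0.82·NDF), so the two fibre fractions are effectively interchangeable.

The fixture diets lack DMI, energy concentrations and ash, which the
original data holders did not release. `emeq.synth.complete_diets` fills
them in deterministically from a seeded `CompletionConfig`:

- **DMI** (kg DM/day) is drawn uniformly inside cohort bounds — lactating
  (18, 24), dry (10, 14) — then blended monotonically toward an
  NDF-rank-based profile until the across-diet correlation between ME
  concentration (MEI/DMI) and NDF reaches a target of −0.68 ± 0.05. That
  target is the correlation implying a variance inflation factor of
  1/(1−r²) ≈ 1.87 for an ME+NDF model, i.e. the degree of energy–fibre
  confounding a realistic dairy diet set exhibits. The blend never leaves
  the bounds; if the target is unreachable the completion fails loudly with
  the closest achievable correlation.
- **GE** is ME plus a constant 6.5 MJ/kg DM, realising exact GE–ME
  collinearity (r = 1.00): the two are interchangeable energy proxies and
  an equation set never needs both.
- **Ash** defaults to 7.5 % DM; exactly one registry equation uses ash, so
  results are insensitive to this choice (the leave-one-equation-out
  analysis covers the equation concerned).

What the completion does *not* emulate: real DMI varies with milk yield,
body weight and parity, not only with diet fibre; real GE–ME gaps vary with
diet digestibility; ash varies by ration. Consequently the fitted
coefficients on the packaged data are conditional on the completion, and
tests that pass on this data demonstrate correctness of the machinery and
calibration of magnitudes — not that the packaged coefficients equal those
obtainable with the withheld intakes. The package therefore also ships the
reference combined equation (0.33·ME + 0.31·NDF + 3.47) separately from
anything it fits.

`generate_synthetic_diets` draws fully synthetic rations whose marginal
ranges span the fixture (NDF 32–53 % DM, CP 12–23, EE 2.7–6.5, FA 0–7.5,
forage 50–82), with ADF = 0.82·NDF ± ≤0.1 and MEI declining in NDF
(470 − 7·NDF ± 20 MJ/day) as energy-dense rations carry less fibre.
`simulate_predictions` generates prediction tables from the known
random-intercept model and records the drawn equation intercepts, enabling
parameter-recovery checks against ground truth.

All stochastic operations take explicit integer seeds
(`numpy.random.default_rng`); the pipeline manifest records seed, full
configuration and its hash.

## The combining model

With predictions nested in equations, the model is

    y_ij = b0 + sum_j b_j X_ij + u_i + e_ij,
    u_i ~ N(0, sigma_equation^2),  e_ij ~ N(0, sigma^2)

fitted by REML. Random slopes are not offered: per-equation slopes on this
kind of data tend not to converge and add no substantive fit, so the model
is deliberately restricted to one grouping factor with a random intercept.

Predictors are centred and scaled with the sample (n−1) SD over the *long*
table (480 rows for the packaged design, i.e. the 15 diet values stacked
once per equation), because that is the table the model is fitted to; this
convention is what makes the published standardized NDF slope (1.88) divide
down to the raw slope 0.31. The response is never standardized, so the
fitted intercept sits on the g CH4/kg DM scale (it equals the grand mean of
the response for centred predictors).

### REML implementation

Because the covariance structure is a single scalar random intercept, the
REML criterion is profiled to one dimension (`emeq.lmm`): for a fixed
variance ratio λ = σ²_equation/σ², the GLS fixed effects, residual scale
and restricted likelihood are closed-form, with (I + λZZ')⁻¹ applied as a
per-group rank-one downdate. A bounded scalar search over log λ (with an
explicit λ = 0 boundary check) then yields estimates accurate to near
machine precision, including the two degenerate cases that matter for
testing: σ²_equation = 0 (the fit collapses exactly to pooled OLS) and
noise-free data (residuals collapse to ~1e−15 and held-out prediction is
exact). Numerical guards: the residual quadratic form is floored at 1e−300
before the log so the criterion stays finite on noise-free data, and the
search is bounded at log λ = ±25 — far beyond any statistically meaningful
ratio — to keep the profiled normal equations well-conditioned at the
extreme-shrinkage end. The implementation is cross-checked in the test
suite against statsmodels `MixedLM` and R `lme4` on the same data.

Random intercepts are reported as BLUPs. Model metrics follow the
conventions: R² is the squared Pearson correlation between observations
and fitted values *including* the random intercepts (the R² flavour is not
uniquely defined for mixed models; this conditional-fit version is used
and documented), RMSE is the root mean squared residual on the same fitted
values, and "residual variance" is the REML σ². Both variance components
are always reported, along with the between-equation SD
√(σ²_equation) — the expected disagreement between two published equations
given identical diet composition.

### Candidate models and selection

Twelve predictor combinations are compared (every combination includes
NDF; all but two include an energy proxy, GE or ME, never both). The
collinearity screen groups variables whose pairwise |r| across diets
exceeds 0.75 and keeps one representative per cluster (NDF over ADF, ME
over GE by default); VIFs are computed on the fitted design as
1/(1−R²_j). Slopes are called significant by the |t| > 2 rule
(t = estimate/SE); no degrees-of-freedom approximation is layered on top,
as the screening rule does not use one. Selection prefers, among fully
significant candidates, the fewest predictors, then lower RMSE, then ME
over GE as the energy proxy (ME+NDF and GE+NDF are numerically equivalent
fits when GE is an affine shift of ME, so the preference is what breaks
that tie). If no candidate is fully significant the best-RMSE fit is
returned with an explicit flag.

## Validation

**Leave-one-diet-out CV.** Each diet is held out, the model refitted, and
the held-out records predicted as fixed effects plus each equation's
*training* random intercept — the equations are the same groups in
training and test, so their intercepts transfer. Per-diet skill is
R² = 1 − SSE/SST over the held-out records (configurable in principle;
1 − SSE/SST is used because SST within a held-out diet is exactly the
between-equation disagreement the combined equation is meant to explain).
Diets whose refit fails are flagged and excluded from aggregates with a
warning. On the default packaged run the mean held-out R² is ~0.6, with
the dry-cow diets hardest to predict — they sit at the boundary of the
predictor space, so more between-equation variance remains unexplained
there, and predictions for dry cows should be interpreted cautiously. A
configuration switch excludes the dry-cow diets from fitting entirely.

**Leave-one-equation-out sensitivity.** Each equation is removed in turn
and the model refitted; the back-transformed coefficients are tabulated
with their min–max ranges, which always bracket the full-data coefficients.
Narrow ranges (the packaged default run confines the NDF slope to
0.36–0.38) mean no single published equation drives the combined fit.

## Numerical and reporting conventions

All arithmetic is double precision; values are rounded (2 dp) only at the
reporting layer. Ties in model selection are resolved deterministically
(RMSE compared after rounding to 6 dp, then the ME-over-GE preference,
then model id). Pipeline outputs are plain CSV/JSON tables; figures
(per-diet boxplots, random-intercept dot plot) are optional renderers over
those tables, not part of the run artefacts.

Problem sizes used by the shipped tests and the acceptance script: the
full 32 × 15 packaged design (480 records) everywhere; parameter-recovery
and CV-envelope properties use 10–100 seeded replicates of that design,
which this implementation fits in well under a second per hundred fits.

## Known limitations

- The completion is a model of the withheld intakes, not a reconstruction;
  fitted coefficients on packaged data shift with the completion settings
  (the energy slope more than the fibre slope, since the NDF column is
  fully observed).
- The registry's unit assignments for two source families are
  magnitude-audited rather than source-verified (`unit_uncertain` flags).
- The combined equation is derived from temperate, predominantly lactating
  UK-style rations; extrapolation to markedly different feeding systems
  (tropical forages, maize-based TMRs) is unsupported.
- The mixed-model engine is deliberately minimal: one grouping factor,
  random intercept only. Anything richer should use a general LMM package.
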