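# scar16

Genotype–phenotype analysis toolkit for **SCAR16** (spinocerebellar ataxia
autosomal recessive 16), the cerebellar ataxia caused by coding mutations
in *STUB1*/CHIP. The package is aimed at rare-disease analysts working
with small mixed-type cohorts: it screens clinical and biochemical
variables with false-discovery-rate control, fits reduced partial least
squares (PLS) models of ataxia severity (SARA, 0–40) and age of onset
(AOO, years), and runs Monte Carlo desirability simulations that identify
biochemical changes to mutant CHIP predicted to lessen disease severity.

## What it computes

**Screening.** Distribution tests (Shapiro–Wilk *W* for continuous
variables; likelihood-ratio χ² against an equal-frequency null for
categorical ones), bivariate association tests dispatched by type —
pooled *t* test / one-way ANOVA with Tukey–Kramer post hocs, OLS
regression, and a two-tailed Fisher's exact test on 2×k contingency
tables computed by exhaustive enumeration (point-probability definition)
— with Benjamini–Hochberg *Q* values per screening family and a default
flag at *Q* < 0.10.

**Multivariate structure.** Pairwise-complete Pearson correlation matrix
with FDR control, and Ward minimum-variance clustering of standardized
biochemical profiles (merge costs are error-sum-of-squares increases).

**PLS with VIP reduction.** A NIPALS PLS engine (single- or
multi-response) with effect-coded categorical factors, leave-one-out
PRESS factor selection, and variable importance in projection,

    VIP_j = sqrt( p · Σ_a SS_a (w_ja / ‖w_a‖)² / Σ_a SS_a ),

where SS_a is the Y-variance captured by factor *a*. Predictors with
VIP ≤ 0.8 are dropped and the model refit once; each response is exported
as a raw-scale linear equation, e.g. the reduced severity models

    AOO  = 20.6 − 3.9·z(%HSP70 Ub) + 5.3·z(%Ub chain) + 4.9·z(K_D) − 7.1·z(B_max)
    SARA = 18.8 + 1.9·z(%HSP70 Ub) + 0.2·z(%Ub chain) − 2.3·z(K_D) + 0.3·z(B_max)

with z(x) = (x − mean)/SD using the cohort locations/scales
(43.7/15.5, 69.9/39.0, 7.8/6.0, 212.0/16.6). The estimator
`PLSVIPRegressor` follows scikit-learn fit/predict conventions and
composes with sklearn tooling.

**Desirability simulation.** Inputs are drawn from normal distributions
whose means are adjustable settings; responses are scored with one-sided
Derringer–Suich ramps anchored at the baseline mean and saturating at the
improvement target (one response SD: +11 years AOO, −10 SARA points);
overall desirability D is the geometric mean across responses, maximized
by a seeded random search with coordinate refinement.

A synthetic-cohort generator reproduces the documented study conditions
(trait frequencies, biochemical locations/scales, the linear effect
structures plus noise), so the full pipeline is testable without the
original patient tables.

## Worked example

```bash
$ scar16 simulate --n-draws 5000 --seed 1 --optimize
baseline: AOO 20.6 y, SARA 18.8
optimized: AOO 60.5 y, SARA 5.4  (D=0.990)
```

The baseline run draws the four biochemical inputs at the cohort means
and recovers the cohort-level severity (mean AOO 20.6 years, mean SARA
18.8 — the equation intercepts, as expected for affine models). The
optimizer then moves the settings toward lower HSP70 ubiquitination,
lower chain formation and weaker HSP70 binding (higher K_D), pushing
essentially all simulated patients past both improvement targets
(D ≈ 0.99): further inhibiting residual mutant-CHIP activity toward
HSP70 is what the models predict to lessen severity.

```bash
$ scar16 synth --n 24 --seed 7 --out-dir demo
$ scar16 pls --cohort demo/cohort.csv --response sara
retained predictors: ['ancestry', 'cd']
factors: 2  R^2[sara]: 0.504
```

On a 24-patient synthetic cohort the VIP screen retains cognitive
dysfunction and ancestry — two of the three factors the generator's
effect model actually uses — and the reduced model explains ~50% of the
SARA variance. `scar16 run` executes the whole pipeline (distribution
table, contingency table, screens, correlations/clustering, PLS,
simulation) and writes one CSV per stage plus a checksummed manifest.

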