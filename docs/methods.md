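# Methods

This note records the statistical model, the defaults and the numerical
choices behind the package, and what the synthetic-data tests do and do
not establish.

## Data model

The cohort table holds one row per patient: sex, ancestry
super-population (AMR, SAS, MENA, EUR, EAS), homozygosity, the protein
change on each allele, age of onset (AOO, years > 0), SARA score (0–40),
and the binary phenotypes cognitive dysfunction (CD), increased tendon
reflex (TR) and hypogonadism. Only AOO and hypogonadism may be missing;
every test is complete-case for its own variable pair, so per-test n can
differ. The biochemistry table holds one row per characterized CHIP
variant: K_D (μM) and B_max (μmol·min⁻¹) for the HSP70 EEVD peptide,
%HSP70 ubiquitination, %ubiquitin-chain formation relative to wild type,
melting temperature, oligomer class (dimer vs higher-order) and relative
cellular stability %E, plus the wild-type reference row
(73.1, 100, 2.9, 204).

Allele-level analyses expand each patient to one record per substitution
allele; stop-codon and frameshift alleles are dropped (no protein to
characterize, and transcripts are expected to be removed by
nonsense-mediated decay). Whether a homozygous patient contributes two
allele copies or one distinct mutation is a config switch
(`per_allele_copy`, the default, vs `per_distinct_mutation`): published
per-allele percentages do not disambiguate the two conventions, so both
are computable. The mutation→domain map ships as a versioned resource
built from CHIP's residue ranges (TPR 1–126, coiled-coil 127–229, Ubox
230–303); substitutions absent from the file are assigned by the same
residue rule at load time.

## Screening statistics

Continuous distributions are tested with Shapiro–Wilk; categorical ones
with a likelihood-ratio χ² (G = 2·Σ O·ln(O/E)) against an equal-frequency
null over the *observed* levels, df = levels − 1 — the natural reading
when the reference level set is unstated. Bivariate dispatch:
continuous×continuous → OLS regression (slope, R², F-test p);
continuous×categorical → pooled-variance t test for two usable levels
(Welch behind a flag) or one-way ANOVA with Tukey–Kramer post hocs
(unbalanced-safe; singleton levels excluded and reported);
categorical×categorical → Fisher's exact test.

Fisher's two-tailed p uses the point-probability (Fisher–Irwin)
definition: the sum over all tables with the observed margins whose
conditional probability does not exceed the observed table's (relative
tie tolerance 1e−7, matching R's convention). 2×2 and 2×3 tables share
one exhaustive-enumeration code path; the doubled-one-tail alternative is
available behind a flag because software defaults differ. A zero margin
makes the test vacuous: p = 1 with a warning rather than an error.

Multiplicity is controlled per analysis family (one family per screen,
one per correlation matrix), not globally, using Benjamini–Hochberg
step-up Q values with a default discovery flag at Q < 0.10. Note that BH
is *not* idempotent in general — re-adjusting an adjusted family can only
raise Q values — so "already adjusted" families are treated as final.

## Multivariate structure

Correlations are pairwise-complete Pearson ρ with two-sided p from the t
transform; pairs with fewer than 3 complete cases or zero variance are
reported missing, and Q is computed across the strict upper triangle.
Clustering standardizes variables to mean 0, sample SD 1 (ddof = 1) and
applies Ward's minimum-variance linkage to rows; reported merge costs are
the error-sum-of-squares increases (linkage height²/2), verified against
brute-force greedy ESS agglomeration in the tests. Tie-breaking follows
the linkage implementation's deterministic ordering.

## PLS engine

Continuous predictors are standardized; a k-level factor contributes k
indicator columns, each centered and scaled like any other column, so
every level appears in the exported equation. The NIPALS inner loop
(tolerance 1e−10 on the score vector, max 500 iterations) deflates both
X and Y per factor; Y is centered/scaled internally and predictions are
returned on the raw response scale. With as many factors as the design's
rank, predictions coincide with OLS (tested to machine precision, and
cross-checked against scikit-learn's PLS at reduced rank).

Factor count is chosen by leave-one-out PRESS on a per-response
standardized scale, with the *first-minimum* rule (stop when the next
factor stops improving); A = 0 is the intercept-only model. LOO folds
re-encode the design, so centers/scales are honest; a fold that loses all
variation in a column (e.g. a singleton factor level left out) falls back
to mean-only prediction for that fold, and a level unseen in training
contributes zeros before centering.

VIP is computed per design column with Y-variance weights SS_a = (tᵀt)(cᵀc);
mean VIP² = 1 by construction. Reduction is one-pass: fit everything,
drop predictors whose best column VIP ≤ 0.8, refit once; a categorical
factor is retained whole if any level clears the cutoff, since the
exported equation reports an offset for every level. The refit's factor
count is re-selected but capped at the initial fit's. If nothing clears
the cutoff the single best predictor is kept rather than returning an
empty model.

Exported equations are affine in raw inputs: intercept + Σ coef·(x −
center)/scale + per-level offsets. Offsets are recentered to sum to zero
per factor (the removed mean folds into the intercept), so evaluation is
exactly the model prediction. The shipped reference equations keep their
published coefficients verbatim, including an ancestry block whose
printed offsets sum to −0.9 rather than 0 — a rounding artifact retained
deliberately (the validation tolerance admits it).

Exact reproduction of published coefficient values from the original
cohort is treated as a stretch goal: the original analysis ran in a
commercial package whose factor-selection criterion and categorical
scaling conventions are not fully specified, so the contract is sign and
ranking agreement, which the parameter-recovery tests enforce on
generator-known ground truth (raw-scale slopes within ±15% at n = 500,
≥ 80% of 20 seeds).

## Simulation and desirability

Inputs are normal with adjustable means ("settings") and fixed SDs; each
equation is evaluated per draw (5000 by default). Desirability is a
one-sided linear ramp: 0 at the anchor (baseline mean), 1 at the target,
clipped outside; minimize goals are mirrored; a smooth logistic variant
through the same two points is selectable. The reference configuration
anchors at the baseline means (20.6 years, 18.8 points) with targets one
response SD away: +11 years AOO and −10 SARA points — the SARA offset is
the *cohort* SD of observed SARA, not the model-implied response SD.
Overall D is the geometric mean of per-response mean desirabilities.

Optimization adjusts input means only (SDs fixed), within default bounds
of mean ± 3 SD floored at 0 for physical quantities: ~60% of the
candidate budget goes to uniform random search, the rest to 11-point
per-coordinate grid refinement, all candidates sharing common random
numbers (250 draws each) so comparisons are smooth. The baseline is
always a candidate and the returned optimum is re-scored on the final
draw stream against the baseline, so it weakly dominates baseline
desirability by construction. One caveat of saturating ramps: once every
draw clears a target, D plateaus and any plateau point is reported —
optimized settings are then one representative of an optimal region, not
a unique optimum. One master seed spawns separate, reproducible streams
for the baseline, search and final evaluations.

## Synthetic cohort generator

The generator reproduces the documented study conditions: trait
frequencies (54% male; ancestry 4/4/25/33/33; 46% homozygous; 75% TR;
17% hypogonadism), biochemical locations/scales (43.7/15.5, 69.9/39.0,
7.8/6.0, 212.0/16.6), and CD arising from the allele's domain — 94%
given a Ubox allele, 59% otherwise. Domain draw weights (0.40/0.30/0.30)
are the unique solution making the implied overall CD frequency ≈ 71%
under that conditional structure. SARA is generated from the clinical
effect model (CD ±5.6, ancestry block, TR ±2.7 around 17.2) plus
Gaussian noise clamped to [0, 40]; AOO from a homozygosity effect (±6
years around 17, i.e. a 12-year gap) clamped positive. Residual SDs
(SARA 6, AOO 8) are free parameters — no empirical values exist for them
— and are flagged as such in the config.

Physical bounds are enforced by clipping, not resampling; clipping
biases means upward when the bound is within ~2 SDs (about +0.3 on K_D at
mean 7.8, SD 6), which the location tests tolerate. Marginals of AOO and
SARA come from the effect models rather than being matched to published
medians: downstream tests need known ground-truth structure, not
distributional cosmetics. Rare ancestry levels are kept so 5-level
effect coding is exercised. A null variant of the generator zeroes every
effect, which is the testbed for the screening stage's type-I error;
that check is restricted to the continuous-response screens (t/ANOVA/
regression are exact under normality), because Fisher's exact test is
conservative by construction at n = 24 and sits below any nominal band.

What passing on synthetic data does **not** show: recovery of the
published coefficient values from the real cohort, realism of mutation
spelling or allele frequencies, or any non-linear structure — the
generator is linear by design.

## Problem sizes

Defaults are cohort-scale throughout: 24 patients, 13 mutants + WT, 5000
simulation draws, a 5000-candidate optimization budget, 500-replicate
null calibration, and 20-seed recovery studies — sizes at which the full
test suite and the acceptance script each complete in minutes on one
core.
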