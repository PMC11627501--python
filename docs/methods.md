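# Methods

## Scope and data model

`xbrainage` implements a cross-species brain-age analysis over tables of
homologous structural features.  Every subject — human or macaque — is a
row of 260 named features: 92 regional gray-matter volumes (46 bilateral
pairs of a regional-map-style parcellation) and 42 white-matter tracts
(19 bilateral pairs + 4 commissural tracts of a cross-species tract
atlas) × four diffusion metrics (FA, MD, AD, RD).  The schema is shared
between species by construction; that homology is the entire basis for
applying a model trained in one species to the other.  The full 92-label
gray-matter list of the original parcellation is not published as a flat
list, so the default schema carries the recoverable anatomical labels
and pads the remainder with placeholders explicitly marked synthetic
(`SYN44`–`SYN46`); users with a concrete atlas can supply their own
label lists.

Image-space processing (segmentation, registration, tractography,
atlas extraction) is out of scope: the package starts from feature
tables.

## Harmonization

Macaque cohorts span two scanners, so feature tables are adjusted with a
parametric empirical-Bayes location/scale model (the standard ComBat
formulation): per feature, covariate effects and a pooled variance are
estimated by OLS on a batch+covariate design; data are standardized;
per-(batch, feature) location γ and scale δ² are shrunk across features
toward normal / inverse-gamma priors whose hyperparameters come from
method-of-moments; the data are rebuilt with the shrunken effects
removed and covariate effects restored.  The implementation is validated
against Bioconductor `sva::ComBat` (agreement ≈ 1e-7 on a shared
fixture) and, with shrinkage disabled (`eb=False`), reduces exactly to
per-batch standardization, which serves as a small-instance oracle.

Choices worth flagging:

- **Covariates preserved: sex only.**  Site is the batch variable, and
  age is deliberately *not* protected.  With sites assigned at random
  this is harmless; if sites differ in age composition the adjustment
  can attenuate age signal — a real limitation, surfaced in the tests
  only as the preserved-correlation check.
- **All five measures are harmonized** (GMV, FA, MD, AD, RD), each
  measure as its own ComBat family (`harmonize_by_measure`), so EB
  priors pool only across features of one imaging index.
- Harmonization happens at **feature level** (post-parcellation); the
  voxel level is out of scope here.  The model is identical, the
  granularity is not.
- A single-batch fit is the identity by definition — there is nothing
  to remove — rather than a degenerate EB estimation.

## Feature selection

Per repetition, one random ten-fold partition is drawn; one fold is held
out and the remaining nine-tenths is the screening/training set.  All
features are Pearson-correlated with age there; two-sided p < α
(default 0.01, strict) survives.  The linear model fitted on the
surviving features gives the repetition's held-out MAE.  Default 100
repetitions.  Reductions: the **common** set (intersection over all
repetitions; order follows the schema), the **min-MAE** set (the
selection of the best repetition; empty selections are excluded from
that competition with a warning), and **top-k** by |r| on the full
sample with ties broken by schema order.

One fold partition is drawn *per repetition* (a fresh 90/10 split each
time), not one fixed partition reused 100 times; with a fixed partition
the "common" intersection would degenerate to a single screening.
Whether min-MAE uses held-out or in-sample error is a genuine design
fork; held-out is used, as the less optimistic choice.

Screening is calibrated: on pure-noise features the per-repetition
selection rate is α (checked against the binomial band over 500
replicates), and on fully null data the probability that any feature is
common to 100 independent screenings is bounded by α¹⁰⁰ per feature.

## Age model

OLS of age on z-scored selected features with intercept, solved by
minimum-norm least squares (`numpy.linalg.lstsq`), so rank-deficient
designs — duplicated features, p > n — yield well-defined predictions
with a logged warning instead of an error; no regularization anywhere.
Standardization statistics always come from the training sample of the
fit at hand (training folds during CV, the full own-species sample for
the transferable model).

Within-species performance is repeated ten-fold CV (default 100
repetitions): every subject is predicted exactly once per repetition by
a model that never saw it; the final per-subject prediction is the mean
of its held-out predictions, and R/MAE are computed on those finals.
The transferable model is the single full-sample fit — "the trained
model", not the CV ensemble.

**Cross-species standardization** is the one genuinely open choice: the
foreign table is z-scored with the *foreign* species' own statistics.
Raw feature scales differ grossly between species (absolute volumes,
diffusivity ranges), so scoring raw or training-scaled foreign data
would measure scale differences, not developmental pattern.  The
consequence is that cross-species predictions live in the training
species' age units and are centred at the training cohort's mean age;
cross-species MAE is therefore dominated by the offset between the two
species' age ranges (~8 years here), and in the regime where every gap
has the same sign, both directions' MAEs collapse to the difference of
cohort mean ages.

## Gap and BCAP

The absolute brain-age gap is |actual − predicted|.  Its correlation
with actual age characterizes transfer systematics: a macaque model
predicts humans near the macaque mean age, so the human-cohort gap is
essentially (age − constant) and correlates with age at r ≈ 1; a human
model applied to macaques over-predicts with an attenuated slope (< 1
year per year), so the macaque-cohort gap *shrinks* with age and the
correlation is negative.

Percentiles use the mean-rank tie convention, pct(vᵢ) = 100·(c_lt +
½·c_eq)/n, equivalently 100·(rank_avg − ½)/n.  This makes the mean
percentile exactly 50 and the mean BCAP exactly 0 — identities used as
invariants — and makes BCAP invariant under strictly monotone transforms
of either prediction vector, antisymmetric under swapping them, and
permutation-equivariant.  BCAP is computed on the repetition-averaged
own-model CV predictions versus the full-sample macaque-model
predictions, and only for the human cohort.

## Associations

"Pearson correlation with age as covariate" is implemented as partial
correlation: residualize both variables on [1, age] by least squares,
correlate the residuals, p from the t transform with n − k − 2 df.
With zero covariates it equals plain Pearson exactly.  Behavioral
tables may have missing entries; rows are dropped pairwise-complete and
df adjusted per test; behaviors with fewer than 10 complete pairs are
skipped with a warning.  FDR control is Benjamini–Hochberg.  Family
boundaries are a choice the source analysis leaves open: one family for
the 40 behaviors, and one family per measure (GMV/FA/MD/AD/RD) for the
260 structural features.

Feature classification across species: common = intersection of the two
species' selected sets, specific = the set differences; per-measure
percentages are computed within each measure over the union restricted
to that measure (a within-class alternative is exposed as an option).

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes,
not images or growth curves.  Cohort shape (defaults): 370 humans aged
8–14 y, 181 macaques aged 2–4 y split ~42/139 across two scanner sites,
sex ratios 170/200 and 89/92, ages uniform within each range (only
range and mean±SD of the real cohorts are known; uniform keeps leverage
spread).  Each feature is baseline + slope·age + site effects (macaque
only) + N(0, σ²) noise, with σ = 1 so slopes are in noise-SD units per
year.

Planted classes: 40 common-informative features (same slope sign in both
species), 60 human-specific, 10 macaque-specific, remainder pure noise.
Human-specific features are routed 80% into white matter and
macaque-specific 80% into gray matter (configurable), echoing the
qualitative compartment pattern the analysis is meant to expose.  Site
effects are one shift ~N(0, 0.5²) and one scale ~U(0.9, 1.1) per
(site, feature), recorded in the ground truth.

Calibrated defaults, chosen once at design time:

- `effect_size_range = (0.15, 0.45)` per year.  Over the 6-year human
  window this yields feature–age correlations of roughly 0.25–0.6,
  the plausible range for developmental structural effects.
- `macaque_slope_scale = 2.0`: macaque per-year slopes are doubled.
  The 2–4 y window covers a faster developmental phase, and without the
  scaling macaque features would rarely survive p < 0.01 screening over
  a 2-year age span, leaving the common set empty.
- **Latent divergence** is the *realized* age-adjusted expression of the
  human-specific features: the standardized per-subject mean of
  sign(slope)·(observed − expected) over that set.  An independently
  planted shared factor is the obvious alternative, but multivariate OLS
  provably cancels a common factor that is orthogonal to age (the
  conserved features supply a latent-free age estimate), so such a
  factor is *not* recoverable by any prediction-based statistic and
  additionally pushes the model toward conserved features, destroying
  the transfer asymmetry.  The realized-residual definition is exactly
  the quantity an own-model-minus-foreign-model contrast can see.  A
  shared-factor option (`latent_loading`) remains available, default 0.
- Behaviors: 40 columns, the first 2 load on the latent divergence with
  slope 2.0 against unit noise (r ≈ 0.89 with the latent), plus a mild
  age confound (0.2/y) that the partial correlation must remove; 10%
  missingness completely at random.  The strong loading represents a
  behavior genuinely driven by the divergence axis; weaker loadings are
  a power dial for sensitivity studies, not the default condition.

With these defaults the designed qualitative signature — macaque→human
transfer R above human→macaque, gap–age r positive in humans and
negative in macaques, BCAP–latent correlation ≈ 0.3–0.4, both planted
behaviors surviving FDR — held in 15/15 design-phase seeds before the
test suite froze them.

### What the generator does not emulate

Linear noise-additive features only: no nonlinear growth, no
feature–feature covariance beyond the optional shared factor, no
age-by-site confounding, no heavy-tailed measurement error, no
longitudinal structure, and behaviors missing completely at random
rather than by design.  Passing tests therefore demonstrate that the
*pipeline machinery* is correct and calibrated under the assumed data
model — they do not certify performance numbers on real human/macaque
cohorts, whose headline statistics depend on restricted-access data.

## Numerical choices

- Determinism: every stochastic routine takes a seed or Generator; the
  pipeline fans one seed into per-stage child seeds via `SeedSequence`
  so stages can be rerun in isolation.
- Percentile ties by mean rank (see above); |r| ties in rankings broken
  by schema order via stable sorts.
- Constant feature columns are excluded from screening with a warning
  (never selected); constant prediction vectors leave R undefined (NaN)
  but still yield MAE.
- Collinearity in partial correlation is detected by residual norm
  relative to the variable's own spread (tolerance 1e-8).
- EB shrinkage iterations run to an absolute change of 1e-10 (cap 500);
  degenerate hyperpriors (zero across-feature variance) fall back to
  unshrunken estimates with a warning.
- Problem sizes in the test suite: calibration checks run at n = 300–370
  with the full 260-feature schema; repeated-CV depth is reduced (3–20
  repetitions) in unit tests and kept at the full 100×10 in the
  end-to-end determinism check, which completes in well under a minute
  per run.

## Known limitations

- Age is unprotected during harmonization (see above).
- No bias correction of brain-age estimates (the well-known
  regression-to-the-mean of gap scores); gap–age correlations are
  reported raw, which is intentional for the transfer analysis but
  would overstate within-species gap effects.
- The BCAP is defined for the human cohort only; a macaque-side analogue
  would need a symmetric treatment that is deliberately not provided.
- The min-MAE criterion selects on a single held-out fold and is
  noisy; the common-feature criterion is the default for that reason.
- Sex-stratified runs reuse the global configuration; strata smaller
  than the fold count are rejected rather than silently re-folded.
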