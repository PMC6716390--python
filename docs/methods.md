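# Methods

This note documents the statistical machinery in `lexacq`: the
generative model behind the synthetic studies, the predictor
definitions, the imputation procedure, the mixed-model fitting and its
approximations, the consistency analysis, and the numerical and design
choices that were genuinely open.

## Word predictors

Nine word-level predictors enter every model, in this fixed order:
`frequency`, `solo_frequency`, `final_frequency`, `mlu_w`,
`n_phonemes`, `concreteness`, `valence`, `arousal`, `babiness`.

**Frequency.** Unigram counts over adult utterances only, case-folded,
whitespace-tokenized. A token is resolved in a fixed order: an
inflection/synonym variant contributes its full mass to its canonical
item; otherwise a polysemous form splits mass `1/k` uniformly over its
`k` sense items; otherwise an exact word-form match counts; otherwise
the token is tallied as unmapped. Mass is conserved: mapped mass plus
unmapped tokens equals the adult token total. Counts are normalized
per million corpus tokens (the base is recorded in the output
metadata so corpora of different sizes remain comparable), Laplace
smoothed — a count of 0 is replaced by 1 *before* normalization — and
natural-log transformed.

**Solo and final frequencies.** Solo: the utterance consists of
exactly one token and it maps to the item. Final: the last token of an
utterance of length ≥ 2 maps to the item (single-word utterances are
excluded from final counts by definition). Both pass through the same
smoothing/normalization as frequency and are then residualized against
log frequency by simple OLS, so they measure variance beyond plain
frequency. Residualization runs before within-language scaling;
residuals are centered and orthogonal to the covariate by
construction (asserted to `1e-8` relative).

**MLU-w.** Mean length in words of the utterances containing the item,
one contribution per occurrence, weighted by the same fractional
polysemy mass as frequency. Items with total occurrence mass below 10
(configurable; the threshold compares possibly fractional mass) are
missing.

**Number of phonemes.** Symbol count of a space-delimited phonemic
transcription supplied as input; never missing.

**Norms.** Concreteness (1–5), valence and arousal (1–9), babiness
(1–10) are supplied rating columns, merged by item id.

**Scaling.** Every numeric predictor is centered and scaled within
language using the sample SD of non-missing values; missing cells stay
missing; constant columns are an error. Scaling means/SDs are emitted
as metadata.

**Collinearity diagnostics.** Pairwise Pearson correlations and
`VIF_p = 1/(1 − R²_p)` from an intercept-augmented OLS of each
predictor on the others, on the completed table.

## Imputation

Iterative regression imputation within language: missing cells are
initialized by sampling with replacement from the observed values of
the same column (the only stochastic step; seeded), then columns are
swept in the declared predictor order, re-imputing each column's
missing cells as the deterministic linear-regression prediction from
all other columns, the regression being trained on the originally
observed rows. Sweeps stop when the maximum absolute change of any
imputed cell falls below `1e-6` or after 20 sweeps (both
configurable); the iteration count, final change and per-column
imputed counts go into a convergence report. Observed cells are never
modified. Monotone convergence is not guaranteed by the procedure and
is not asserted — it is checked empirically and reported. No noise is
added at the imputation step and no multiple imputation is attempted;
the completed table is treated as fixed downstream, so predictor
uncertainty from imputation is not propagated (a known limitation).
In the pipeline, imputation runs on the unscaled table and scaling
follows it, so the scaled table is complete with exact unit moments.

## The acquisition model

Per language × measure, a binomial-logit mixed model over child × word
responses. Fixed effects: intercept, standardized age, the nine
predictors, optionally predictor × age interactions and predictor ×
lexical-category interactions plus category main effects. Category
contrasts are deviation (sum-to-zero) coded over
{Nouns, Predicates, Function Words, Other} with `Other` as the dropped
level; treatment coding is available and fixed-effect predictions are
coding-invariant (tested to `1e-6`). Random effects: a per-word
intercept and age slope, bivariate normal with optional estimated
correlation. Per-child random effects are deliberately omitted, so a
separate model is fitted per language × measure rather than one joint
model.

**Age scaling.** Ages are integer months; age enters as
`(age − midpoint) / half-range` of the configured instrument range
(default 8–30), so age spans roughly [−1, 1] and interaction
coefficients are on comparable standardized scales. The instrument
range, not the realized sample range, defines the transform so that
different samples of the same instrument are scaled identically.

**Exact binomial aggregation.** Every fixed and random covariate is a
function of (word, age) only, so Bernoulli responses are aggregated
into binomial (word, age) cells before fitting. The likelihood is
identical; the row count drops from `children × words` to
`words × ages`, which is what makes the simulation studies cheap.

**Laplace fitting.** For fixed variance parameters θ the joint
(β, b) mode is found by penalized IRLS; the Newton system is solved
exactly via the Schur complement (the random-effect block is
block-diagonal with one 2×2 block per word), with step-halving on the
penalized deviance. The Laplace log-likelihood
`ℓ(θ) = loglik(ŷ) − ½ Σ_w b̂'Σ⁻¹b̂ − ½ Σ_w log det(I + Σ G_w)` is
maximized over θ = (log SDs, atanh correlation) by Nelder-Mead with
the inner state warm-started between evaluations. SD parameters are
bounded in `[1e-4, 20]` on the SD scale; at the lower boundary the
model collapses onto ordinary logistic regression (verified against
`statsmodels` GLM to well under `1e-2`). A fit against `lme4`
(`glmer`, nAGQ=1) on a shared dataset agrees in coefficients, standard
errors and random-effect SDs to three to four decimals.

**Small-sample Wald inference.** The conditional covariance of β given
θ̂ understates sampling variability when the number of words is modest:
the ML variance components are biased low (there is no REML for this
model) and their uncertainty is ignored. Null simulations put the raw
Wald-z rejection rate near 9% at α = .05 with 50 words. `lexacq`
therefore applies a between-within correction: the fixed effects that
carry only word-level information (no within-word variation) are
counted as `n_between`, the residual degrees of freedom are
`df = n_words − n_between`, standard errors are scaled by
`sqrt(n_words / df)` (the REML-analog adjustment of the dominant
variance term) and Wald statistics are referred to `t_df`. With the
correction the measured null rejection rate is 5.1% (pooled over 150
replicates of 1,000 children × 50 words). The correction vanishes as
the word count grows.

**Separation and identifiability.** The fitter raises on singular
fixed-effect systems, on non-positive-definite information at the
optimum, and when any fixed effect exceeds 30 on the logit scale
(quasi-separation). A structural caveat discovered in testing: with 9
predictors, the predictor × category interaction design becomes
*exactly* singular when a category cell has fewer than about 11 items
(the per-category slope columns cannot be full rank on fewer items
than predictors). `build_design` refuses category interactions when
any category has fewer than `n_predictors + 2` items; analyses with
category interactions should use lexicons of ~300 items or more under
the default 55/25/10/10 category proportions.

**Composed category effects.** The per-category effect of a predictor
is the sum of the predictor's main effect, the category's main effect
and their interaction, reported for the three named categories (the
reference level `Other` has no composed effect). Per-category cell
slopes are coding-invariant; the composed sum is defined relative to
the deviation-coded (grand-mean) intercept.

**Trajectories.** Per-word logistic curves of proportion knowing
versus age are ML binomial GLM fits (via `statsmodels`); all-known or
all-unknown words have no finite MLE and raise.

## Consistency analysis

Coefficient profiles are the nine main-effect estimates per language
(interaction terms are excluded by default; configurable). Pairwise
Pearson correlation between languages (Spearman available), each
language's mean correlation with the others, and a shuffled baseline:
each of 1,000 bootstrap replicates independently applies a uniform
random permutation to every language's coefficient vector and records
the per-language mean pairwise correlation; the 2.5–97.5 percentile
band is the null interval. Fewer than 100 replicates triggers a
recorded warning. The baseline is distribution-free — it conditions
on the observed values and only destroys their alignment across
languages. Calibration was verified by simulation: with independent
coefficient vectors the observed mean r falls inside the interval
≈ 95% of the time; a shared vector escapes above it essentially
always. Hierarchical clustering uses distance `1 − r` with complete
linkage by default (scipy), serialized as Newick with branch lengths
equal to merge-height differences. Per-category consistency applies
the same correlation machinery to the composed per-category effect
vectors and reports the mean of the upper-triangle correlations.

## The synthetic-data generator

The generator emulates the four input families with a known ground
truth so that every stage has an oracle.

**Lexicon.** Categories drawn i.i.d. from configurable proportions
(default 55% Nouns, 25% Predicates, 10% Function Words, 10% Other).
Latent standardized property values are multivariate normal with a
configurable correlation matrix; the default embeds the naturalistic
structure that makes collinearity diagnostics meaningful —
frequency–concreteness −0.35, frequency–word length −0.33,
MLU–solo −0.44. Word forms are pseudo-word syllable strings, unique
per language except for a few deliberately shared (polysemous) forms;
every item also has an inflected variant form.

**Corpora.** One adult-speech corpus per language. Each utterance
draws a head item with probability ∝ `exp(z_frequency)`; its length is
`1 + Poisson(target MLU − 1)` with the target derived from `z_mlu_w`
(clipped to [1, 12] words); the head lands utterance-final with
probability `logistic(z_final_frequency)`; other slots are filled by
frequency-weighted draws; 20% of tokens surface as inflected variants.
Extraction round-trips: at 20,000 utterances the extracted log
frequency correlates with its target at ρ ≥ 0.9.

**Administrations.** Integer ages uniform over the instrument range;
responses Bernoulli of the logistic model above, with per-word random
intercept/slope drawn from an explicit Cholesky factor (so zero SDs
are valid). Default effect profile: frequency 0.23, solo 0.17, final
0.13, MLU-w −0.14, phonemes −0.19, concreteness 0.18, valence 0.06,
arousal 0.003, babiness 0.13 — magnitudes chosen to emulate the
typical cross-language profile of these predictors — with age effect
2.0, random SDs 0.5 (intercept) and 0.2 (slope), and a comprehension
advantage of +0.5 logits over production (−0.5).

**Norms and missingness.** Ratings are noisy linear maps of the
latent values onto conventional scales, clipped to their ranges.
Missingness is MCAR with per-column rates (defaults: concreteness 1%,
valence/arousal 10%, babiness 20%; word length must stay complete).
Real-world missingness is resource-driven rather than MCAR; MCAR is
sufficient to exercise the imputation contract but means the tests do
not probe MAR/MNAR robustness.

What the generator does *not* emulate: longitudinal (repeated-child)
sampling, parental reporting bias, morphological tiers beyond a single
inflected variant per word, non-uniform sense frequencies for
polysemous forms, and cross-language differences in instrument
composition. Passing tests therefore demonstrate the statistical
machinery is correct under the stated model, not that real archives
would yield any particular effect profile.

## Pipeline scales and runtimes

The validation studies use these problem sizes, chosen as the
package's standard desk-scale conditions: type-I error — 50 replicates
of 1,000 children × 50 words; recovery — 50 replicates of 1,000
children × 100 words with a generating frequency effect of 0.4;
baseline calibration — 200 replicates of 5 languages × 9 predictors;
category ordering — 20 end-to-end runs of 5 languages × 300 items ×
250 children × 8,000 utterances, production only, with
language-specific function-word offsets drawn N(0, 0.5). The demo
pipeline configuration is 3 languages × 100 items × 500 children and
fits the model without category interactions (see the identifiability
caveat above).

## Known limitations

- Wald (not likelihood-ratio or bootstrap) inference for fixed
  effects; variance-component uncertainty enters only through the df
  correction.
- Single grouping factor (words); no child random effects, so
  within-child correlation is ignored, exactly as in the modeling
  design the package implements.
- Deterministic single imputation; no uncertainty propagation.
- The shuffled baseline calibrates the *mean* pairwise correlation,
  not individual pairwise entries.
- The generator's MCAR missingness and pseudo-word corpora are
  idealizations; see above.
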