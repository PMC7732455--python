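# Methods

This note documents the statistical procedures, the synthetic-cohort
generator that serves as the package's test bed, the numerical choices,
and the known limitations. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design and data model

The design is paired: each participant contributes a birth sample (DOL 0)
and exactly one follow-up sample at DOL 1, 3 or 7, so each follow-up day
defines a disjoint two-timepoint arm. Metadata validation enforces this
invariant and names offending participants.

Quantification follows the MaxQuant `proteinGroups.txt` conventions:
tab-separated, `+`-marked flag columns, and 0 meaning "not quantified" in
LFQ/iBAQ columns (MaxQuant never emits a true zero intensity). LFQ values
are log2-transformed on read and stay on that scale everywhere; iBAQ
values stay linear because the immunoglobulin analysis takes within-sample
ratios. Sample-column-to-ID mapping is an explicit input — no fuzzy
matching against raw-file names.

## Filtering

1. **Flags** — contaminants, decoy (reverse) hits and proteins identified
   only by modified peptides are removed; a multiply-flagged row is counted
   once (contaminant > reverse > modified-only).
2. **Valid values** — per comparison arm, a protein must be quantified in
   at least 50% of the arm's DOL0 samples *and* 50% of its follow-up
   samples. "Less than 50%" removes; exactly 50% is kept (the inclusive
   reading retains the most data). Restricting the count to the arm's own
   participants matches the paired per-day testing. The filter never
   creates or alters values. For the global PCA a union-across-arms variant
   is used, since ordination pools all samples.
3. **RNA** — genes matching globin patterns are dropped, as are genes with
   fewer than 10 counts in nine or more samples (both configurable).

## Batch correction

An empirical-Bayes location/scale adjustment (ComBat-style, parametric
priors) written to tolerate missing entries: every sum runs over observed
values only, and missing entries remain missing. Per protein the data are
standardised by a least-squares fit including protected covariates
(default: day of life and sex), per-batch location γ and scale δ² are
estimated, shrunk by iterated conditional modes (normal prior on γ,
inverse-gamma on δ², method-of-moments hyperparameters; convergence 1e-4,
max 100 iterations), and removed. A single batch returns the input exactly
(γ=0, δ²=1). The test suite cross-checks the output against the R
reference implementation (sva::ComBat) on complete data, where the two
agree to ~1e-5, and against a closed-form per-batch standardisation oracle
in the non-informative-prior limit.

Two deliberate additions to the textbook algorithm:

* `preserve_grand_mean` (default on) recentres each protein to its
  original observed mean after adjustment. EB shrinkage otherwise moves
  the per-protein grand mean by a small amount; the recentering is a pure
  location shift absorbed by any downstream intercept and makes the
  correction exactly mean-preserving.
* A rank-based confounding check refuses designs in which a protected
  covariate is aliased with batch, listing the aliased columns.

Note a structural property verified in development: EB shrinkage
deliberately retains part of each protein's *observed* batch deviation
(the prior pulls estimates toward the batch consensus), so per-protein
batch mean differences after correction are not zero — only the
systematic (protein-averaged) component of an injected artifact is removed
essentially completely. The reference implementation behaves identically.

## Global distribution test

A quantro-style permutation test for whether whole sample intensity
distributions differ between groups: each sample is summarised by 100
equally spaced quantiles of its observed values; the statistic is the
ratio of between-group to within-group mean squared deviation of these
quantile vectors; group labels are permuted (default 10,000 permutations)
and the p-value uses the add-one estimator (1 + #{perm ≥ obs})/(1 + n_perm),
which can never return 0. The probe count is an internal detail fixed at
100. Under an exchangeable null the test is exact (type-I error ≈ α);
under the paired design with participant random effects, same-participant
samples in different groups are positively correlated and the test becomes
conservative — a validity-preserving direction, verified by simulation.

## Left-censored imputation (ordination only)

LFQ missingness is abundance-driven, so missing values are treated as
left-censored. For PCA only, each sample's complete intensity distribution
is estimated by regressing the observed order statistics on
standard-normal quantiles with Blom plotting positions that account for
the censored mass below the detection limit; missing entries are then
drawn from a normal with that mean and sd × `tune_sigma` (default 0.3),
truncated above at the distribution's `q`-quantile (default 0.01). Draws
are seeded; observed values are never touched. The imputed matrix carries
an `imputed` provenance flag and every statistical stage refuses such a
matrix, so imputation is structurally quarantined to ordination. Samples
with fewer than 10 observed values are rejected (the quantile fit is
unstable there).

PCA itself is protein-wise mean-centred SVD. Unit-variance scaling is off
by default — log2 LFQ intensities share a scale — but exposed as a flag.

## Differential abundance

Per protein and arm: a random-intercept linear mixed model with fixed
effects day, sex and batch, random participant intercept. The day
coefficient is the reported log2 fold change (the raw mean paired
difference is reported alongside; with no covariates and complete pairs
the two coincide exactly, a property the tests assert at 1e-9). The
p-value is a 1-df likelihood-ratio test, both models refit by maximum
likelihood; REML refits provide the variance components for reporting.
Covariate columns aliased with the design (e.g. a batch constant within an
arm) are dropped with a logged warning. Proteins with fewer than two
complete pairs are marked not testable. BH correction is applied within
each follow-up day across proteins; the dual significance gate is
q < 0.05 and |log2FC| > 0.2.

The fitter is written in-package and vectorised across proteins: with
clusters of size ≤ 2 the covariance inverse and determinant are closed
form, so the profile likelihood in the single variance ratio θ = σ²_u/σ²_e
is evaluated for all proteins simultaneously and maximised by a golden-
section search on θ ∈ [0, 100] (45 iterations, boundary θ=0 checked
explicitly). The test suite verifies ML and REML estimates, likelihoods
and LRT p-values against statsmodels MixedLM to ~1e-6. This makes
100-replicate × 2000-protein null calibrations feasible in minutes.

Small-sample caveat: with 10–30 pairs per arm the χ²₁ reference for the
ML LRT is anticonservative in the extreme tail (the bulk of the p-value
distribution is uniform to KS ≈ 0.02–0.03 at 30 pairs, but p-values near
1e-5 run ~2× small). Consequently the realized false discovery rate of
the q < 0.05 gate under a 2000-protein global null is ~0.10 rather than
0.05, as the acceptance suite measures honestly. This is a property of
the ML-LRT/χ² method itself (any implementation, including the standard
mixed-model ANOVA, shows it); users needing strict small-sample FDR
control should interpret borderline calls accordingly.

Missingness analysis: per protein and arm, a two-sided Fisher's exact test
on the 2×2 detected/undetected × DOL0/DOLx table, computed on the matrix
*before* valid-value filtering, because that filter would silently discard
day-unique proteins.

## Trajectories and correlation

Δ = log2 intensity at DOLx minus the same participant's DOL0 value, one
column per follow-up sample, missing where either endpoint is missing.
Protein–protein Pearson correlation is pairwise-complete with a minimum of
6 shared observations (fewer ⇒ entry undefined); clustering is average
linkage on 1 − R with undefined entries treated as distance 1, and the
leaf order is deterministic. The single-target screen reports R with the
exact t-transform p-value and deliberately applies no multiple-testing
correction (it mirrors a raw-p exploratory table; stated in the output).

## Immunoglobulin kinetics

iBAQ ratios are taken within sample against a reference subclass (IgG2
default; switching the reference is an exact change of units, which the
tests assert). Newborn-vs-adult ratio differences use Welch's t-test. The
repository ships no real adult cohort; `synthetic_adult_panel()` generates
a clearly-labelled synthetic stand-in with the adult subclass ordering and
an IgG1:IgG2 ratio near 2.

The apparent half-life estimator is zero-intercept least squares of
participant-level Δ on elapsed days — Δ(0) = 0 holds by construction, so
the origin constraint is exact, and on noise-free first-order decay the
estimator recovers any t½ exactly (property-tested over 5–60 days). A
slope ≥ 0 flags t½ = +∞ (no net decay). The CI is a nonparametric
bootstrap over participants (default 2000 resamples, seeded), this
package's own choice of uncertainty quantification for the estimator.
Estimates are scale-invariant under
global log2 shifts. All-single-day inputs are fit (the origin constraint
still identifies the slope) but flagged.

Concentration projection multiplies a baseline concentration (e.g. mean
IgM at birth, 18.5 mg/dl) by a measured linear fold-change or interval.

## Protein–mRNA concordance

RNA counts are normalised by median-of-ratios size factors and
log2(count/sf + 1) — a deliberate lightweight stand-in for a full
negative-binomial DGE model, adequate because only paired Δ values enter
the correlation. Concordance is computed at two levels: across individual
follow-up samples, and across the three per-DOL mean Δ values; the
classification threshold (average-level R > 0.3) applies to the DOL-level
correlation, and every row carries an explicit "n=3, unstable" caveat
instead of a p-value. By the arcsine law a 3-point null correlation
exceeds 0.3 about 40% of the time, so the classifier's false-call rate on
non-concordant pairs is intrinsically high — the tests freeze that band
and assert discrimination (high-target pairs called concordant far more
often than low-target pairs) rather than a small absolute false rate.

## Synthetic cohort generator

The generator emulates the study conditions rather than any particular
dataset: 30 participants split 10/10/10 over follow-up days; ~200 plasma
proteins with log2 baselines N(26, 2²); participant random intercepts
(SD 0.5 log2) and residual noise (SD 0.3 log2); trajectory classes flat /
increasing / decreasing / acute-DOL1 (55/20/15/10%) with effect magnitudes
drawn from 0.2–1.5 log2 units (the class shapes: log-like saturating rise
or fall, and a DOL1-only spike that returns to baseline); two batches with
a +0.5 log2 location shift and ×1.2 residual scale on the second (batch
assigned per participant); logistic left-censoring with threshold at the
15th intensity percentile and steepness 2 per log2 unit, giving ~15–17%
missingness as in typical plasma LFQ; an immunoglobulin panel with
newborn-like baselines (IgG1:IgG2:IgG3:IgG4 ≈ 4:1:0.3:0.15), first-order
decay at t½ = 21.1/21/7/21 days, and IgM/J-chain growth (doubling ≈ 5.5 d)
coupled through a shared participant-level growth latent (75% shared);
RNA counts negative-binomial (dispersion 0.05) around means engineered so
the paired log2 change correlates with the matched protein's change at a
target R (7 of 30 genes at R = 0.85, the rest at 0.10). Effect-size and
missingness defaults are calibration choices where the emulated study is
silent, chosen once to be realistic for newborn plasma LFQ.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide ambiguity, retention-time drift, correlated protein modules
beyond the configured classes, longitudinal RNA library composition
effects, and real iBAQ-to-concentration calibration. Passing
parameter-recovery tests therefore demonstrates correctness of the
statistical machinery under the assumed model, not performance on any
particular real cohort.

All randomness flows from a single seed; identical configs produce
byte-identical cohorts. The pipeline derives per-stage substreams from one
root seed via a hash of the stage name.

## Problem sizes used in the automated checks

Calibration checks run at the scale that makes their Monte-Carlo error
small relative to the tested band: 200 replicate cohorts for half-life
recovery; 100 replicates × 2000 proteins for the global-null FDR and LRT
uniformity (the uniformity check uses a 30-pair arm, where the χ²
asymptotics are the intended reference); 500 replicates × 200 permutations
for the permutation-test type-I error; 5 replicates × 200 proteins for
batch recovery; 40 replicate cohorts for concordance classification.

## Known limitations

* No moderated (limma-style) variance shrinkage; each protein is fit
  independently.
* The half-life estimator assumes a common decay rate across participants
  and days; synthesis is not separated from decay (the estimate is the
  *apparent* half-life).
* The quantro-style statistic tests location/shape differences of whole
  sample distributions; it does not localise which quantiles differ.
* DOL-average concordance rests on 3 points by design; treat
  classifications as screening, not inference.
* Absolute concentration calibration from iBAQ is out of scope; the
  concentration projection requires an external baseline.
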