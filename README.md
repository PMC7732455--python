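# neoplasma

Longitudinal analysis of the newborn plasma proteome over the first week of
life, built for paired label-free quantification (LFQ) cohorts: every
participant is sampled at birth (day of life, DOL 0) and once more at DOL 1,
3 or 7. The package takes MaxQuant-style `proteinGroups.txt` tables and
sample metadata through filtering, empirical-Bayes batch correction,
left-censored imputation (for ordination only), paired mixed-model
differential abundance, trajectory correlation, immunoglobulin subclass
kinetics, and protein–mRNA concordance — together with a synthetic-cohort
generator that reproduces the statistical structure of such a study with
known ground truth, so every stage is testable without any external data.

## Who it is for

Proteomics analysts working with short longitudinal plasma panels
(neonatal or otherwise) who need a paired-design differential pipeline that
treats missing LFQ values as left-censored (missing-not-at-random) rather
than imputing them into the statistics, and who want parameter-recovery
evidence for every stage.

## The model

Per protein, log2 LFQ intensity in a two-timepoint arm is modelled as a
random-intercept linear mixed model

    y_ij = β0 + β_DOL·1[day_ij = d] + β_sex·sex_i + β_batch·batch_i + u_i + ε_ij,
    u_i ~ N(0, σ²_u),  ε_ij ~ N(0, σ²_e)

with participant `i` as the random intercept. The day effect β_DOL is the
log2 fold change; its p-value comes from a 1-df likelihood-ratio test
against the same model without the day term (both refit by maximum
likelihood), Benjamini–Hochberg corrected within each follow-up day, and a
protein is called significant at q < 0.05 **and** |log2FC| > 0.2. Proteins
detected on one day only are handled by a complementary Fisher's-exact
missingness analysis on the pre-filter detection table.

Maternally transferred antibodies decay by first order,
C(t) = C(0)·2^(−t/t½). On the paired change scale Δ(t) = −t/t½, so the
apparent half-life is estimated by zero-intercept least squares of
participant-level Δ on elapsed days, with a bootstrap CI over participants.
IgG subclass abundances are compared through per-sample iBAQ ratios
normalised to IgG2.

## Worked example

```python
import neoplasma as npl
from neoplasma.simulate import SimConfig

matrix, rna, meta, truth = npl.generate_cohort(SimConfig(seed=11))

flagged, report = npl.filter_flags(matrix)              # decoys/contaminants
arm, _ = npl.filter_valid_values(flagged, meta, 7)      # >=50% detected rule
corrected, _ = npl.correct_batch(arm, meta)             # EB location/scale
res = npl.fit_paired_lmm(corrected, meta, 7)            # paired mixed model
print(res.summary())

traj = npl.compute_changes(corrected, meta)
hl = npl.estimate_half_life(traj, "IG_IGHG1", bootstrap_n=2000, seed=0)
print(hl.summary())
```

prints

```
Paired differential abundance, DOL7 vs DOL0
design: intercept + dol7 + sex_M + batch_plateB + (1|participant)
proteins tested: 175 of 175
significant (q<0.05, |log2FC|>0.2): 54  (up 30, down 24)

Apparent half-life of IG_IGHG1
slope: -0.05545 log2/day   t_half: 18.0 d [10.2, 50.0] d
paired changes used: 30 over 3 follow-up day(s)
```

The 54 significant proteins at DOL7 are dominated by the cohort's built-in
increasing/decreasing trajectory classes; the IgG1 half-life estimate of
18.0 days (bootstrap 95% CI 10.2–50.0) reflects one noisy 30-participant
cohort around the configured 21.1-day decay — the estimator's median over
200 replicate cohorts recovers 21.1 days to within 1%.

A CLI mirrors the stages (`neoplasma simulate | preprocess | pca |
diffabund | missingness | trajectories | ig | integrate | run-all`).

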