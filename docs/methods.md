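# Methods

This package re-implements, as a tested pipeline, a serum-protein prognostic
analysis for resected gastric cancer: from batch-structured targeted-MRM
peak areas and disease-free-survival (DFS) records to two deployable Cox
modules — a prognosis module (PM) that refines TNM staging, and an
adjuvant-therapy (AT) selection module that stratifies expected benefit from
chemotherapy (CTX) versus chemoradiation (CCRT).  The real cohort sera are
not available, so a synthetic-cohort generator with recorded ground truth
stands in for the study data; everything below describes both the analysis
and what the generator does and does not emulate.

## Quantification model and normalization

Raw MRM peak areas are modelled as

    PA_{j,s} = A_{p(j),s} · NSF_s^{β_j} · ε_{j,s}

where `A` is the biological abundance of the protein behind peptide `j` in
run `s`, `NSF_s` is a run-level multiplicative instrument drift, `β_j` a
peptide-specific ionization response exponent, and `ε` lognormal technical
noise.  The normalization scaling factor of run `s` is estimated from five
endogenous normalizing peptides (NPs):

    NSF_s = median_i ( N_{i,s} / N̂_i ),   N̂_i = median over runs of N_{i,s}

so the median over runs of each NP ratio is exactly 1 by construction.
`β_j` is the OLS slope of log2(PA_{j,s}) on log2(NSF_s) over the pooled QC
runs (one per batch; identical material, so any systematic change is
drift).  The corrected abundance is `PA / NSF^β`, the unique form that (a)
reduces to plain NSF division at β = 1 and (b) inverts the log-log slope
definition; in the noise-free limit it recovers `A` exactly, which the
tests use as a round-trip identity against the generator.  β is estimated
on 10 points, so slopes are clamped to [0.5, 2] with a warning; identical
QC NSFs make the slope undefined and β falls back to 1.

NP candidates are screened before selection: detected in every clinical
sample; one-way ANOVA p ≥ 0.05 across the three outcome groups (recurred
within 72 months / censored earlier / event-free at 72 months), computed on
raw areas since normalization is not yet defined at that stage; Pearson
r > 0.5 with the spiked exogenous control (both respond to the same
drift).  Survivors are ranked by a stability score in the NormFinder
spirit — the square root of weighted intra-group variance plus squared
inter-group mean deviation on the log2 scale — and the five most stable are
selected.  The exact NormFinder model-based estimate is not reproduced; the
ranking contract (group-shifted or noisy candidates rank worse) is what the
pipeline relies on and what the tests check.

## QC filtering

Two samples per batch are injected in triplicate.  The CV (sample sd / mean,
n−1 denominator) of raw areas over the triplicates is computed per peptide
and sample; a peptide with CV > 25% in strictly more than five samples is
excluded.  Peptides with no triplicated sample are flagged "not assessable"
but never excluded.  When a protein has several surviving peptides, one
representative is chosen lexicographically by (interference score if
provided, median replicate CV, −median peak area), with the peptide id as a
deterministic tie-break.  Interference is not computable from synthetic
chromatogram-free data, so it is an optional input defaulting to a
constant.

## Survival machinery

Cox models maximise the Efron-tie-corrected partial likelihood by damped
Newton–Raphson, vectorised with reverse cumulative sums (and per-event
segment matmuls at larger covariate counts).  This in-package fitter exists
because stability selection refits Cox models tens of thousands of times;
it is validated against lifelines' `CoxPHFitter` to ~1e-6 on tied and
untied data in the test suite.  Separation / monotone likelihood is flagged
as non-convergence when a coefficient exceeds 20 per covariate sd.
Backward elimination repeatedly drops the non-forced covariate with the
largest Wald p above 0.05 (warm-starting each refit); forced covariates are
never dropped.

Time-dependent ROC curves use the cumulative-case/dynamic-control
Kaplan–Meier estimator (Heagerty–Lumley–Pepe "KM" variant, chosen over the
nearest-neighbour variant for determinism):

    sens(c) = [1 − S(t | X > c)] P(X > c) / [1 − S(t)]
    spec(c) = 1 − S(t | X > c) P(X > c) / S(t)

with the curve traversed by decreasing cutoff and the AUC taken by
trapezoid.  With no censoring before the horizon this equals pairwise
case/control concordance exactly (a test asserts bit-level agreement on 50
random datasets).  Univariate cutoffs maximise the Youden index, ties
toward the smaller cutoff.  AUC confidence intervals are BCa bootstrap over
subject resampling (scipy's implementation, with the package's AUC as the
statistic).  Six years is mapped to 72 months throughout.

## Endpoints

PM endpoint: 2 = recurred within 72 months (event at the recurrence time),
1 = censored earlier (censored at that time), 0 = event-free at the horizon
(censored at 72).  A recurrence recorded after 72 months counts as class 0.
AT endpoint: identical to PM for CCRT patients; reversed (2 − PM) for CTX
patients, encoding the hypothesis that CTX patients who did poorly might
have benefited from CCRT and vice versa.  The reversal's (time, event)
conversion is not uniquely determined by a three-level code; this package
assigns the reversed class 2 (originally event-free) an event at the
72-month horizon and censors the reversed class 0 (originally recurred) at
the observed recurrence time, preserving each subject's information span.
Applying the reversal twice restores the PM coding exactly (tested over all
3^k toy cohorts).

## Feature selection

For each panel and purpose, 8-fold cross-validation (random partition
stratified by the derived event indicator, reseeded per iteration from a
root seed) is repeated `n_iterations` times (500 by default).  On each 7/8
training split, backward elimination reduces the model (stage is forced for
prognosis modules and excluded from the protein ranking); a protein scores
an observation N.O. in an iteration when it is retained in at least 4 of
the 8 folds.  A non-convergent fold counts as non-selection for every
protein.  Proteins are ranked by descending N.O. (peptide id as tie-break)
and the panel is the longest prefix in which every rank s satisfies

    Z = (N.O.(s) − I·p_s) / sqrt(I·p_s·(1 − p_s)) ≥ 1.96,
    p_s = Σ_{i=4..8} C(8,i) (s/n)^i ((n−s)/n)^{8−i}

with I the iteration count and n the panel size — i.e. each rank must be
observed significantly more often than a feature drawn at random s-of-n per
fold would be.

A calibration caveat, measured and documented deliberately: this rule
controls enrichment over *random fold draws*, not dataset-level false
positives.  On an all-null panel of 20 proteins, roughly one protein is
expected to show a spurious marginal association at α = 0.05; such a
protein is retained under almost every fold re-partition, so its N.O.
saturates and it is selected with a huge Z.  In simulation, a majority of
all-null datasets select at least one protein.  The corresponding
acceptance test asserts the stricter "no selections under the null"
property and therefore fails by design of the published rule, not by
implementation error; the power property (a planted |coef| = 0.8 protein is
selected in ≥90% of datasets) holds.

## Modules and stratification

The final module is a single full-data Cox fit on the selected proteins
(plus forced ordinal stage 1b→1 … 4→4 for prognosis; a single stage
coefficient implies the ordinal coding).  A subject's score is the linear
predictor Σ coef·covariate with no baseline term; the training-cohort
median score is the classification cutoff.  Prognosis: score ≤ median is
low-risk; evaluation reports per-stage and overall KM groups, log-rank p,
low-vs-high hazard ratio, and the 6-year AUC with sensitivity/specificity
at the cutoff.  AT selection: CCRT patients below the cutoff are tCCRT
(well-treated), other CCRT are fCCRT; CTX below the cutoff are fCTX, above
are tCTX; the four groups partition the cohort and are evaluated on
observed DFS with fCTX as the poor-prognosis reference.

## Synthetic cohort generator

Defaults emulate the study design: 227 patients in 10 batches of 21–24
clinical runs plus one pooled QC run each, two samples per batch in
triplicate; stage mix 1b/2/3/4 ≈ 58/88/61/20; arms CTX/CCRT ≈ 107/120
assigned independently of covariates (randomized-trial emulation); 73 MD
and 20 ND representative proteins (one peptide, one transition each), 15 NP
candidates, one constant spiked control.  DFS is exponential with hazard
h₀·exp(stage_coef·stage + Σ effect_k·z_k), the simplest
proportional-hazards-consistent choice, with z_k the standardized log2
abundance of the k-th planted protein; uniform censoring on (0, 72] hits a
45% subset and everyone is administratively censored at 72 months.  With
the default h₀ = 0.0009/month, stage_coef = 0.5 and effects (0.7, 0.6,
−0.6), the outcome mix is ≈47 recurred / 84 censored / 96 event-free —
close to the emulated cohort's 44/80/103.  Abundances are lognormal
(log2-means uniform on [14, 22]); the true distribution of serum protein
abundances is unknown, so lognormality is an assumption, documented as
such.  Drift is a batch-level log2 shift (sd 0.25) plus run-level jitter
(half that sd), so NSF varies within batch; β is uniform on [0.8, 1.2];
technical noise is lognormal with CV 7% (between the two panels' reported
replicate medians, which a single knob cannot hit simultaneously).  Two NP
candidates are tilted along the true disease severity so the ANOVA screen
has something to reject.

What the generator does *not* emulate: retention-time scheduling,
transition interference, depletion chemistry, missing values, non-random
batch assignment, or non-proportional hazards.  Passing recovery tests
therefore show the pipeline inverts its own generative assumptions — not
that those assumptions hold for real sera.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced presets chosen as the
package's own defaults for desk-scale verification: cohorts of 60–350
patients, panels of 6–24 proteins, 4–150 selection iterations (the
published 500×8-fold preset remains the library default).  Newton
convergence is |Δ loglik| < 1e-9 with step-halving; fold partitions are
seeded as `default_rng([seed, 7919, iteration])`; all randomness descends
from explicit integer seeds and reruns are bit-identical.  Degenerate
cases are first-class: empty strata report NA statistics, identical module
scores make the median split an error, a log-rank test with no events
returns (0, 1), and an ROC horizon with no cases raises rather than
returning a silent 0.5.
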