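# seprogadic

Serum-protein prognosis and adjuvant-therapy-selection modules for resected
gastric cancer, built from targeted-MRM (multiple reaction monitoring)
serum proteomics and disease-free-survival (DFS) records.

TNM stage alone sorts post-gastrectomy patients into four coarse risk
groups.  This package implements a pipeline that refines that grouping with
quantified serum proteins: replicate-based QC of transition-level peak
areas, normalization against endogenous reference proteins with a
per-peptide ionization correction, and cross-validated Cox
proportional-hazards feature selection that assembles two deployable
classifiers — a **prognosis module** (PM; protein panel + forced stage) and
an **adjuvant-therapy selection module** (AT; who benefits from
chemoradiation vs chemotherapy alone).  Because the original cohort sera
are not publicly available at desk scale, a synthetic-cohort generator with
recorded ground truth (planted prognostic proteins, per-run drift,
per-peptide ionization exponents) stands in for the study data and makes
every stage testable by recovery.

## The model in brief

Raw peak areas follow `PA_{j,s} = A_{p(j),s} · NSF_s^{β_j} · ε`, where the
normalization scaling factor of run *s* is the median of five normalizing
peptide ratios, `NSF_s = median_i(N_{i,s}/N̂_i)` with `N̂_i` the cohort
median, and `β_j` is the slope of log₂PA on log₂NSF over the pooled QC
runs.  Corrected abundances `PA/NSF^β` enter Cox models of 6-year DFS.
Feature selection repeats 8-fold cross-validated backward elimination
(Wald p > 0.05) for many random partitions; a protein scores an observation
N.O. when retained in ≥4 of 8 folds, and the panel is the longest
N.O.-ranked prefix whose every rank *s* beats random s-of-n fold draws:

    p_s = Σ_{i=4..8} C(8,i)(s/n)^i((n−s)/n)^{8−i}
    Z   = (N.O.(s) − I·p_s) / √(I·p_s(1−p_s)) ≥ 1.96

A patient's module score is the Cox linear predictor; the cohort median
splits low/high risk (PM) or crosses with the treatment arm into
tCCRT/fCCRT/tCTX/fCTX benefit groups (AT).  Details, design decisions and
caveats are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from seprogadic import (SimulationConfig, simulate_cohort,
                        PipelineConfig, run_pipeline)

cohort = simulate_cohort(SimulationConfig(n_md_proteins=16, n_nd_proteins=8, seed=7))
result = run_pipeline(
    PipelineConfig(n_iterations=50, seed=0, purposes=("prognosis",), panels=("MD",)),
    quant=cohort.quant, clinical=cohort.clinical,
)
sel = result.selections[("MD", "prognosis")]
print(sel.table.head(5).to_string(index=False))
print(result.modules[("MD", "prognosis")].summary().round(3))
```

prints the selection ranking and the fitted module:

```
feature  n_obs  rank      p_s          z
  MD001     50     1 0.000871 239.545568
  MD002     50     2 0.011248  66.297122
  MD003     50     3 0.045523  32.378041
  MD005     43     4 0.113815  16.613796
  MD011      2     5 0.217387  -3.041006

        Coef     SE      P     HR
ID
Stage  0.541  0.184  0.003  1.718
MD001  0.779  0.158  0.000  2.178
MD002  0.475  0.158  0.003  1.608
MD003 -0.420  0.156  0.007  0.657
MD005  0.368  0.178  0.039  1.445
```

The cohort was simulated with three truly prognostic proteins
(MD001 +0.7, MD002 +0.6, MD003 −0.6 log-hazard per sd of log₂ abundance);
all three are recovered at the top of the ranking with coefficients of the
right sign and size, stage keeps its forced positive effect, and one
spurious protein (MD005) rides along — the selection rule guards against
random fold draws, not against dataset-level flukes (see the methods
note).  The N.O. column counts iterations (of 50) in which a protein
survived backward elimination in ≥4 of 8 folds; HR is exp(Coef).  The
median-score split of this cohort gives low-vs-high HR 0.17, log-rank
p < 1e-7 and a 6-year time-dependent AUC of 0.83 versus 0.61 for the
stage-only model.

The same objects are scriptable from the shell:

```sh
seprogadic simulate --out sim/ --seed 7
seprogadic run --quant sim/quant.csv --clinical sim/clinical.tsv \
    --out results/ --iterations 50 --seed 0
```

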