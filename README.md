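# somaticsurv

Cross-validated survival risk models from binary somatic-mutation
profiles.

## The problem

Whole-exome sequencing of a tumor cohort yields, per patient, the set of
somatically mutated genes — a sparse binary patients × genes matrix —
together with censored clinical follow-up (overall survival, OS, and
progression-free survival, PFS). Can the mutation profile alone predict
who is at high risk? Naively fitting a Cox model to hundreds of genes and
evaluating it on the same patients gives meaninglessly optimistic
answers. `somaticsurv` implements the honest version of this analysis
for biostatisticians and computational oncologists:

* build the binary incidence matrix from a MAF-dialect mutation file,
  drop genes mutated in fewer than 5 patients, align with the clinical
  table per endpoint;
* **complete leave-one-out cross-validation**: inside every fold, re-run
  per-gene log-rank screening (keep p < 0.01), re-standardize with the
  training mean/sd, re-fit the multivariate Cox model
  η = Σ_g β_g (x_g − m_g)/s_g, and score the held-out patient with a
  model that never saw them;
* split the n out-of-fold scores at their median into low-/high-risk
  groups, compare them with Kaplan–Meier curves and the log-rank test;
* a **permutation null** for that cross-validated log-rank statistic —
  the (time, event) pairs are shuffled and the entire cross-validation
  is rerun B times — because the naive p-value is biased by the reuse of
  the survival data;
* **time-dependent ROC/AUC** at a landmark time (default 36 months) with
  the nearest-neighbor bivariate survival estimator to handle censoring;
* a combined genes + clinical model (age, grade, stage, surgical
  residual) for comparison, and risk-group × clinical-factor association
  tables (Pearson chi-square).

The survival primitives — Kaplan–Meier with Greenwood variance and
median CI, two-group log-rank, Newton–Raphson Cox with Efron/Breslow
ties, Pearson chi-square — are implemented in the package and
cross-checked against independent libraries in the test suite. A
synthetic-cohort generator with a planted proportional-hazards signal
makes every stage testable without any data download.

## Worked example

```python
import numpy as np
import somaticsurv as ss

cohort = ss.generate_cohort(ss.SimConfig(n_patients=300, n_genes=200, seed=8))
matrix = ss.filter_rare_genes(cohort.mutation_matrix, 5)
outcome = cohort.os_outcome

cv = ss.loocv_risk_scores(matrix, outcome, ss.SelectionConfig(alpha=0.01))
perm = ss.permutation_pvalue(matrix, outcome,
                             ss.SelectionConfig(alpha=0.01),
                             ss.PermutationConfig(n_permutations=49, seed=1))
low = np.flatnonzero(~cv.high_risk); high = np.flatnonzero(cv.high_risk)
print(f"median OS low-risk:  {ss.km_estimate(outcome.subset(low)).median:.1f} months")
print(f"median OS high-risk: {ss.km_estimate(outcome.subset(high)).median:.1f} months")
print(f"permutation p: {perm.p_value:.3f}")
print(f"AUC at t=36: {ss.roc_at_time(cv.scores, outcome, ss.ROCConfig(36.0)).auc:.3f}")
```

prints

```
median OS low-risk:  53.1 months
median OS high-risk: 17.0 months
permutation p: 0.020
AUC at t=36: 0.742
```

The low-risk half of the cohort lives ~3× longer at the median than the
high-risk half; the permutation p-value says a separation this strong
arose in none of the 49 outcome-shuffled reruns of the full
cross-validation (p = (1+0)/50); and at three years the cross-validated
score ranks a patient who will have died ahead of one who will not about
74% of the time. The `examples/` directory has one short script per
capability (simulation, cross-validated fitting, permutation inference,
time-dependent ROC, clinical association tables), and the `somaticsurv`
CLI (`simulate`, `fit`, `permute`, `roc`, `report`) wraps the same
functions for shell use.

## Layout

```
src/somaticsurv/
  io.py          MAF/clinical readers, rare-gene filter, cohort alignment
  survival.py    KM, log-rank (+ vectorized screen), Cox, chi-square
  pipeline.py    LOOCV risk scores, median split, final/combined models
  permutation.py permutation null for the cross-validated log-rank
  tdroc.py       time-dependent ROC/AUC (NNE and KM estimators)
  simulate.py    synthetic cohorts with planted prognostic signal
  report.py      end-to-end run -> report bundle with manifest
  cli.py         thin click CLI over the above
```

See `docs/methods.md` for the statistical details, the numerical
choices, and what the simulations do and do not establish.
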