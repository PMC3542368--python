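"""Predictive accuracy of the cross-validated risk score at a landmark time.

Cases are patients with an event by t = 36 months, controls those
event-free past t; censoring is handled by the nearest-neighbor
bivariate survival estimator.  AUC(t) curves compare the genes-only
model with the combined genes+clinical model.
"""

import numpy as np

import somaticsurv as ss

cohort = ss.generate_cohort(ss.SimConfig(n_patients=300, n_genes=200, seed=8))
matrix = ss.filter_rare_genes(cohort.mutation_matrix, 5)
outcome = cohort.os_outcome

cv = ss.loocv_risk_scores(matrix, outcome)

roc = ss.roc_at_time(cv.scores, outcome, ss.ROCConfig(landmark_t=36.0))
print(f"AUC at t=36 months (NNE, span={roc.span_used:.3f}): {roc.auc:.3f}")

curve = ss.auc_over_time(cv.scores, outcome, [12, 24, 36, 48, 60])
print("AUC over time (genes-only model):")
for t, auc in curve:
    print(f"  t={t:5.0f} months  AUC={auc:.3f}")

# combined model on complete-case patients
ind = ss.clinical_indicators(cohort.clinical)
idx = np.flatnonzero(ind.notna().all(axis=1).to_numpy())
cv_comb = ss.loocv_risk_scores(
    matrix.subset_patients(idx), outcome.subset(idx),
    ss.SelectionConfig(), cohort.clinical.iloc[idx],
)
curve_comb = ss.auc_over_time(cv_comb.scores, outcome.subset(idx), [12, 24, 36, 48, 60])
print("AUC over time (genes + clinical):")
for t, auc in curve_comb:
    print(f"  t={t:5.0f} months  AUC={auc:.3f}")
# An AUC of 0.5 is a coin flip; values around 0.7-0.8 match what a strong
# mutation signature achieves at this cohort size.
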