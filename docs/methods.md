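# Methods

`somaticsurv` builds prognostic survival risk models from binary somatic
mutation profiles and — the part that needs the most care — evaluates
them honestly. This note records the statistical model, the numerical
choices, what the synthetic cohorts do and do not emulate, and the
design decisions that were genuinely open.

## The modeling problem

Input is a patients × genes incidence matrix X ∈ {0,1}^(n×G) (1 = the
patient carries at least one somatic mutation in the gene) and a
right-censored endpoint (T_i, δ_i) in months — overall survival (OS) or
progression-free survival (PFS). Genes mutated in fewer than 5 patients
are removed before modeling ("rare-gene filter"); patients missing the
endpoint are dropped. The fitted object is a gene signature: a selected
gene set S, per-gene training means m_g and standard deviations s_g, and
Cox log-hazard-ratio coefficients β_g, giving the risk score

    η_i = Σ_{g∈S} β_g (x_ig − m_g)/s_g .

## Complete leave-one-out cross-validation

Because G ≫ the number of events, the apparent performance of a
signature fitted and evaluated on the same cohort is worthless. Every
model-building step is therefore repeated inside each fold of a
leave-one-out loop: for each patient i, on the other n−1 patients the
per-gene two-group log-rank screen keeps genes with p < α (default
0.01), the kept columns are standardized with the training mean and
sample sd (n−1 denominator), a multivariate Cox model is fitted, and
patient i receives the resulting linear predictor computed with the
*training* standardization. Folds that select no gene contribute the
empty predictor (score 0) so the later median split always sees n
scores. The n out-of-fold scores are split at their median (ties fall to
low risk); the two groups' Kaplan–Meier curves and log-rank statistic
are the "cross-validated" results.

### Fold-median centering of the scores

The Cox linear predictor has no intercept, and its *level* depends on
which genes the fold selected: a fold whose model contains gene set S
scores every wild-type patient at −Σ_{S} β_g m_g/s_g. Leave-one-out
selection is unstable exactly for the held-out patient — removing
patient i removes the evidence their own outcome contributed to every
gene's screening p — so the fold-to-fold level jitter is systematically
*anti-correlated* with the held-out outcome. Pooling raw predictors
across folds therefore produces grossly anti-predictive rankings on null
data (in our simulations: cross-validated AUC ≈ 0.29 where 0.5 is
correct, and cross-validated log-rank p-values down to 10⁻⁶⁰ on
*permuted* outcomes), and on signal data the artifact cancels the true
effect.

Each held-out score is therefore centered at the median of the fold
model's linear predictors over its own training patients — the cutoff
convention of survival risk-group prediction as implemented in the
standard microarray-era tools. Centering cancels the fold-level shift
(both the patient's score and the reference move together when the
selected set changes) and makes scores comparable across folds; the
median split is then applied to the centered scores. This was the one
place the package deviates from a literal "pool the raw predictors"
reading of the recipe, and simulations show it is not optional for
sparse binary predictors.

## Permutation inference

The cross-validated log-rank statistic still has no usable chi-square
reference: the n scores are built from overlapping training sets, and
the resulting dependence inflates the statistic under the null. The
honest p-value permutes the (time, event) *pairs* across patients —
preserving the censoring pattern and the mutation matrix — and reruns
the entire cross-validation, gene re-selection included, B times:

    p = (1 + #{b : p_b ≤ p_obs}) / (B + 1).

The add-one estimator counts the observed data as one draw from its own
null and never returns 0; a flag switches to the plain count/B
estimator. Permuted p-values tying the observed one count toward the
numerator (conservative). B = 1000 is the production default; the test
suite and the acceptance script use B in the tens (p-value granularity
1/(B+1)), chosen to keep full-pipeline reruns affordable.

## Time-dependent ROC and AUC

At landmark t (default 36 months) a case is a patient with an event by
t, a control one event-free past t. With censoring the operating
characteristics come from an estimate of S(c, t) = P(M > c, T > t):

* **NNE** (default): S(c,t) averages, over patients with marker above c,
  a weighted Kaplan–Meier of survival conditional on the marker, using a
  symmetric 0/1 nearest-neighbor kernel containing the 2λn marker-rank
  neighbors; span λ = 0.25·n^(−0.20) unless set. This is the smoothed
  estimator recommended for valid, monotone ROC curves under censoring.
* **KM**: subset Kaplan–Meier, S(c,t) = Ŝ_{M>c}(t)·P(M>c). With no
  censoring before t this reduces *exactly* to the empirical binary ROC
  of 1[T ≤ t] — the property the test suite exploits as an oracle.

TPR(c) = [P(M>c) − S(c,t)]/[1 − S(t)], FPR(c) = S(c,t)/S(t); thresholds
sweep the unique scores; the curve is anchored at (0,0) and (1,1),
clipped to the unit square, forced monotone (kernel-edge violations are
tiny), and integrated by the trapezoid rule. AUC is invariant to
strictly increasing transformations of the marker. ROC is computed on
the *continuous* centered cross-validated scores, not the dichotomized
groups.

## Survival primitives

All four primitives are implemented in the package and cross-checked
against independent references in the tests:

* **Kaplan–Meier** with Greenwood variance; median = smallest time with
  Ŝ ≤ 0.5; the median's 95% CI inverts the pointwise log(−log Ŝ)
  confidence band (the Brookmeyer–Crowley-style interval that Stata and
  lifelines report). Censored observations tied with events are treated
  as censored after the events.
* **Log-rank**: (ΣO−E)²/ΣV with hypergeometric expectation and variance
  at each distinct event time, p from chi-square with 1 df (two-sided in
  the statistic). A vectorized screen computes all G per-gene statistics
  with two segment-sum passes, which is what keeps full-pipeline
  permutation runs tractable.
* **Cox**: Newton–Raphson from β = 0 on the partial likelihood, Efron
  tie handling by default (Breslow available), step-halving on
  likelihood decrease, convergence at max|score| ≤ 1e−9 or relative
  log-likelihood change ≤ 1e−12, at most 50 iterations; monotone
  likelihood is reported as non-convergence, never an exception, so a
  pathological fold cannot abort a cross-validation run.
* **Pearson chi-square** for contingency tables, *without* continuity
  correction — the convention confirmed by the association tables this
  package is designed to reproduce.

## The synthetic cohort generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline's statistical claims are verified.

| parameter | default | rationale |
|---|---|---|
| n_patients | 311 | OS cohort size of the motivating study |
| n_genes | 509 | gene count after the rare-gene filter there |
| causal_genes | 5 | small prognostic set, matching signature sizes of 8–10 with overlap |
| causal_log_hr | 1.0 | per-mutation hazard ratio e ≈ 2.7; consistent with reported standardized coefficients ≈ 0.2 once divided by the sd (≈ 0.2) of a rare binary gene |
| mutation_freq_range | (0.016, 0.15) | per-gene frequencies from the filter floor (5/311) to a moderately common gene |
| baseline_hazard | 0.015 /month | exponential OS baseline, median ≈ 46 months |
| pfs_hazard_multiplier | 3.0 | progression runs on a ∼3× faster clock than death |
| censor_rate | 0.010 /month | with the 120-month administrative cap gives ≈ 50–60% observed events; the study does not report its censoring fraction, so this is an assumption |
| clinical_missing_rate | 0.05 | MCAR gaps mimicking the varying denominators of real clinical tables |

Gene columns are independent Bernoulli draws; survival is exponential
with hazard h₀·exp(Σ β_g x_ig); censoring is exponential truncated at
the follow-up cap; OS and PFS are independent draws given the matrix;
clinical covariates are drawn from marginals matching an advanced-stage
serous ovarian carcinoma cohort and are independent of the genes (no
confounding by default, since no joint distribution is reported).

What the generator does **not** emulate: gene–gene correlation,
mutational signatures or hypermutators, a near-ubiquitous driver (a
TP53-like column), informative censoring, or clinical–genomic
confounding. Passing tests therefore demonstrate the pipeline's
statistical correctness under clean proportional-hazards sparse-binary
conditions, not robustness to those real-data features.

## Verification scales

Full-pipeline Monte-Carlo checks rerun the complete cross-validation
hundreds to thousands of times, so the verification suites run at
reduced scale: null calibration uses n = 150, G = 200, B = 33, 50
replicate seeds; signal recovery uses full study scale (n = 311,
G = 509) with 5 causal genes at |β| = 1 and B = 19 (permutation
granularity 1/20, sufficient to call p ≤ 0.05). The acceptance script
runs one full-size cohort end to end. Signal recovery needs the full
n ≈ 300:
at n = 150 a five-gene signature carried by ∼10 patients per gene does
not reliably dominate the selection noise; a cohort in the hundreds is
a precondition for this class of model to work at all.

## Power of the planted-signal conditions

The signal-recovery suite plants 5 causal genes with per-mutation log
hazard ratio 1 at realistic frequencies (uniform on 0.016–0.15). Those
conditions imply a true linear-predictor standard deviation of about
√(Σ f_g(1−f_g)) ≈ 0.6 and hence a true concordance near 0.65 — the
ceiling any estimator can reach there, which is why the cross-validated
landmark AUC averages ≈ 0.66 rather than the ≈ 0.8 a stronger clinical
signature can show. Against the heavy-tailed permutation null of the
cross-validated log-rank statistic, roughly three quarters of signal
draws are detected at the 5% level; the remainder are genuinely
indistinguishable from the null's tail at this effect size, and no
amount of permutation resolution recovers them. Detecting weaker or
rarer signatures needs larger cohorts: with sparse binary predictors,
sample size — not permutation resolution — is the binding resource for
mutation-profile risk models.

## Known limitations

* The rare-gene filter is applied to the full matrix before patients
  with missing outcomes are dropped (the alternative ordering is a
  one-line change but alters the gene count).
* The combined genes+clinical model is complete-case: patients missing
  any of the four indicators (age > 60, grade 3, stage IV, macroscopic
  residual) are excluded from it.
* No v-fold CV, no penalized Cox, no stratified log-rank, no
  incident/dynamic ROC, no AUC confidence bands.
* The permutation test is exact under exchangeability of (time, event)
  pairs but inherits the granularity 1/(B+1).
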