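"""Leave-one-out cross-validated risk modeling with per-fold gene re-selection.

The modeling recipe, applied independently inside every fold so the
held-out patient never touches their own score:

1. hold out patient i; the remaining n−1 patients form the training set;
2. on the training set, screen every gene with the two-group log-rank
   test (mutated vs wild-type) and keep genes with p below the screening
   threshold (default 0.01);
3. standardize the selected gene columns with the training mean and
   standard deviation (n−1 denominator) and fit a multivariate Cox model;
4. score patient i with the fitted linear predictor, standardizing their
   gene values with the *training* mean and sd, and center the score at
   the median of the fold model's own training predictors — without this
   centering the fold-to-fold level of the predictor is not comparable
   (each fold selects its own gene set) and the level jitter is
   systematically anti-correlated with the held-out outcome;
5. after all n folds, dichotomize the n cross-validated scores at their
   median into low-/high-risk groups and compare the groups with the
   log-rank test ("cross-validated log-rank").

The naive p-value of that final log-rank test is optimistically biased
because the groups were built from the same survival data; it is
reported, but honest inference uses the permutation null in
:mod:`somaticsurv.permutation`.

A combined genes + clinical model forces four binary clinical indicators
(age > 60, grade 3, stage IV, macroscopic residual) unstandardized into
every fold's Cox fit alongside that fold's selected genes.  Platinum
status is never a model covariate — it is unknown at initial surgery —
and only appears in association tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MutationMatrix
from .survival import (
    CoxFit,
    LogrankResult,
    LoocvLogrankScreen,
    SurvivalOutcome,
    cox_fit,
    logrank_screen,
    logrank_test,
)

__all__ = [
    "SelectionConfig",
    "RiskModel",
    "CVResult",
    "CLINICAL_MODEL_TERMS",
    "clinical_indicators",
    "select_genes",
    "standardize",
    "loocv_risk_scores",
    "fit_final_model",
    "selection_frequency_report",
]

logger = logging.getLogger(__name__)

# model-eligible clinical contrasts (reference level listed second)
CLINICAL_MODEL_TERMS = ("age_gt60", "grade3", "stage4", "macroscopic")


@dataclass(frozen=True)
class SelectionConfig:
    """Per-gene screening settings: log-rank alpha and the endpoint label."""

    alpha: float = 0.01
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.endpoint.upper() not in ("OS", "PFS"):
            raise ValueError("endpoint must be 'OS' or 'PFS'")


@dataclass(frozen=True)
class RiskModel:
    """A fitted signature: genes, training standardization, Cox coefficients."""

    genes: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    coefficients: np.ndarray
    clinical_terms: dict[str, float] | None = None
    logrank_p: np.ndarray | None = None
    center: float = 0.0
    fit: CoxFit | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        k = len(self.genes)
        if not (len(self.means) == len(self.sds) == len(self.coefficients) == k):
            raise ValueError("genes/means/sds/coefficients must align")
        if k and np.any(np.asarray(self.sds) <= 0):
            raise ValueError("training standard deviations must be positive")

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0 and not self.clinical_terms

    def score(self, gene_values: np.ndarray, clinical_values: np.ndarray | None = None):
        """Centered linear predictor for rows of per-gene values.

        The raw Cox linear predictor is shifted by ``center`` — the median
        of the model's own training predictors — so that scores from
        models trained on different folds share one comparable scale.
        """
        gene_values = np.atleast_2d(np.asarray(gene_values, dtype=float))
        if len(self.genes):
            z = (gene_values - self.means) / self.sds
            s = z @ self.coefficients
        else:
            s = np.zeros(gene_values.shape[0])
        if self.clinical_terms:
            cv = np.atleast_2d(np.asarray(clinical_values, dtype=float))
            s = s + cv @ np.array(list(self.clinical_terms.values()))
        return s - self.center

    def report(self) -> pd.DataFrame:
        """Signature table: per gene its screening p-value and Cox coefficient."""
        return pd.DataFrame(
            {
                "gene": list(self.genes),
                "logrank_p": self.logrank_p if self.logrank_p is not None else np.nan,
                "coefficient": self.coefficients,
            }
        )


@dataclass(frozen=True)
class CVResult:
    """Everything the LOOCV produces, one score per patient."""

    scores: np.ndarray
    cutoff: float
    high_risk: np.ndarray  # boolean; True = score above the median
    cv_logrank: LogrankResult
    per_fold_models: tuple[RiskModel, ...]
    selection_frequency: dict[str, int]
    empty_folds: int
    unconverged_folds: int

    @property
    def risk_group(self) -> np.ndarray:
        return np.where(self.high_risk, "high", "low")


def select_genes(
    matrix: MutationMatrix, outcome: SurvivalOutcome, config: SelectionConfig
) -> list[tuple[str, float]]:
    """Screen every gene with the mutated-vs-wild-type log-rank test.

    Returns ``(gene, p)`` pairs with p < alpha, ordered by ascending p.
    Genes whose mutated or wild-type group is empty are untestable and
    skipped.
    """
    _, p, testable = logrank_screen(outcome.time, outcome.event, matrix.values)
    hits = np.flatnonzero(testable & (p < config.alpha))
    hits = hits[np.argsort(p[hits], kind="stable")]
    return [(str(matrix.gene_symbols[j]), float(p[j])) for j in hits]


def standardize(
    train_values: np.ndarray, apply_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise (x − train_mean) / train_sd, sample sd (n−1 denominator).

    Returns (standardized apply_values, train means, train sds).  A zero
    training sd is an error — it cannot occur for a screened gene, whose
    two groups are both non-empty.
    """
    train = np.atleast_2d(np.asarray(train_values, dtype=float))
    apply_ = np.atleast_2d(np.asarray(apply_values, dtype=float))
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero training standard deviation")
    return (apply_ - mean) / sd, mean, sd


def clinical_indicators(clinical: pd.DataFrame) -> pd.DataFrame:
    """The four 0/1 model covariates; NaN where the source value is missing.

    Contrasts: age ≤60 vs >60; grade 2 vs 3; stages II–III vs IV;
    microscopic vs macroscopic residual.
    """

    def _ind(series, positive):
        vals = series.astype(object)
        return vals.map(lambda v: np.nan if pd.isna(v) else float(str(v) == positive))

    return pd.DataFrame(
        {
            "age_gt60": pd.to_numeric(clinical["age_gt60"], errors="coerce"),
            "grade3": _ind(clinical["grade"], "3"),
            "stage4": _ind(clinical["stage"], "4"),
            "macroscopic": _ind(clinical["residual"], "macroscopic"),
        },
        index=clinical.index,
    )


def _fit_fold(
    X: np.ndarray,
    train_idx: np.ndarray | slice,
    gene_symbols: np.ndarray,
    outcome: SurvivalOutcome,
    config: SelectionConfig,
    clin: np.ndarray | None,
    screen: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[RiskModel, bool]:
    """Select, standardize and fit on one training set. Returns (model, converged).

    ``X`` holds all gene columns; only the selected columns of the
    ``train_idx`` rows are ever materialized.  ``screen`` may carry
    precomputed per-gene (p, testable) arrays (the LOOCV loop supplies
    exact leave-one-out downdates), otherwise the screen is computed here.
    """
    if screen is None:
        sub = X[train_idx]
        _, p, testable = logrank_screen(outcome.time, outcome.event, sub)
    else:
        p, testable = screen
    hits = np.flatnonzero(testable & (p < config.alpha))
    hits = hits[np.argsort(p[hits], kind="stable")]
    k = hits.size
    if k == 0 and clin is None:
        return RiskModel((), np.empty(0), np.empty(0), np.empty(0)), True

    blocks = []
    names: list[str] = []
    if k:
        X_train = X[train_idx][:, hits] if isinstance(train_idx, slice) else X[
            np.ix_(train_idx, hits)
        ]
        z, mean, sd = standardize(X_train, X_train)
        blocks.append(z)
        names.extend(str(g) for g in gene_symbols[hits])
    else:
        mean = sd = np.empty(0)
    if clin is not None:
        blocks.append(clin)
        names.extend(CLINICAL_MODEL_TERMS)
    design = np.hstack(blocks)
    with warnings.catch_warnings(record=True):
        warnings.simplefilter("always")
        fit = cox_fit(design, outcome, names=tuple(names))
    converged = fit.converged
    clin_terms = None
    if clin is not None:
        clin_terms = dict(zip(CLINICAL_MODEL_TERMS, fit.coefficients[k:].tolist()))
    # center at the median training predictor: scores from different folds
    # become comparable, and "high risk" means above this model's own
    # training middle
    center = float(np.median(design @ fit.coefficients))
    model = RiskModel(
        tuple(str(g) for g in gene_symbols[hits]),
        mean,
        sd,
        fit.coefficients[:k],
        clin_terms,
        p[hits],
        center,
        fit,
    )
    return model, converged


def loocv_risk_scores(
    matrix: MutationMatrix,
    outcome: SurvivalOutcome,
    config: SelectionConfig = SelectionConfig(),
    clinical: pd.DataFrame | None = None,
) -> CVResult:
    """Complete leave-one-out cross-validation of the risk model.

    Gene screening, standardization and Cox fitting are all redone on
    every training set of n−1 patients; patient i's score comes from the
    model that never saw them.  Folds that select no gene contribute the
    empty linear predictor (score 0) rather than being dropped, so the
    median split always sees n scores.  When ``clinical`` is given the
    combined model is fitted (four clinical indicators forced into every
    fold); patients with a missing indicator must be excluded beforehand.

    Per-fold Cox non-convergence (monotone likelihood is possible in
    small folds) is logged and counted, never fatal.
    """
    n = matrix.n_patients
    if n < 20:
        raise ValueError("LOOCV needs at least 20 patients for meaningful folds")
    if len(outcome) != n:
        raise ValueError("matrix and outcome are misaligned")
    clin_values = None
    if clinical is not None:
        ind = clinical_indicators(clinical)
        if not np.array_equal(ind.index.to_numpy(), matrix.patient_ids):
            raise ValueError("clinical table misaligned with the matrix")
        clin_values = ind.to_numpy(dtype=float)
        if np.isnan(clin_values).any():
            raise ValueError(
                "combined model requires complete clinical indicators; "
                "drop incomplete patients first (complete-case analysis)"
            )

    X = matrix.values.astype(float)
    gene_col = {str(g): j for j, g in enumerate(matrix.gene_symbols)}
    screen_cache = LoocvLogrankScreen(outcome.time, outcome.event, X)
    scores = np.zeros(n)
    models: list[RiskModel] = []
    freq: dict[str, int] = {}
    empty_folds = 0
    unconverged = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        train_idx = np.flatnonzero(mask)
        model, converged = _fit_fold(
            X,
            train_idx,
            matrix.gene_symbols,
            outcome.subset(train_idx),
            config,
            None if clin_values is None else clin_values[train_idx],
            screen=screen_cache.screen(i),
        )
        mask[i] = True
        if not converged:
            unconverged += 1
            logger.warning("fold %d: Cox fit did not converge", i)
        if len(model.genes) == 0:
            empty_folds += 1
            logger.debug("fold %d selected no genes; score set to 0", i)
        for g in model.genes:
            freq[g] = freq.get(g, 0) + 1
        gene_cols = np.array([gene_col[g] for g in model.genes], dtype=int)
        scores[i] = model.score(
            X[i, gene_cols][None, :],
            None if clin_values is None else clin_values[i][None, :],
        )[0]
        models.append(model)

    cutoff = float(np.median(scores))
    high = scores > cutoff  # ties at the median fall to low risk
    if high.any() and not high.all():
        cv_lr = logrank_test(outcome, high)
    else:
        warnings.warn(
            "degenerate median split (all cross-validated scores tied); "
            "cross-validated log-rank undefined, reporting p = 1",
            stacklevel=2,
        )
        cv_lr = LogrankResult(0.0, 1.0, (0.0, 0.0))
    return CVResult(
        scores,
        cutoff,
        high,
        cv_lr,
        tuple(models),
        dict(sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))),
        empty_folds,
        unconverged,
    )


def fit_final_model(
    matrix: MutationMatrix,
    outcome: SurvivalOutcome,
    config: SelectionConfig = SelectionConfig(),
    clinical: pd.DataFrame | None = None,
) -> RiskModel:
    """Single full-cohort pass: screen, standardize, fit.

    This is the model one would report as the signature (per-gene
    screening p-value and Cox coefficient); its apparent performance on
    the same cohort is optimistic, which is what the LOOCV quantifies.
    """
    clin_values = None
    if clinical is not None:
        ind = clinical_indicators(clinical)
        clin_values = ind.to_numpy(dtype=float)
        if np.isnan(clin_values).any():
            raise ValueError("combined model requires complete clinical indicators")
    model, converged = _fit_fold(
        matrix.values.astype(float), slice(None), matrix.gene_symbols,
        outcome, config, clin_values,
    )
    if model.is_empty:
        warnings.warn("no gene passed the screening threshold; model is empty",
                      stacklevel=2)
    if not converged:
        warnings.warn("final Cox fit did not converge", stacklevel=2)
    return model


def selection_frequency_report(cv: CVResult) -> pd.DataFrame:
    """Genes by the number of folds whose model included them, descending.

    In a strong signature most genes appear in nearly every fold (n or
    n−1 of n); genes never selected do not appear.
    """
    return pd.DataFrame(
        {
            "gene": list(cv.selection_frequency),
            "folds_selected": list(cv.selection_frequency.values()),
        }
    )
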