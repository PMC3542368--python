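"""End-to-end orchestration: one call from input files (or a simulated
cohort) to the full artifact set.

The bundle written to the output directory mirrors what a study report
needs: the signature table (gene, screening p, Cox coefficient), the
per-patient cross-validated scores and risk groups, Kaplan–Meier tables
for the two risk groups with medians and the between-group hazard ratio,
the permutation p-value for the cross-validated log-rank statistic, ROC
points and AUC at the landmark time, AUC-over-time tables (genes-only
and, when clinical data is supplied, the combined model on an aligned
grid), risk-group × clinical-factor association tables, and a manifest
recording every parameter and seed so the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    align_cohort,
    cohort_summary,
    filter_rare_genes,
    read_maf,
)
from .pipeline import (
    SelectionConfig,
    clinical_indicators,
    fit_final_model,
    loocv_risk_scores,
    selection_frequency_report,
)
from .permutation import PermutationConfig, permutation_pvalue
from .simulate import SimConfig, generate_cohort
from .survival import (
    SurvivalOutcome,
    association_test,
    group_hazard_ratio,
    km_estimate,
)
from .tdroc import ROCConfig, auc_over_time, roc_at_time

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

ASSOCIATION_FACTORS = {
    "age": ("age_gt60", {0.0: "<=60", 1.0: ">60"}),
    "grade": ("grade", None),
    "stage": ("stage", None),
    "surgical_outcome": ("residual", None),
    "platinum_status": ("platinum", None),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one input source: (maf_path, clinical_path) for real files, or
    sim for a synthetic cohort.
    """

    endpoint: str = "OS"
    maf_path: str | None = None
    clinical_path: str | None = None
    sim: SimConfig | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    roc: ROCConfig = field(default_factory=ROCConfig)
    min_mutated_patients: int = 5
    combined: bool = False
    auc_grid: tuple[float, ...] = (12.0, 24.0, 36.0, 48.0, 60.0)
    out_dir: str = "somaticsurv_run"
    seed: int = 0

    def __post_init__(self) -> None:
        files = self.maf_path is not None and self.clinical_path is not None
        if files == (self.sim is not None):
            raise ValueError("provide either input file paths or a SimConfig, not both")


def _km_table(outcome: SurvivalOutcome, label: np.ndarray) -> pd.DataFrame:
    frames = []
    for grp in ("low", "high"):
        sel = label == grp
        km = km_estimate(outcome.subset(np.flatnonzero(sel)))
        frames.append(
            pd.DataFrame(
                {
                    "risk_group": grp,
                    "time": km.event_times,
                    "at_risk": km.at_risk,
                    "events": km.n_events,
                    "survival": km.survival,
                    "greenwood_var": km.greenwood_var,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _association_tables(clinical: pd.DataFrame, label: np.ndarray) -> pd.DataFrame:
    """Risk-group × factor contingency tables with chi-square p-values."""
    rows = []
    groups = pd.Series(label, index=clinical.index)
    for factor, (col, relabel) in ASSOCIATION_FACTORS.items():
        vals = clinical[col]
        mask = vals.notna()
        if mask.sum() == 0:
            continue
        v = vals[mask]
        if relabel:
            v = v.map(relabel)
        tab = pd.crosstab(v, groups[mask])
        if tab.shape[0] < 2 or tab.shape[1] < 2 or (tab.sum(0) == 0).any():
            logger.info("skipping association for %s: degenerate table", factor)
            continue
        tab = tab.reindex(columns=["low", "high"])
        res = association_test(tab.to_numpy())
        for level, row in tab.iterrows():
            rows.append(
                {
                    "factor": factor,
                    "level": str(level),
                    "low_risk": int(row["low"]),
                    "high_risk": int(row["high"]),
                    "chi2": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the complete pipeline and write the report bundle.

    Returns a dict of the headline numbers; all tables land in
    ``config.out_dir``.  Identical configs give byte-identical bundles.
    On a stage failure the partially written bundle is removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    def _write_json(name: str, obj) -> None:
        p = out_dir / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
        written.append(p)

    stage = "setup"
    try:
        stage = "load"
        stage = "filter"
        # genes are rare-filtered on the full matrix, before the
        # missing-outcome exclusion restricts the patient set
        if config.sim is not None:
            cohort = generate_cohort(config.sim)
            matrix = filter_rare_genes(
                cohort.mutation_matrix, config.min_mutated_patients
            )
            clinical = cohort.clinical
            outcome = (
                cohort.os_outcome
                if config.endpoint.upper() == "OS"
                else cohort.pfs_outcome
            )
        else:
            raw = read_maf(config.maf_path)
            filtered = filter_rare_genes(raw, config.min_mutated_patients)
            matrix, outcome, clinical = align_cohort(
                filtered, config.clinical_path, config.endpoint
            )
        _write_json("cohort_summary.json", cohort_summary(matrix, outcome))

        stage = "loocv"
        cv = loocv_risk_scores(matrix, outcome, config.selection)
        _write_df(
            "cv_scores.csv",
            pd.DataFrame(
                {
                    "patient_id": matrix.patient_ids,
                    "score": cv.scores,
                    "risk_group": cv.risk_group,
                }
            ),
        )
        _write_df("selection_frequency.csv", selection_frequency_report(cv))
        _write_df("km_risk_groups.csv", _km_table(outcome, cv.risk_group))

        low = np.flatnonzero(~cv.high_risk)
        high = np.flatnonzero(cv.high_risk)
        km_low = km_estimate(outcome.subset(low))
        km_high = km_estimate(outcome.subset(high))
        hr, lo_ci, hi_ci = group_hazard_ratio(outcome, ~cv.high_risk)

        stage = "final model"
        final = fit_final_model(matrix, outcome, config.selection)
        _write_df("gene_signature.csv", final.report())

        stage = "permutation"
        perm = permutation_pvalue(
            matrix, outcome, config.selection, config.permutation
        )
        _write_json("permutation.json", perm.summary())

        stage = "roc"
        roc = roc_at_time(cv.scores, outcome, config.roc)
        _write_df(
            "roc_points.csv",
            pd.DataFrame(
                {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
            ),
        )
        auc_genes = auc_over_time(cv.scores, outcome, config.auc_grid, config.roc)
        auc_tables = {
            "genes_only": pd.DataFrame(auc_genes, columns=["t", "auc"])
        }

        cv_combined = None
        if config.combined:
            stage = "combined model"
            ind = clinical_indicators(clinical)
            complete = ind.notna().all(axis=1).to_numpy()
            if complete.sum() < 20:
                raise ValueError("too few complete-case patients for the combined model")
            idx = np.flatnonzero(complete)
            cv_combined = loocv_risk_scores(
                matrix.subset_patients(idx),
                outcome.subset(idx),
                config.selection,
                clinical.iloc[idx],
            )
            auc_comb = auc_over_time(
                cv_combined.scores, outcome.subset(idx), config.auc_grid, config.roc
            )
            auc_tables["combined"] = pd.DataFrame(auc_comb, columns=["t", "auc"])
            _write_df(
                "cv_scores_combined.csv",
                pd.DataFrame(
                    {
                        "patient_id": matrix.patient_ids[idx],
                        "score": cv_combined.scores,
                        "risk_group": cv_combined.risk_group,
                    }
                ),
            )
        for name, tab in auc_tables.items():
            _write_df(f"auc_over_time_{name}.csv", tab)

        stage = "association"
        assoc = _association_tables(clinical, cv.risk_group)
        _write_df("risk_group_associations.csv", assoc)

        stage = "manifest"
        headline = {
            "endpoint": config.endpoint.upper(),
            "n_patients": int(matrix.n_patients),
            "n_genes_after_filter": int(matrix.n_genes),
            "cv_logrank_statistic": cv.cv_logrank.statistic,
            "cv_logrank_naive_p": cv.cv_logrank.p_value,
            "permutation_p": perm.p_value,
            "median_low_risk": km_low.median,
            "median_low_risk_ci": list(km_low.median_ci),
            "median_high_risk": km_high.median,
            "median_high_risk_ci": list(km_high.median_ci),
            "hazard_ratio_low_vs_high": hr,
            "hazard_ratio_ci": [lo_ci, hi_ci],
            "auc_landmark": roc.auc,
            "landmark_t": config.roc.landmark_t,
            "empty_folds": cv.empty_folds,
        }
        manifest = {
            "somaticsurv_version": __version__,
            "config": _config_dict(config),
            "headline": _jsonable(headline),
        }
        _write_json("manifest.json", manifest)
        headline["out_dir"] = str(out_dir)
        return headline
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.sim is not None:
        d["sim"] = config.sim.to_dict()
    d["auc_grid"] = list(config.auc_grid)
    d.pop("out_dir")  # a location, not a parameter: identical runs must
    return _jsonable(d)  # produce identical manifests wherever they land


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
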