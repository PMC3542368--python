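"""Synthetic Ov-HGSC-like cohorts for exercising the risk pipeline.

The generator emulates the statistical structure the downstream analysis
assumes: a patients × genes binary somatic-mutation incidence matrix with
per-gene mutation frequencies in the range seen after rare-gene filtering
of an exome-sequenced serous ovarian carcinoma cohort (roughly 300
patients, several hundred genes, each mutated in at least ~1.5% of
patients), survival drawn from a proportional-hazards model in which a
small set of causal genes carries the signal, independent exponential
censoring with an administrative follow-up cap, and categorical clinical
covariates with missing-completely-at-random gaps.

Overall and progression-free survival are simulated as independent draws
(the analysis treats the endpoints as separate modeling problems);
progression uses a shorter baseline time scale.  Exponential baselines
keep closed-form sanity checks available — with no causal genes and no
censoring, observed times are i.i.d. exponential with mean
1/baseline_hazard.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .survival import SurvivalOutcome
from .io import MutationMatrix, MAF_COLUMNS

__all__ = ["SimConfig", "SyntheticCohort", "generate_cohort", "write_fixture"]

# Marginal clinical frequencies matching an advanced-stage serous ovarian
# carcinoma cohort: ~half the patients over 60, grade 3 dominant, mostly
# stage III, macroscopic residual disease in ~4 of 5 debulkings, and about
# two thirds platinum-sensitive among evaluable patients.
_CLINICAL_MARGINALS = {
    "age_gt60": {1: 0.49, 0: 0.51},
    "grade": {"2": 0.09, "3": 0.91},
    "stage": {"2": 0.045, "3": 0.78, "4": 0.175},
    "residual": {"microscopic": 0.21, "macroscopic": 0.79},
    "platinum": {"sensitive": 0.67, "resistant": 0.33},
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions of the motivating cohort: ~311
    patients, a few hundred candidate genes each mutated in 1.6%–15% of
    patients, a handful of prognostic genes with per-mutation log hazard
    ratio 1.0, an exponential overall-survival baseline with median near
    four years, and censoring tuned to yield roughly half observed events
    within a ten-year administrative follow-up window.
    """

    n_patients: int = 311
    n_genes: int = 509
    causal_genes: int = 5
    causal_log_hr: float = 1.0
    mutation_freq_range: tuple[float, float] = (0.016, 0.15)
    baseline_hazard: float = 0.015  # events per month; median OS ≈ 46 months
    pfs_hazard_multiplier: float = 3.0  # progression runs on a ~3x faster clock
    censor_rate: float = 0.010  # per month
    max_followup: float = 120.0  # months
    clinical_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.causal_genes <= self.n_genes:
            raise ValueError("causal_genes must lie in [0, n_genes]")
        if not math.isfinite(self.causal_log_hr):
            raise ValueError("causal_log_hr must be finite")
        lo, hi = self.mutation_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("mutation_freq_range must satisfy 0 < low <= high < 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.pfs_hazard_multiplier <= 0:
            raise ValueError("pfs_hazard_multiplier must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be positive")
        if not 0 <= self.clinical_missing_rate < 1:
            raise ValueError("clinical_missing_rate must lie in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Load a config from YAML or JSON; the seed key is mandatory."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        if "seed" not in raw:
            raise ValueError("simulation config must state a seed")
        if "mutation_freq_range" in raw:
            raw["mutation_freq_range"] = tuple(raw["mutation_freq_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mutation_freq_range"] = list(self.mutation_freq_range)
        return d


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: mutations, both endpoints, clinical table, truth."""

    mutation_matrix: MutationMatrix
    os_outcome: SurvivalOutcome
    pfs_outcome: SurvivalOutcome
    clinical: pd.DataFrame
    truth: tuple[tuple[str, float], ...]
    config: SimConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        pids = self.mutation_matrix.patient_ids
        if not (
            np.array_equal(pids, self.os_outcome.patient_ids)
            and np.array_equal(pids, self.pfs_outcome.patient_ids)
            and np.array_equal(pids, self.clinical.index.to_numpy())
        ):
            raise ValueError("cohort components must share one patient ordering")
        genes = set(self.mutation_matrix.gene_symbols)
        for g, _ in self.truth:
            if g not in genes:
                raise ValueError(f"truth gene {g!r} missing from the matrix")


def _draw_survival(rng: np.random.Generator, hazard: np.ndarray, config: SimConfig):
    n = hazard.size
    latent = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, n)
    else:
        censor = np.full(n, np.inf)
    horizon = np.minimum(censor, config.max_followup)
    observed = np.minimum(latent, horizon)
    event = (latent <= horizon).astype(np.int8)
    # strictly positive times: guard against floating underflow at tiny draws
    observed = np.maximum(observed, 1e-9)
    return observed, event


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort, reproducible from ``config.seed``.

    Gene columns are independent Bernoulli with per-gene frequencies drawn
    uniformly over ``mutation_freq_range``; the first ``causal_genes``
    genes each add ``causal_log_hr`` to the log hazard of a mutated
    patient.  OS and PFS are independent conditional on the matrix.
    """
    rng = np.random.default_rng(config.seed)
    n, G = config.n_patients, config.n_genes
    patient_ids = np.array([f"TCGA-SS-{i:04d}" for i in range(n)])
    gene_symbols = np.array([f"SG{j:04d}" for j in range(G)])

    lo, hi = config.mutation_freq_range
    freqs = rng.uniform(lo, hi, G)
    X = (rng.random((n, G)) < freqs).astype(np.int8)
    matrix = MutationMatrix(patient_ids, gene_symbols, X)

    beta = np.zeros(G)
    beta[: config.causal_genes] = config.causal_log_hr
    log_rel_hazard = X[:, : config.causal_genes] @ beta[: config.causal_genes]
    os_time, os_event = _draw_survival(
        rng, config.baseline_hazard * np.exp(log_rel_hazard), config
    )
    pfs_time, pfs_event = _draw_survival(
        rng,
        config.baseline_hazard * config.pfs_hazard_multiplier * np.exp(log_rel_hazard),
        config,
    )

    clin = {}
    for col, marg in _CLINICAL_MARGINALS.items():
        levels = list(marg)
        probs = np.array([marg[k] for k in levels], dtype=float)
        draw = rng.choice(len(levels), size=n, p=probs / probs.sum())
        values = pd.Series([levels[k] for k in draw], index=patient_ids, dtype=object)
        if config.clinical_missing_rate > 0:
            gaps = rng.random(n) < config.clinical_missing_rate
            values[gaps] = None
        clin[col] = values
    clinical = pd.DataFrame(clin, index=pd.Index(patient_ids, name="patient_id"))

    truth = tuple(
        (str(gene_symbols[j]), float(config.causal_log_hr))
        for j in range(config.causal_genes)
    )
    return SyntheticCohort(
        matrix,
        SurvivalOutcome(os_time, os_event, patient_ids),
        SurvivalOutcome(pfs_time, pfs_event, patient_ids),
        clinical,
        truth,
        config,
    )


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as a MAF-dialect mutation file plus a clinical TSV.

    The files round-trip exactly through :func:`somaticsurv.io.read_maf` and
    :func:`somaticsurv.io.read_clinical`.  Sample barcodes carry a trailing
    aliquot token so the reader's barcode-truncation rule is exercised.
    Patients with zero mutations appear only in the clinical file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    maf_path = directory / "mutations.maf.tsv"
    clin_path = directory / "clinical.tsv"

    m = cohort.mutation_matrix
    rows_i, cols_j = np.nonzero(m.values)
    with open(maf_path, "w") as fh:
        fh.write("\t".join(MAF_COLUMNS) + "\n")
        for i, j in zip(rows_i, cols_j):
            fh.write(
                f"{m.gene_symbols[j]}\t{m.patient_ids[i]}-01A\tMissense_Mutation\n"
            )

    clinical = cohort.clinical
    out = pd.DataFrame(
        {
            "patient_id": m.patient_ids,
            "os_months": cohort.os_outcome.time,
            "os_event": cohort.os_outcome.event,
            "pfs_months": cohort.pfs_outcome.time,
            "pfs_event": cohort.pfs_outcome.event,
        }
    )
    for col in ("age_gt60", "grade", "stage", "residual", "platinum"):
        out[col] = clinical[col].to_numpy()
    out.to_csv(clin_path, sep="\t", index=False, float_format="%.10g")

    truth_path = directory / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "causal_genes": [[g, b] for g, b in cohort.truth],
                "config": cohort.config.to_dict() if cohort.config else None,
            },
            fh,
            indent=1,
        )
    return {"mutations": maf_path, "clinical": clin_path, "truth": truth_path}
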