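"""Cohort input/output: mutation files, clinical tables, cohort filters.

Reads a MAF-dialect tab-separated mutation file into a binary
patients × genes incidence matrix (1 = the patient carries at least one
somatic mutation in the gene), applies the rare-gene filter, and aligns
the matrix with a clinical table for a chosen survival endpoint.

"Rarely mutated" is interpreted as the number of *distinct mutated
patients*, not the raw mutation count — the matrix is binary and the
model works on per-patient incidence — with the threshold configurable
(default 5).  Variant classes are not filtered by default; a silent-class
exclusion flag is available.  All times are months; day-scaled inputs are
converted only on explicit request (factor 30.44), never silently.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import SurvivalOutcome

__all__ = [
    "MutationMatrix",
    "FormatError",
    "read_maf",
    "read_clinical",
    "filter_rare_genes",
    "align_cohort",
    "cohort_summary",
]

MAF_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")
CLINICAL_COLUMNS = (
    "patient_id",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "age_gt60",
    "grade",
    "stage",
    "residual",
    "platinum",
)
GRADE_LEVELS = ("2", "3")
STAGE_LEVELS = ("2", "3", "4")
RESIDUAL_LEVELS = ("microscopic", "macroscopic")
PLATINUM_LEVELS = ("sensitive", "resistant")

SILENT_CLASSES = frozenset({"Silent", "silent"})
DAYS_PER_MONTH = 30.44

# TCGA-style patient id: first three dash-delimited tokens of the barcode
DEFAULT_BARCODE_PATTERN = r"^([^-]+-[^-]+-[^-]+)"


class FormatError(ValueError):
    """A required column or structure is missing from an input file."""


@dataclass(frozen=True)
class MutationMatrix:
    """Binary somatic-mutation incidence, patients × genes."""

    patient_ids: np.ndarray
    gene_symbols: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pids = np.asarray(self.patient_ids)
        genes = np.asarray(self.gene_symbols)
        vals = np.asarray(self.values, dtype=np.int8)
        if vals.shape != (pids.size, genes.size):
            raise ValueError("matrix shape does not match id/symbol lengths")
        if pids.size != np.unique(pids).size:
            raise ValueError("duplicate patient ids")
        if genes.size != np.unique(genes).size:
            raise ValueError("duplicate gene symbols")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        object.__setattr__(self, "patient_ids", pids)
        object.__setattr__(self, "gene_symbols", genes)
        object.__setattr__(self, "values", vals)

    @property
    def n_patients(self) -> int:
        return self.patient_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_symbols.size

    def mutated_patient_counts(self) -> np.ndarray:
        """Per gene: number of patients carrying at least one mutation."""
        return self.values.sum(axis=0)

    def subset_patients(self, index: np.ndarray) -> "MutationMatrix":
        return MutationMatrix(
            self.patient_ids[index], self.gene_symbols, self.values[index]
        )

    def subset_genes(self, index: np.ndarray) -> "MutationMatrix":
        return MutationMatrix(
            self.patient_ids, self.gene_symbols[index], self.values[:, index]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.gene_symbols,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_triplets(self, path: str | Path) -> None:
        """Sparse (patient_id, gene, 1) triplet CSV."""
        i, j = np.nonzero(self.values)
        pd.DataFrame(
            {
                "patient_id": self.patient_ids[i],
                "gene": self.gene_symbols[j],
                "mutated": 1,
            }
        ).to_csv(path, index=False)


def read_maf(
    path: str | Path,
    barcode_pattern: str = DEFAULT_BARCODE_PATTERN,
    exclude_silent: bool = False,
) -> MutationMatrix:
    """Build the binary incidence matrix from a MAF-dialect TSV.

    One row per mutation; multiple mutations of a gene in one sample
    collapse to a single 1.  Sample barcodes are reduced to patient ids by
    ``barcode_pattern`` (first capture group; default: the first three
    dash-delimited tokens, the TCGA participant id).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in MAF_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path.name}: no mutation rows")
    if exclude_silent:
        df = df[~df["Variant_Classification"].isin(SILENT_CLASSES)]
        if len(df) == 0:
            raise FormatError(f"{path.name}: no rows left after silent-class filter")

    pattern = re.compile(barcode_pattern)

    def _patient(barcode: str) -> str:
        m = pattern.match(barcode)
        return m.group(1) if m else barcode

    patients = df["Tumor_Sample_Barcode"].map(_patient)
    genes = df["Hugo_Symbol"]
    patient_ids = np.sort(patients.unique())
    gene_symbols = np.sort(genes.unique())
    pi = pd.Index(patient_ids).get_indexer(patients)
    gi = pd.Index(gene_symbols).get_indexer(genes)
    values = np.zeros((patient_ids.size, gene_symbols.size), dtype=np.int8)
    values[pi, gi] = 1
    return MutationMatrix(patient_ids, gene_symbols, values)


def read_clinical(path: str | Path, times_in_days: bool = False) -> pd.DataFrame:
    """Read the clinical TSV; returns a patient-indexed typed DataFrame.

    Survival columns stay numeric with NaN for missing; categorical
    columns are validated against their allowed levels (missing allowed).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    if df["patient_id"].duplicated().any():
        raise FormatError(f"{path.name}: duplicate patient ids")
    df = df.set_index("patient_id")
    for col in ("os_months", "os_event", "pfs_months", "pfs_event"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if times_in_days:
        df["os_months"] = df["os_months"] / DAYS_PER_MONTH
        df["pfs_months"] = df["pfs_months"] / DAYS_PER_MONTH
    df["age_gt60"] = pd.to_numeric(df["age_gt60"], errors="coerce")
    levels = {
        "grade": GRADE_LEVELS,
        "stage": STAGE_LEVELS,
        "residual": RESIDUAL_LEVELS,
        "platinum": PLATINUM_LEVELS,
    }
    for col, allowed in levels.items():
        vals = df[col].astype(object)
        vals = vals.map(lambda v: None if pd.isna(v) else str(v).split(".")[0] if col in ("grade", "stage") else str(v))
        bad = set(v for v in vals.dropna().unique()) - set(allowed)
        if bad:
            raise FormatError(f"{path.name}: column {col!r} has invalid levels {sorted(bad)}")
        df[col] = vals
    return df


def filter_rare_genes(
    matrix: MutationMatrix, min_mutated_patients: int = 5
) -> MutationMatrix:
    """Drop genes mutated in fewer than ``min_mutated_patients`` patients.

    The patient set is unchanged.  With the default threshold of 5 this is
    the rare-gene exclusion applied before candidate-gene screening.
    """
    if min_mutated_patients < 1:
        raise ValueError("min_mutated_patients must be >= 1")
    keep = matrix.mutated_patient_counts() >= min_mutated_patients
    if not keep.any():
        warnings.warn("rare-gene filter removed every gene", stacklevel=2)
    return matrix.subset_genes(np.flatnonzero(keep))


def align_cohort(
    matrix: MutationMatrix,
    clinical: pd.DataFrame | str | Path,
    endpoint: str = "OS",
) -> tuple[MutationMatrix, SurvivalOutcome, pd.DataFrame]:
    """Restrict matrix + clinical data to patients with the chosen endpoint.

    Patients missing the endpoint's time or event indicator (or with a
    non-positive time) are dropped; the remaining tables are restricted to
    the id intersection in one canonical (sorted) order.
    """
    if isinstance(clinical, (str, Path)):
        clinical = read_clinical(clinical)
    endpoint = endpoint.upper()
    if endpoint not in ("OS", "PFS"):
        raise ValueError("endpoint must be 'OS' or 'PFS'")
    tcol, ecol = (("os_months", "os_event") if endpoint == "OS" else ("pfs_months", "pfs_event"))
    ok = clinical[tcol].notna() & clinical[ecol].notna() & (clinical[tcol] > 0)
    keep_ids = np.intersect1d(matrix.patient_ids, clinical.index[ok].to_numpy())
    if keep_ids.size == 0:
        raise ValueError("no patients shared between mutation and clinical data "
                         f"with complete {endpoint} follow-up")
    midx = pd.Index(matrix.patient_ids).get_indexer(keep_ids)
    sub_matrix = matrix.subset_patients(midx)
    clin = clinical.loc[keep_ids]
    outcome = SurvivalOutcome(
        clin[tcol].to_numpy(dtype=float),
        clin[ecol].to_numpy(dtype=np.int8),
        keep_ids,
    )
    return sub_matrix, outcome, clin


def cohort_summary(matrix: MutationMatrix, outcome: SurvivalOutcome) -> dict:
    counts = matrix.mutated_patient_counts()
    return {
        "n_patients": int(matrix.n_patients),
        "n_genes": int(matrix.n_genes),
        "total_mutated_cells": int(counts.sum()),
        "events": int(outcome.n_events),
        "censored": int(len(outcome) - outcome.n_events),
        "median_followup_months": float(np.median(outcome.time)),
    }


def write_cohort_summary(path: str | Path, matrix, outcome) -> None:
    with open(path, "w") as fh:
        json.dump(cohort_summary(matrix, outcome), fh, indent=1)
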