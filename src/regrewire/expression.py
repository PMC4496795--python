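"""Expression matrices, sample sheets, and regulator/target sample matching.

mRNA and miRNA abundances live in separate feature-by-sample matrices whose
sample ids need not coincide (real matched tumor/normal cohorts profile the
two modalities on overlapping but unequal sample sets).  For an edge, the
regulator's values come from the matrix of its modality (miRNA regulators
from the miRNA matrix, everything else from the mRNA matrix), the target's
likewise, and the two vectors are restricted to the samples of the requested
cohort and condition present in BOTH matrices, matched by exact sample id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "MatchedVectors",
    "EdgeSkipped",
    "load_expression",
    "load_sample_sheet",
    "samples_for",
    "matched_vectors",
]

MODALITIES = ("mRNA", "miRNA")
SHEET_COLUMNS = ("sample_id", "patient_id", "condition", "cohort")
CONDITIONS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """A rectangular feature-by-sample abundance matrix with a modality tag."""

    modality: str
    values: pd.DataFrame  # index: feature ids; columns: sample ids

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class MatchedVectors:
    """Paired regulator/target values over matched samples of one condition."""

    edge: Any
    condition: str
    n: int
    x: np.ndarray
    y: np.ndarray
    sample_ids: list[str]


class EdgeSkipped(Exception):
    """Signal that an edge cannot be scored; carries a machine-readable reason."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)


def load_expression(path: str | Path, modality: str) -> ExpressionMatrix:
    """Load a features-by-samples TSV (first column feature id, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression file {path} is empty")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated feature row {dup!r} in {path}")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        row = df.index[coerced.isna()][0] if coerced.isna().any() else "?"
        raise ValueError(f"non-numeric value in {path} at feature {row!r}, sample {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(modality=modality, values=df)


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Load a sample sheet TSV with columns sample_id, patient_id, condition, cohort."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition values {sorted(bad)}; expected {CONDITIONS}")
    if (sheet["cohort"].isna() | (sheet["cohort"] == "")).any():
        raise ValueError("empty cohort value in sample sheet")
    return sheet


def samples_for(sheet: pd.DataFrame, cohort: str, condition: str) -> list[str]:
    """Sample ids of one cohort and condition, in sheet order."""
    mask = (sheet["cohort"] == cohort) & (sheet["condition"] == condition)
    return sheet.loc[mask, "sample_id"].tolist()


def matrix_for_kind(kind: str, mrna: ExpressionMatrix, mirna: ExpressionMatrix) -> ExpressionMatrix:
    """The matrix a feature of *kind* is profiled in (miRNA -> miRNA matrix)."""
    return mirna if kind == "miRNA" else mrna


def matched_vectors(
    edge: Any,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    sheet: pd.DataFrame,
    cohort: str,
    condition: str,
) -> MatchedVectors:
    """Matched regulator/target value vectors for one edge, cohort and condition.

    Raises :class:`EdgeSkipped` (reason ``feature_missing``) when either
    endpoint is not profiled in its modality's matrix; callers treat this as
    a logged skip, not a hard error.
    """
    reg_id, reg_kind = edge.regulator_id, edge.regulator_kind
    tgt_id, tgt_kind = edge.target_id, edge.target_kind
    reg_mat = matrix_for_kind(reg_kind, mrna, mirna)
    tgt_mat = matrix_for_kind(tgt_kind, mrna, mirna)
    if reg_id not in reg_mat.features:
        raise EdgeSkipped("feature_missing", reg_id)
    if tgt_id not in tgt_mat.features:
        raise EdgeSkipped("feature_missing", tgt_id)
    wanted = samples_for(sheet, cohort, condition)
    reg_cols = set(reg_mat.samples)
    tgt_cols = set(tgt_mat.samples)
    shared = [s for s in wanted if s in reg_cols and s in tgt_cols]
    x = reg_mat.values.loc[reg_id, shared].to_numpy(dtype=float)
    y = tgt_mat.values.loc[tgt_id, shared].to_numpy(dtype=float)
    return MatchedVectors(
        edge=edge, condition=condition, n=len(shared), x=x, y=y, sample_ids=shared
    )
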