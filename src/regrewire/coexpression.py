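"""Co-expression scoring of a regulatory network.

Each scorable regulation gets a Spearman rank correlation between regulator
and target expression over matched samples, which is variance-stabilized by
the Fisher transformation and standardized by the matched sample count:

    z = arctanh(rho) * sqrt(n - 3)

so networks built from cohorts of different depth are comparable.  A
regulation with |z| >= 2.5 is called significantly correlated; "top k%"
condition-specific networks retain the k% of regulations with largest |z|.
Reciprocal (feedback) pairs are scored once per pair via a canonical key —
Spearman correlation is symmetric.

Sign summaries treat a positive correlation as evidence of activation and a
negative one of repression, and test whether either sign is over-represented
in a top network against the full (100%) scored network by a one-sided
Fisher's exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, matrix_for_kind, samples_for
from .grn import GRN, RegulationClass, pair_key

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeCorrelation",
    "CorrelatedGRN",
    "spearman_rho",
    "fisher_z",
    "scoring_units",
    "score_network",
    "significant_edges",
    "top_percent",
    "sign_activity",
]

#: |z| threshold for a significantly correlated regulation.
Z_THRESHOLD = 2.5
#: |rho| is clamped to this before arctanh so perfect correlations stay finite.
RHO_CLAMP = 1.0 - 1e-7

RECORD_COLUMNS = [
    "edge_key", "pair_key", "reg_class",
    "regulator_id", "regulator_kind", "target_id", "target_kind",
    "condition", "n", "rho", "z", "clamped",
]

#: Alias kept for symmetry with the domain vocabulary: one row of a scored
#: table (edge, condition, matched n, Spearman rho, standardized Fisher z).
EdgeCorrelation = pd.Series


@dataclass
class CorrelatedGRN:
    """A condition-specific correlated network: retained scored regulations."""

    condition: str
    selection: str
    records: pd.DataFrame

    @property
    def edge_keys(self) -> set[str]:
        return set(self.records["edge_key"])

    @property
    def nodes(self) -> set[str]:
        """Interactors: nodes touching at least one retained regulation."""
        if self.records.empty:
            return set()
        return set(self.records["regulator_id"]) | set(self.records["target_id"])


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with average ranks for ties.

    Returns NaN (the undefined-correlation signal) when either vector is
    constant; callers skip and log such edges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def fisher_z(rho, n):
    """Standardized Fisher transform arctanh(rho)*sqrt(n-3); NaN for n < 4.

    rho is clamped to +/-(1 - 1e-7) so |rho| = 1 maps to a large finite score
    that preserves ranking.  Works element-wise on arrays.
    """
    rho_a = np.asarray(rho, dtype=float)
    n_a = np.asarray(n, dtype=float)
    clamped = np.clip(rho_a, -RHO_CLAMP, RHO_CLAMP)
    with np.errstate(invalid="ignore"):
        z = np.arctanh(clamped) * np.sqrt(n_a - 3.0)
    z = np.where(n_a >= 4, z, np.nan)
    if np.isscalar(rho) and np.isscalar(n):
        return float(z)
    return z


def scoring_units(grn: GRN) -> pd.DataFrame:
    """One row per scoring unit: each unidirectional edge, each reciprocal pair once.

    Bidirectional pairs use a canonical orientation (BiTM: TF as regulator;
    BiTT: lexicographically smaller id as regulator) and the unordered pair
    key as ``edge_key``; unidirectional edges use ``"regulator>target"``.
    """
    if not grn.classified:
        raise ValueError("GRN must be classified before scoring (run classify_edges)")
    e = grn.edges
    rows = []
    seen_pairs: set[str] = set()
    bidir = {RegulationClass.BITT.value, RegulationClass.BITM.value}
    for row in e.itertuples(index=False):
        pk = pair_key(row.regulator_id, row.target_id)
        if row.reg_class in bidir:
            if pk in seen_pairs:
                continue
            seen_pairs.add(pk)
            reg_id, reg_kind = row.regulator_id, row.regulator_kind
            tgt_id, tgt_kind = row.target_id, row.target_kind
            if row.reg_class == RegulationClass.BITM.value and reg_kind != "TF":
                reg_id, reg_kind, tgt_id, tgt_kind = tgt_id, tgt_kind, reg_id, reg_kind
            elif row.reg_class == RegulationClass.BITT.value and reg_id > tgt_id:
                reg_id, tgt_id = tgt_id, reg_id
            rows.append((pk, pk, row.reg_class, reg_id, reg_kind, tgt_id, tgt_kind))
        else:
            ek = f"{row.regulator_id}>{row.target_id}"
            rows.append((ek, pk, row.reg_class, row.regulator_id, row.regulator_kind,
                         row.target_id, row.target_kind))
    return pd.DataFrame(
        rows,
        columns=["edge_key", "pair_key", "reg_class",
                 "regulator_id", "regulator_kind", "target_id", "target_kind"],
    )


def _rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center+normalize average ranks per row; flags constant rows."""
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks ** 2).sum(axis=1))
    constant = norm == 0
    norm[constant] = 1.0
    return ranks / norm[:, None], constant


def score_network(
    grn: GRN,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    sheet: pd.DataFrame,
    cohort: str,
    condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every scorable regulation of one cohort and condition.

    Returns ``(records, skips)``: *records* has one row per scoring unit with
    finite z (columns :data:`RECORD_COLUMNS`), *skips* the unscorable units
    with reasons (``feature_missing``, ``n_lt_4``, ``constant_values``).
    Spearman correlations are computed as Pearson correlations of average
    ranks, vectorized per modality pairing (all units of a pairing share one
    matched-sample universe).
    """
    wanted = samples_for(sheet, cohort, condition)
    if not wanted:
        raise ValueError(f"no samples for cohort {cohort!r}, condition {condition!r}")
    units = scoring_units(grn)
    records: list[pd.DataFrame] = []
    skips: list[tuple[str, str, str]] = []  # edge_key, reason, detail

    mods = units["regulator_kind"].where(units["regulator_kind"] == "miRNA", "mRNA")
    tmods = units["target_kind"].where(units["target_kind"] == "miRNA", "mRNA")
    for (rmod, tmod), grp in units.groupby([mods, tmods], sort=True):
        reg_mat = mirna if rmod == "miRNA" else mrna
        tgt_mat = mirna if tmod == "miRNA" else mrna
        reg_feats = set(reg_mat.features)
        tgt_feats = set(tgt_mat.features)
        ok = grp["regulator_id"].isin(reg_feats) & grp["target_id"].isin(tgt_feats)
        for row in grp[~ok].itertuples(index=False):
            missing = row.regulator_id if row.regulator_id not in reg_feats else row.target_id
            skips.append((row.edge_key, "feature_missing", missing))
        grp = grp[ok]
        if grp.empty:
            continue
        reg_cols = set(reg_mat.samples)
        tgt_cols = set(tgt_mat.samples)
        shared = [s for s in wanted if s in reg_cols and s in tgt_cols]
        n = len(shared)
        if n < 4:
            skips.extend((ek, "n_lt_4", str(n)) for ek in grp["edge_key"])
            continue
        reg_vals = reg_mat.values.loc[grp["regulator_id"], shared].to_numpy(dtype=float)
        tgt_vals = tgt_mat.values.loc[grp["target_id"], shared].to_numpy(dtype=float)
        xr, x_const = _rank_rows(reg_vals)
        yr, y_const = _rank_rows(tgt_vals)
        rho = np.einsum("ij,ij->i", xr, yr)
        constant = x_const | y_const
        if constant.any():
            skips.extend(
                (ek, "constant_values", "") for ek in grp.loc[grp.index[constant], "edge_key"]
            )
        keep = grp[~constant].copy()
        rho = rho[~constant]
        keep["condition"] = condition
        keep["n"] = n
        keep["rho"] = np.clip(rho, -1.0, 1.0)
        keep["z"] = fisher_z(keep["rho"].to_numpy(), n)
        keep["clamped"] = np.abs(keep["rho"].to_numpy()) >= RHO_CLAMP
        records.append(keep)

    if records:
        out = pd.concat(records, ignore_index=True)[RECORD_COLUMNS]
        out = out.sort_values("edge_key", kind="mergesort").reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=RECORD_COLUMNS)
    skips_df = pd.DataFrame(skips, columns=["edge_key", "reason", "detail"])
    if len(skips_df):
        logger.info(
            "score_network(%s/%s): %d scored, %d skipped (%s)",
            cohort, condition, len(out), len(skips_df),
            dict(skips_df["reason"].value_counts()),
        )
    return out, skips_df


def significant_edges(records: pd.DataFrame, z_thresh: float = Z_THRESHOLD) -> pd.DataFrame:
    """Records with |z| >= z_thresh (inclusive boundary)."""
    z = records["z"].to_numpy(dtype=float)
    return records[np.isfinite(z) & (np.abs(z) >= z_thresh)].reset_index(drop=True)


def _ranked(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df["_absz"] = df["z"].abs()
    df = df.sort_values(
        by=["_absz", "pair_key", "regulator_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_absz")
    return df


def top_percent(records: pd.DataFrame, k: float, condition: str | None = None) -> CorrelatedGRN:
    """The ceil(k*N) records with largest |z| as a :class:`CorrelatedGRN`.

    Ties at the cut are broken deterministically (|z| descending, pair key
    ascending).  ``k = 1.0`` retains everything.
    """
    if not (0 < k <= 1):
        raise ValueError(f"k must be in (0, 1], got {k}")
    if condition is None:
        condition = records["condition"].iloc[0] if len(records) else "?"
    n_keep = math.ceil(k * len(records))
    retained = _ranked(records).head(n_keep).reset_index(drop=True)
    return CorrelatedGRN(condition=condition, selection=f"top_{k:g}", records=retained)


def sign_activity(correlated: CorrelatedGRN, background: CorrelatedGRN) -> pd.DataFrame:
    """Per-class positive/negative regulation counts and sign-enrichment p-values.

    For each regulation class, counts of positive (z >= 0; zero counted
    positive) and negative records in the top network, and one-sided Fisher's
    exact p-values for over-representation of each sign versus the background
    (100%) network of the same scoring run.  A class absent from the top
    network gets zero counts and p = 1.
    """
    rows = []
    bg = background.records
    top = correlated.records
    for cls in [c.value for c in RegulationClass]:
        t = top[top["reg_class"] == cls]
        b = bg[bg["reg_class"] == cls]
        tp = int((t["z"] >= 0).sum())
        tn = int((t["z"] < 0).sum())
        bp = int((b["z"] >= 0).sum())
        bn = int((b["z"] < 0).sum())
        if tp > bp or tn > bn:
            raise ValueError("top network is not a subset of the background")
        if tp + tn == 0:
            p_pos = p_neg = 1.0
        else:
            p_pos = stats.fisher_exact(
                [[tp, tn], [bp - tp, bn - tn]], alternative="greater"
            ).pvalue
            p_neg = stats.fisher_exact(
                [[tn, tp], [bn - tn, bp - tp]], alternative="greater"
            ).pvalue
        rows.append((cls, tp, tn, float(p_pos), float(p_neg)))
    return pd.DataFrame(rows, columns=["reg_class", "n_pos", "n_neg", "p_pos", "p_neg"])
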