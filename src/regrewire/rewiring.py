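"""Normal-vs-tumor network comparison: overlap, rewiring, D(z), loop ranking.

Two condition-specific correlated networks built under the same selection
rule are compared three ways:

* **Overlap** — Jaccard fractions of shared interactors (nodes touching a
  retained regulation) and shared interactions (retained regulations).
* **Rewiring** — every regulation present in exactly one condition is
  classified by how many of its two endpoints remain interactors in the
  other condition's network: type I (both retained), II (one), III (none),
  with a gained/lost direction (lost = normal-only, gained = tumor-only).
* **Differential co-expression** — for every regulation scored in both
  conditions and significant (|z| >= threshold) in at least one, the score
  D = |z_N - z_T|; the top fraction of D values is flagged DC.  TF–miRNA
  feedback (BiTM) pairs with a D value in every cohort are ranked by mean D
  across cohorts to nominate consistently rewired feedback loops.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._stats import rank_sum_test
from .coexpression import CorrelatedGRN, Z_THRESHOLD
from .grn import RegulationClass

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapStats",
    "overlap_stats",
    "compare_overlap_across_cohorts",
    "classify_rewiring",
    "dz",
    "dc_select",
    "rank_bitm_across_cohorts",
]

#: Default fraction of D(z) values flagged differentially co-expressed.
DC_FRACTION = 0.10

DC_COLUMNS = [
    "edge_key", "pair_key", "reg_class",
    "regulator_id", "regulator_kind", "target_id", "target_kind",
    "z_normal", "z_tumor", "D",
]


@dataclass
class OverlapStats:
    """Jaccard overlap of interactors and interactions between two networks."""

    jaccard_interactors: float
    jaccard_interactions: float
    n_shared_nodes: int
    n_total_nodes: int
    n_shared_edges: int
    n_total_edges: int


def overlap_stats(net_n: CorrelatedGRN, net_t: CorrelatedGRN) -> OverlapStats:
    """Overlap between the normal and tumor networks of one selection rule."""
    nodes_n, nodes_t = net_n.nodes, net_t.nodes
    edges_n, edges_t = net_n.edge_keys, net_t.edge_keys
    node_union = nodes_n | nodes_t
    edge_union = edges_n | edges_t
    if not node_union and not edge_union:
        warnings.warn("both networks are empty; overlap reported as 0", stacklevel=2)
    return OverlapStats(
        jaccard_interactors=len(nodes_n & nodes_t) / len(node_union) if node_union else 0.0,
        jaccard_interactions=len(edges_n & edges_t) / len(edge_union) if edge_union else 0.0,
        n_shared_nodes=len(nodes_n & nodes_t),
        n_total_nodes=len(node_union),
        n_shared_edges=len(edges_n & edges_t),
        n_total_edges=len(edge_union),
    )


def compare_overlap_across_cohorts(interactor_fracs, interaction_fracs) -> float:
    """Two-sided Wilcoxon rank-sum p comparing the two overlap fractions.

    One value per cohort in each sample; exact enumeration for combined
    size <= 12, normal approximation with tie correction otherwise.
    """
    if len(interactor_fracs) == 0 or len(interaction_fracs) == 0:
        raise ValueError("both samples of overlap fractions must be non-empty")
    return rank_sum_test(interactor_fracs, interaction_fracs, alternative="two-sided")


def classify_rewiring(net_n: CorrelatedGRN, net_t: CorrelatedGRN) -> pd.DataFrame:
    """Classify every gained/lost regulation by endpoint retention.

    For each regulation in the symmetric difference of the two edge sets,
    the number of its endpoints that are interactors in the OTHER
    condition's network determines the type: 2 -> I, 1 -> II, 0 -> III.
    Returns columns ``edge_key, direction (gained|lost), type, regulator_id,
    target_id, reg_class``.
    """
    type_by_kept = {0: "III", 1: "II", 2: "I"}
    keys_n, keys_t = net_n.edge_keys, net_t.edge_keys
    rows = []
    for direction, source, other_nodes in (
        ("lost", net_n, net_t.nodes),
        ("gained", net_t, net_n.nodes),
    ):
        only = (keys_n - keys_t) if direction == "lost" else (keys_t - keys_n)
        by_key = source.records.set_index("edge_key")
        for key in sorted(only):
            rec = by_key.loc[key]
            kept = int(rec["regulator_id"] in other_nodes) + int(rec["target_id"] in other_nodes)
            rows.append(
                (key, direction, type_by_kept[kept],
                 rec["regulator_id"], rec["target_id"], rec["reg_class"])
            )
    return pd.DataFrame(
        rows, columns=["edge_key", "direction", "type", "regulator_id", "target_id", "reg_class"]
    )


def dz(
    records_n: pd.DataFrame,
    records_t: pd.DataFrame,
    z_thresh: float = Z_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential co-expression score D = |z_N - z_T| per eligible regulation.

    A regulation is eligible when it has a finite z in both conditions and is
    significantly correlated (|z| >= z_thresh) in at least one — requiring
    both would discard exactly the gained/lost regulations of interest.
    Returns ``(dc_records, omitted)`` where *omitted* carries reasons
    ``missing_condition`` or ``not_significant``.
    """
    meta_cols = ["edge_key", "pair_key", "reg_class",
                 "regulator_id", "regulator_kind", "target_id", "target_kind"]
    n = records_n[meta_cols + ["z"]].rename(columns={"z": "z_normal"})
    t = records_t[meta_cols + ["z"]].rename(columns={"z": "z_tumor"})
    merged = n.merge(t, on=meta_cols, how="outer")
    missing = merged["z_normal"].isna() | merged["z_tumor"].isna()
    omitted = [
        (k, "missing_condition") for k in merged.loc[missing, "edge_key"]
    ]
    both = merged[~missing].copy()
    eligible = (both["z_normal"].abs() >= z_thresh) | (both["z_tumor"].abs() >= z_thresh)
    omitted += [(k, "not_significant") for k in both.loc[~eligible, "edge_key"]]
    both = both[eligible].copy()
    both["D"] = (both["z_normal"] - both["z_tumor"]).abs()
    both = both.sort_values("edge_key", kind="mergesort").reset_index(drop=True)
    omitted_df = pd.DataFrame(omitted, columns=["edge_key", "reason"])
    return both[DC_COLUMNS], omitted_df


def dc_select(records: pd.DataFrame, top_fraction: float = DC_FRACTION) -> pd.DataFrame:
    """Flag the ceil(top_fraction * N) records with largest D as DC.

    Ties broken deterministically (D descending, pair key ascending).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    if records.empty:
        out = records.copy()
        out["dc_flag"] = pd.Series(dtype=bool)
        return out
    n_keep = math.ceil(top_fraction * len(records))
    order = records.sort_values(
        by=["D", "pair_key"], ascending=[False, True], kind="mergesort"
    )
    flagged = set(order.head(n_keep)["edge_key"])
    out = records.copy()
    out["dc_flag"] = out["edge_key"].isin(flagged)
    return out


def rank_bitm_across_cohorts(
    per_cohort: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank TF–miRNA feedback (BiTM) pairs by mean D across cohorts.

    Only pairs with a D value in *every* supplied cohort are ranked (mean D
    descending, pair key breaking ties); pairs covered in some but not all
    cohorts are returned separately.  Returns ``(ranking, partial)`` where
    *ranking* has one row per fully covered pair with per-cohort D columns
    ``D_<cohort>`` and ``mean_D``.
    """
    if not per_cohort:
        raise ValueError("at least one cohort required")
    cohorts = list(per_cohort)
    frames = []
    for cohort in cohorts:
        df = per_cohort[cohort]
        bitm = df[df["reg_class"] == RegulationClass.BITM.value]
        frames.append(
            bitm[["pair_key", "regulator_id", "target_id", "D"]]
            .rename(columns={"D": f"D_{cohort}"})
        )
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=["pair_key", "regulator_id", "target_id"], how="outer")
    d_cols = [f"D_{c}" for c in cohorts]
    full = merged.dropna(subset=d_cols).copy()
    partial = merged[merged[d_cols].isna().any(axis=1)].copy()
    if full.empty:
        warnings.warn("no BiTM pair has a D value in every cohort", stacklevel=2)
        full["mean_D"] = pd.Series(dtype=float)
        return full, partial
    full["mean_D"] = full[d_cols].mean(axis=1)
    full = full.sort_values(
        by=["mean_D", "pair_key"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    full.insert(0, "rank", np.arange(1, len(full) + 1))
    return full, partial.reset_index(drop=True)
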