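"""Exact enrichment tests, cancer-association categories, combined p-values,
and the differential-expression test used for target-module selection.

All 2x2 tests are Fisher's exact test (hypergeometric).  For a TF–miRNA
feedback (BiTM) pair, annotation against cancer-association lists yields a
category: CN (only the TF annotated), NC (only the miRNA), CC (both),
NN (neither); a regulation counts as cancer-associated when at least one
endpoint is annotated.  Per-cohort gene-set p-values are combined across
cohorts with Fisher's method (-2 * sum(ln p) ~ chi-square with 2k df).

The differential-expression test here is a deliberate substitute for count
model based callers (such as edgeR used on raw sequencing counts): it takes
abundance values as given and combines a log2(x+1) mean fold change with an
exact/asymptotic Wilcoxon rank-sum p-value.  It fills the same decision role
(alpha = 0.05, direction by fold-change sign) while staying self-contained;
rank-based, its p-value is invariant under monotone transforms of the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import rank_sum_test
from .coexpression import Z_THRESHOLD
from .grn import RegulationClass

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_exact",
    "assoc_category",
    "cancer_assoc_enrichment",
    "read_gmt",
    "write_gmt",
    "geneset_enrichment",
    "fisher_combined",
    "de_test",
    "regulator_module",
]

DE_ALPHA = 0.05


def fisher_exact(table, alternative: str = "greater") -> float:
    """Fisher's exact p for a 2x2 count table.

    *alternative* is ``greater``/``less`` (one-sided on the top-left cell) or
    ``two_sided`` (sum of table probabilities <= observed).
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    alt = {"two_sided": "two-sided"}.get(alternative, alternative)
    if alt not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(stats.fisher_exact(arr, alternative=alt).pvalue)


def _endpoint_annotated(node_id: str, kind: str, cancer_genes: set, cancer_mirnas: set) -> bool:
    return node_id in (cancer_mirnas if kind == "miRNA" else cancer_genes)


def assoc_category(row, cancer_genes: set, cancer_mirnas: set) -> str:
    """CN/NC/CC/NN category of a BiTM pair row (TF stored as regulator)."""
    tf_assoc = _endpoint_annotated(
        row["regulator_id"], row["regulator_kind"], cancer_genes, cancer_mirnas
    )
    mir_assoc = _endpoint_annotated(
        row["target_id"], row["target_kind"], cancer_genes, cancer_mirnas
    )
    return {
        (True, False): "CN",
        (False, True): "NC",
        (True, True): "CC",
        (False, False): "NN",
    }[(tf_assoc, mir_assoc)]


def cancer_assoc_enrichment(
    dc_pairs: pd.DataFrame,
    background_pairs: pd.DataFrame,
    cancer_genes: Iterable[str],
    cancer_mirnas: Iterable[str],
) -> dict:
    """Cancer-association enrichment of DC regulations against the background.

    *dc_pairs* must be a subset of *background_pairs* (matched by
    ``edge_key``); both need endpoint id/kind columns.  Returns a dict with

    ``overall``
        one-sided Fisher p-values (over/under) for regulations with at least
        one cancer-associated endpoint among DC vs the rest of the
        background, plus the DC cancer-associated proportion, and
    ``bitm_categories``
        per-category (CN/NC/CC) over- and under-representation p-values
        among BiTM pairs.
    """
    if background_pairs.empty:
        raise ValueError("background pair set is empty")
    cg, cm = set(cancer_genes), set(cancer_mirnas)
    dc_keys = set(dc_pairs["edge_key"])
    if not dc_keys <= set(background_pairs["edge_key"]):
        raise ValueError("DC pairs must be a subset of the background pairs")

    def annotated(df: pd.DataFrame) -> np.ndarray:
        reg = [
            _endpoint_annotated(i, k, cg, cm)
            for i, k in zip(df["regulator_id"], df["regulator_kind"])
        ]
        tgt = [
            _endpoint_annotated(i, k, cg, cm)
            for i, k in zip(df["target_id"], df["target_kind"])
        ]
        return np.asarray(reg) | np.asarray(tgt)

    rest = background_pairs[~background_pairs["edge_key"].isin(dc_keys)]
    a = int(annotated(dc_pairs).sum()) if len(dc_pairs) else 0
    b = len(dc_pairs) - a
    c = int(annotated(rest).sum()) if len(rest) else 0
    d = len(rest) - c
    overall = {
        "n_dc": len(dc_pairs),
        "n_background": len(background_pairs),
        "n_dc_assoc": a,
        "prop_dc_assoc": a / len(dc_pairs) if len(dc_pairs) else float("nan"),
        "p_over": fisher_exact([[a, b], [c, d]], "greater"),
        "p_under": fisher_exact([[a, b], [c, d]], "less"),
    }

    bitm = RegulationClass.BITM.value
    dc_bitm = dc_pairs[dc_pairs["reg_class"] == bitm]
    rest_bitm = rest[rest["reg_class"] == bitm]
    cat_dc = (
        dc_bitm.apply(assoc_category, axis=1, args=(cg, cm)) if len(dc_bitm) else pd.Series(dtype=str)
    )
    cat_rest = (
        rest_bitm.apply(assoc_category, axis=1, args=(cg, cm))
        if len(rest_bitm)
        else pd.Series(dtype=str)
    )
    rows = []
    for cat in ("CN", "NC", "CC"):
        k_dc = int((cat_dc == cat).sum())
        k_rest = int((cat_rest == cat).sum())
        table = [
            [k_dc, len(cat_dc) - k_dc],
            [k_rest, len(cat_rest) - k_rest],
        ]
        rows.append(
            (cat, k_dc, len(cat_dc), k_rest, len(cat_rest),
             fisher_exact(table, "greater"), fisher_exact(table, "less"))
        )
    categories = pd.DataFrame(
        rows,
        columns=["category", "k_dc", "n_dc_bitm", "k_background", "n_background_bitm",
                 "p_over", "p_under"],
    )
    return {"overall": overall, "bitm_categories": categories}


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, tab-separated ids)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {p for p in parts[2:] if p}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{description}\t{members}\n")
    return path


def geneset_enrichment(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Each set is intersected with the universe before testing; the query must
    be a subset of the universe.  Returns a DataFrame sorted by raw p with
    Benjamini-Hochberg q-values alongside (columns
    ``set_id k K n N p q direction``).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    big_n, small_n = len(universe), len(query)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & universe
        k = len(members & query)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, small_n)) if big_k else 1.0
        expected = small_n * big_k / big_n
        rows.append((name, k, big_k, small_n, big_n, min(p, 1.0),
                     "over" if k >= expected else "under"))
    out = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p", "direction"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    out = out[["set_id", "k", "K", "n", "N", "p", "q", "direction"]]
    return out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)


def fisher_combined(pvalues: Iterable[float]) -> float:
    """Fisher's combined probability: -2*sum(ln p) against chi-square(2k)."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat, p = stats.combine_pvalues(ps, method="fisher")
    return float(p)


def de_test(values_normal, values_tumor) -> tuple[float, float]:
    """Differential-expression substitute: (log2 fold change, rank-sum p).

    log2fc = mean(log2(x+1)) in tumor minus normal; p is the two-sided
    Wilcoxon rank-sum p (exact for small samples).  Each group needs at
    least 3 values; smaller groups return (nan, nan) — callers skip the
    feature.
    """
    xn = np.asarray(values_normal, dtype=float)
    xt = np.asarray(values_tumor, dtype=float)
    if len(xn) < 3 or len(xt) < 3:
        return float("nan"), float("nan")
    log2fc = float(np.mean(np.log2(xt + 1)) - np.mean(np.log2(xn + 1)))
    p = rank_sum_test(xt, xn, alternative="two-sided")
    return log2fc, p


def regulator_module(
    tf_id: str,
    scored_edges: pd.DataFrame,
    de_results: pd.DataFrame,
    z_thresh: float = Z_THRESHOLD,
    de_alpha: float = DE_ALPHA,
) -> set[str]:
    """Activated target-gene set of one regulator in tumor samples.

    Targets of *tf_id* whose tumor-condition standardized correlation is
    positive and significant (z > z_thresh, one-sided) AND that are
    up-regulated (DE p < de_alpha with log2fc > 0).  *scored_edges* are
    tumor-condition correlation records; *de_results* has columns
    ``feature, log2fc, p``.  Feeds per-cohort gene-set enrichment whose
    p-values are then combined across cohorts with :func:`fisher_combined`.
    """
    targets = scored_edges[scored_edges["regulator_id"] == tf_id]
    if targets.empty:
        warnings.warn(f"regulator {tf_id!r} has no scored targets", stacklevel=2)
        return set()
    positive = targets[targets["z"] > z_thresh]
    de = de_results.set_index("feature")
    out = set()
    for gene in positive["target_id"]:
        if gene not in de.index:
            continue
        row = de.loc[gene]
        if row["p"] < de_alpha and row["log2fc"] > 0:
            out.add(gene)
    return out
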