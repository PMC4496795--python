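"""Drug-signature amplitude, up/down classification, and drug–gene subnetworks.

The amplitude of a drug–gene expression signature follows the Connectivity
Map convention:

    a = 2 (t - c) / (|t| + |c|)

where t and c are the (scaled, thresholded) average-difference values of the
treatment and control groups.  a = 0 means no differential expression, a > 0
increased expression upon treatment, a < 0 decreased; a is bounded in
[-2, 2], antisymmetric in (t, c) and scale invariant.  A treatment value
exactly two-fold a positive control gives a = 2/3 ~ 0.67, which is the
classification cutoff: a > 0.67 -> up, a < -0.67 -> down, otherwise neutral
(strict inequalities, 0.67 applied literally).

The subnetwork assembles the up- and down-classified drugs and their
interacting genes into a bipartite graph annotated with regulation class,
target status and ATC class, exportable as GraphML or SIF.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "amplitude",
    "classify_signatures",
    "build_subnetwork",
    "export_subnetwork",
]

#: Amplitude magnitude above which a signature counts as up/down (two-fold).
AMPLITUDE_CUTOFF = 0.67


def amplitude(t: float, c: float) -> float:
    """CMap-style amplitude a = 2(t - c)/(|t| + |c|).

    Undefined for t = c = 0 (returns NaN; such signatures are dropped and
    logged by :func:`classify_signatures`).
    """
    denom = abs(t) + abs(c)
    if denom == 0:
        return float("nan")
    return 2.0 * (t - c) / denom


def classify_signatures(
    signatures: pd.DataFrame,
    cutoff: float = AMPLITUDE_CUTOFF,
    collapse: str | None = None,
) -> pd.DataFrame:
    """Compute amplitudes and classify signatures as up/down/neutral.

    *signatures* needs columns ``drug_id, t, c``.  Rows with t = c = 0 are
    dropped with a log record.  With ``collapse="max_abs"`` multiple rows per
    drug are collapsed to the one with largest |a| (pair key order breaking
    ties); by default each row is one signature.
    """
    if collapse not in (None, "max_abs"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    df = signatures.copy()
    df["a"] = [amplitude(t, c) for t, c in zip(df["t"].astype(float), df["c"].astype(float))]
    undefined = df["a"].isna()
    if undefined.any():
        logger.info(
            "classify_signatures: dropped %d undefined signatures (t=c=0): %s",
            int(undefined.sum()), sorted(df.loc[undefined, "drug_id"]),
        )
        df = df[~undefined]
    if collapse == "max_abs":
        df = (
            df.assign(_abs=df["a"].abs())
            .sort_values(["_abs", "drug_id"], ascending=[False, True], kind="mergesort")
            .drop_duplicates("drug_id", keep="first")
            .drop(columns="_abs")
        )
    df = df.copy()
    df["sig_class"] = np.select(
        [df["a"] > cutoff, df["a"] < -cutoff], ["up", "down"], default="neutral"
    )
    return df.reset_index(drop=True)


def build_subnetwork(
    classed: pd.DataFrame,
    interactions: pd.DataFrame,
    target_annotation: Mapping[str, str] | None = None,
    drug_annotation: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Bipartite drug–gene graph over up/down drugs and their interactions.

    *classed* comes from :func:`classify_signatures`; *interactions* needs
    columns ``drug_id, gene_id`` (an optional ``source`` tag is kept as an
    edge attribute).  Duplicate drug–gene pairs are removed; interactions
    naming a drug without a classified signature are dropped with a warning;
    drugs classified neutral are excluded.  Node attributes: ``role``
    (drug|gene), ``reg_class`` (up|down, drugs), ``target_status``
    (validated|predicted|non-target, genes; default non-target) and ``atc``
    (drugs; default unclassified).
    """
    target_annotation = dict(target_annotation or {})
    drug_annotation = dict(drug_annotation or {})
    cls = classed.set_index("drug_id")["sig_class"].to_dict()
    inter = interactions.drop_duplicates(subset=["drug_id", "gene_id"], keep="first")
    unknown = sorted(set(inter["drug_id"]) - set(cls))
    if unknown:
        warnings.warn(
            f"{len(unknown)} interaction drug id(s) without a classified signature "
            f"dropped: {unknown[:5]}",
            stacklevel=2,
        )
        inter = inter[inter["drug_id"].isin(cls)]
    inter = inter[inter["drug_id"].map(cls).isin(("up", "down"))]

    g = nx.Graph()
    for drug in sorted(set(inter["drug_id"])):
        g.add_node(
            drug,
            role="drug",
            reg_class=cls[drug],
            atc=drug_annotation.get(drug, "unclassified"),
        )
    for gene in sorted(set(inter["gene_id"])):
        g.add_node(
            gene, role="gene", target_status=target_annotation.get(gene, "non-target")
        )
    has_source = "source" in inter.columns
    for row in inter.sort_values(["drug_id", "gene_id"]).itertuples(index=False):
        attrs = {"source": row.source} if has_source else {}
        g.add_edge(row.drug_id, row.gene_id, **attrs)
    return g


def export_subnetwork(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the subnetwork deterministically as GraphML or SIF."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        rows = [
            f"{u}\tinteracts\t{v}" for u, v in sorted(graph.edges())
        ]
        path.write_text("\n".join(rows) + ("\n" if rows else ""))
    else:
        raise ValueError(f"unsupported format {fmt!r}; supported: ('graphml', 'sif')")
    return path
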