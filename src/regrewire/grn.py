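"""Typed TF/miRNA regulatory graph: data model, regulation classes, file I/O.

A gene regulatory network (GRN) here is a directed graph whose regulators are
transcription factors (TFs) or microRNAs (miRNAs) and whose targets may be
TFs, miRNAs or plain protein-coding genes.  Every directed edge is assigned
one of four regulation classes:

``TFout``
    unidirectional TF -> target (no reciprocal edge),
``miRout``
    unidirectional miRNA -> target,
``BiTT``
    mutual regulation between two TFs (both directed edges present),
``BiTM``
    mutual regulation between a TF and a miRNA — a TF–miRNA feedback loop.

Both directed edges of a reciprocal pair carry the same bidirectional class,
and pair-level statistics use a canonical key (lexicographically smaller id
first).  A reciprocal miRNA–miRNA pair is not anticipated by this taxonomy
(both bidirectional classes require a TF); each such directed edge is kept as
``miRout`` and a warning is emitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NodeKind",
    "RegulationClass",
    "GRN",
    "pair_key",
    "load_grn",
    "classify_edges",
    "export_network",
]


class NodeKind(str, Enum):
    """Kind of a network node; an id maps to exactly one kind per network."""

    TF = "TF"
    MIRNA = "miRNA"
    GENE = "gene"


class RegulationClass(str, Enum):
    """Exhaustive, mutually exclusive edge classes of a classified GRN."""

    TFOUT = "TFout"
    MIROUT = "miRout"
    BITT = "BiTT"
    BITM = "BiTM"


_KIND_VALUES = {k.value for k in NodeKind}
_EDGE_COLUMNS = ["regulator_id", "regulator_kind", "target_id", "target_kind"]
EXPORT_FORMATS = ("tsv", "sif", "graphml")


def pair_key(a: str, b: str) -> str:
    """Canonical unordered key for a node pair (smaller id first)."""
    return f"{a}|{b}" if a <= b else f"{b}|{a}"


@dataclass
class GRN:
    """A typed regulatory network.

    Attributes
    ----------
    node_kinds:
        Mapping from node id to :class:`NodeKind` (stored as its string value).
    edges:
        DataFrame with columns ``regulator_id, regulator_kind, target_id,
        target_kind`` and, after :func:`classify_edges`, ``reg_class``.
    n_duplicates_removed, n_self_loops_removed:
        Counts recorded while loading.
    """

    node_kinds: dict[str, str]
    edges: pd.DataFrame
    n_duplicates_removed: int = 0
    n_self_loops_removed: int = 0

    def __post_init__(self) -> None:
        if self.edges is None or len(self.edges) == 0:
            self.edges = pd.DataFrame(columns=_EDGE_COLUMNS)
        missing = [c for c in _EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        for nid in pd.unique(
            pd.concat([self.edges["regulator_id"], self.edges["target_id"]])
        ):
            if nid not in self.node_kinds:
                raise ValueError(f"edge endpoint {nid!r} absent from node table")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.node_kinds)

    @property
    def classified(self) -> bool:
        return "reg_class" in self.edges.columns

    def kind(self, node_id: str) -> str:
        return self.node_kinds[node_id]

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator_id"], self.edges["target_id"]))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid in sorted(self.node_kinds):
            g.add_node(nid, kind=self.node_kinds[nid])
        cols = ["regulator_id", "target_id"]
        has_class = self.classified
        for row in self.edges.sort_values(cols).itertuples(index=False):
            attrs = {"reg_class": row.reg_class} if has_class else {}
            g.add_edge(row.regulator_id, row.target_id, **attrs)
        return g


def _read_node_kinds(path: str | Path) -> dict[str, str]:
    kinds = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "kind"} <= set(kinds.columns):
        raise ValueError(f"node-kind file {path} needs columns 'id' and 'kind'")
    out: dict[str, str] = {}
    for row in kinds.itertuples(index=False):
        if row.kind not in _KIND_VALUES:
            raise ValueError(
                f"unknown node kind {row.kind!r} for id {row.id!r}; "
                f"expected one of {sorted(_KIND_VALUES)}"
            )
        if row.id in out and out[row.id] != row.kind:
            raise ValueError(f"node {row.id!r} declared with conflicting kinds")
        out[row.id] = row.kind
    return out


def load_grn(path: str | Path, node_kinds: str | Path | dict[str, str] | None = None) -> GRN:
    """Load a GRN from an edge-list TSV plus node-kind annotation.

    The edge file needs columns ``regulator_id`` and ``target_id`` (an
    ``evidence`` column and embedded ``regulator_kind``/``target_kind``
    columns, as written by :func:`export_network`, are accepted).  Kinds come
    from *node_kinds* (TSV with columns ``id``/``kind``, or a dict), falling
    back to embedded kind columns.  Duplicate edges and self-loops are removed
    and counted; a malformed row raises with its line number; an id whose kind
    cannot be resolved raises naming the id.
    """
    try:
        edges = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return GRN(node_kinds={}, edges=pd.DataFrame(columns=_EDGE_COLUMNS))
    if edges.empty and edges.columns.size == 0:
        return GRN(node_kinds={}, edges=pd.DataFrame(columns=_EDGE_COLUMNS))
    for col in ("regulator_id", "target_id"):
        if col not in edges.columns:
            raise ValueError(f"edge file {path} missing column {col!r}")
        bad = edges.index[edges[col].isna() | (edges[col].astype(str).str.strip() == "")]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"malformed row at line {bad[0] + 2}: empty {col}")

    if isinstance(node_kinds, (str, Path)):
        kinds = _read_node_kinds(node_kinds)
    elif isinstance(node_kinds, dict):
        kinds = dict(node_kinds)
        for nid, k in kinds.items():
            if k not in _KIND_VALUES:
                raise ValueError(f"unknown node kind {k!r} for id {nid!r}")
    else:
        kinds = {}
        if {"regulator_kind", "target_kind"} <= set(edges.columns):
            for idc, kc in (("regulator_id", "regulator_kind"), ("target_id", "target_kind")):
                for nid, k in zip(edges[idc], edges[kc]):
                    if k not in _KIND_VALUES:
                        raise ValueError(f"unknown node kind {k!r} for id {nid!r}")
                    if kinds.setdefault(nid, k) != k:
                        raise ValueError(f"node {nid!r} declared with conflicting kinds")

    n_before = len(edges)
    self_loops = edges["regulator_id"] == edges["target_id"]
    n_self = int(self_loops.sum())
    edges = edges[~self_loops]
    n_dup = int(edges.duplicated(subset=["regulator_id", "target_id"]).sum())
    edges = edges.drop_duplicates(subset=["regulator_id", "target_id"], keep="first")
    if n_dup or n_self:
        logger.info(
            "load_grn(%s): %d duplicate, %d self-loop removed of %d rows",
            path, n_dup, n_self, n_before,
        )

    node_ids = pd.unique(pd.concat([edges["regulator_id"], edges["target_id"]]))
    for nid in node_ids:
        if nid not in kinds:
            raise ValueError(f"node kind unknown for id {nid!r}")
    used_kinds = {nid: kinds[nid] for nid in node_ids}

    out = edges[["regulator_id", "target_id"]].copy().reset_index(drop=True)
    out.insert(1, "regulator_kind", out["regulator_id"].map(used_kinds))
    out["target_kind"] = out["target_id"].map(used_kinds)
    if "reg_class" in edges.columns:
        out["reg_class"] = edges["reg_class"].to_numpy()
    return GRN(
        node_kinds=used_kinds,
        edges=out,
        n_duplicates_removed=n_dup,
        n_self_loops_removed=n_self,
    )


def classify_edges(grn: GRN) -> GRN:
    """Assign a :class:`RegulationClass` to every edge.

    An edge (u -> v) is ``BiTT`` iff (v -> u) also exists and both u, v are
    TFs; ``BiTM`` iff (v -> u) exists and the endpoint kinds are {TF, miRNA};
    otherwise ``TFout`` for a TF regulator and ``miRout`` for a miRNA
    regulator.  A gene appearing as a regulator is a hard error; a reciprocal
    miRNA–miRNA pair is classified ``miRout`` on both directed edges with a
    warning.
    """
    e = grn.edges
    bad = e.loc[e["regulator_kind"] == NodeKind.GENE.value, "regulator_id"]
    if len(bad):
        raise ValueError(f"node of kind 'gene' appears as a regulator: {bad.iloc[0]!r}")

    present = set(zip(e["regulator_id"], e["target_id"]))
    classes: list[str] = []
    warned_mir_pair = False
    for reg, rkind, tgt, tkind in zip(
        e["regulator_id"], e["regulator_kind"], e["target_id"], e["target_kind"]
    ):
        reciprocal = (tgt, reg) in present
        if reciprocal and rkind == "TF" and tkind == "TF":
            classes.append(RegulationClass.BITT.value)
        elif reciprocal and {rkind, tkind} == {"TF", "miRNA"}:
            classes.append(RegulationClass.BITM.value)
        elif rkind == "TF":
            classes.append(RegulationClass.TFOUT.value)
        else:
            if reciprocal and rkind == "miRNA" and tkind == "miRNA" and not warned_mir_pair:
                warnings.warn(
                    "reciprocal miRNA–miRNA pair found; both directed edges "
                    "classified miRout (bidirectional classes require a TF)",
                    stacklevel=2,
                )
                warned_mir_pair = True
            classes.append(RegulationClass.MIROUT.value)
    edges = e.copy()
    edges["reg_class"] = classes
    return replace(grn, edges=edges)


def export_network(grn: GRN, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a GRN to *path* as ``tsv``, ``sif`` or ``graphml``.

    The TSV dialect embeds endpoint kinds (and class, when present) so that
    ``load_grn(export)`` round-trips edges and kinds exactly.  SIF rows are
    ``source  relation  target`` with the regulation class (or ``regulates``)
    as relation.  GraphML carries node attribute ``kind`` and edge attribute
    ``reg_class``.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {EXPORT_FORMATS}")
    if fmt == "tsv":
        cols = _EDGE_COLUMNS + (["reg_class"] if grn.classified else [])
        grn.edges[cols].to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        rel = grn.edges["reg_class"] if grn.classified else "regulates"
        out = pd.DataFrame(
            {
                "source": grn.edges["regulator_id"],
                "relation": rel,
                "target": grn.edges["target_id"],
            }
        )
        out.to_csv(path, sep="\t", index=False, header=False)
    else:
        nx.write_graphml(grn.to_networkx(), path)
    return path
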