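"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the inputs of a matched tumor/normal multi-cohort
study: a typed TF/miRNA regulatory graph with unidirectional and reciprocal
(feedback) edges, mRNA and miRNA expression matrices with partial sample
overlap, per-edge Spearman correlations that may differ between normal and
tumor, tumor mean shifts on the log2 scale, cancer-association labels,
gene-set collections, and drug signature/interaction fixtures.  Every
generated entity has a truth record, and every output is a pure function of
``(spec, spec.seed)``.

Correlation planting uses latent Gaussians: a target's latent vector is
``r_P * regulator + sqrt(1 - r_P^2) * noise`` with the Pearson parameter
``r_P = 2 sin(pi * rho_S / 6)`` so the *planted Spearman* value equals the
requested one (the Pearson–Spearman relation for bivariate Gaussians).
Expression values are ``exp(log_mean + latent)`` — a strictly monotone map,
so sample Spearman correlations are unchanged and values live on a positive
abundance-like scale.  Targets of a shared regulator share one latent
factor, so sibling targets carry residual cross-correlation ``r1 * r2``;
this is a property of the construction, recorded rather than forced to
zero.  A feature that is the target of several planted edges keeps its
first planting (generation order); later plantings are recorded as
conflicts in the truth.

Default desk scale: seven cohorts of 60 normal + 60 tumor samples over a
network of ~250 directed edges, chosen so a full pipeline run takes well
under a minute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .coexpression import scoring_units
from .expression import ExpressionMatrix
from .grn import GRN, classify_edges, pair_key

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "PlantedLoop",
    "SimulationSpec",
    "Annotations",
    "SimulatedDataset",
    "default_spec",
    "plant_dc_loop",
    "generate_grn",
    "generate_expression",
    "generate_dataset",
    "generate_annotations",
]

LN2 = math.log(2.0)
DEFAULT_COHORTS = ("BRCA", "HNSC", "KIRC", "LUAD", "LUSC", "THCA", "UCEC")


@dataclass(frozen=True)
class CohortSpec:
    """One emulated cohort: matched sample counts and modality overlap."""

    name: str
    n_normal: int = 60
    n_tumor: int = 60
    mirna_sample_overlap_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.n_normal < 4 or self.n_tumor < 4:
            raise ValueError("sample counts must be >= 4")
        if not (0 < self.mirna_sample_overlap_fraction <= 1):
            raise ValueError("overlap fraction must be in (0, 1]")


@dataclass(frozen=True)
class PlantedLoop:
    """A TF–miRNA feedback pair rewired between conditions in every cohort.

    The pair is uncorrelated in normal samples and strongly positively
    correlated in tumor samples, with the TF shifted up in tumors — the
    expected rank-1 differentially co-expressed feedback loop.  The TF also
    gets a block of activated module targets (positively correlated in tumor
    and up-shifted) so target-module selection and gene-set enrichment have
    a planted answer.
    """

    rho_normal: float = 0.0
    rho_tumor: float = 0.8
    tf_shift_log2: float = 1.0
    n_module_targets: int = 12
    module_rho_normal: float = 0.3
    module_rho_tumor: float = 0.7
    target_shift_log2: float = 1.0


@dataclass(frozen=True)
class SimulationSpec:
    """Full study design of a synthetic run (node/edge counts, cohorts, effects)."""

    seed: int = 0
    n_tf: int = 15
    n_mirna: int = 15
    n_gene: int = 150
    n_tfout: int = 120
    n_mirout: int = 100
    n_bitt_pairs: int = 8
    n_bitm_pairs: int = 7
    cohorts: tuple[CohortSpec, ...] = tuple(CohortSpec(name) for name in DEFAULT_COHORTS)
    # per-class default planted Spearman correlations (rho_normal, rho_tumor)
    class_rho: tuple[tuple[str, float, float], ...] = (
        ("TFout", 0.4, 0.4),
        ("miRout", -0.3, -0.3),
        ("BiTT", 0.5, 0.5),
        ("BiTM", 0.4, 0.4),
    )
    planted_loop: PlantedLoop | None = None
    cancer_fraction: float = 0.2
    force_planted_labels: bool = True
    log_mean: float = 7.0

    def __post_init__(self) -> None:
        for _, rn, rt in self.class_rho:
            if not (-1 < rn < 1 and -1 < rt < 1):
                raise ValueError("planted correlations must lie in (-1, 1)")

    @property
    def class_rho_map(self) -> dict[str, tuple[float, float]]:
        return {c: (rn, rt) for c, rn, rt in self.class_rho}


@dataclass
class Annotations:
    """Cancer-association labels, gene sets, and drug fixtures with truth."""

    cancer_genes: set[str]
    cancer_mirnas: set[str]
    gene_sets: dict[str, set[str]]
    drug_signatures: pd.DataFrame   # drug_id, t, c
    drug_interactions: pd.DataFrame  # drug_id, gene_id, source
    target_annotation: dict[str, str]
    drug_annotation: dict[str, str]
    truth: dict


@dataclass
class SimulatedDataset:
    """A complete simulated study: network, expression, sheet, and truth."""

    spec: SimulationSpec
    grn: GRN
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    sheet: pd.DataFrame
    truth: dict


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """The default desk-scale study design with a given seed."""
    return replace(SimulationSpec(), seed=seed, **overrides)


def plant_dc_loop(spec: SimulationSpec, **loop_overrides) -> SimulationSpec:
    """Return a spec with one BiTM pair planted as rewired in every cohort."""
    if spec.n_bitm_pairs < 1:
        raise ValueError("cannot plant a feedback loop: spec has no BiTM pair")
    loop = replace(PlantedLoop(), **loop_overrides) if loop_overrides else PlantedLoop()
    if loop.n_module_targets > spec.n_tfout:
        raise ValueError("planted module larger than the TFout edge budget")
    return replace(spec, planted_loop=loop)


def _sample_distinct_pairs(rng, pool_a, pool_b, count, exclude=frozenset()):
    """Distinct (a, b) pairs, a != b, avoiding excluded unordered pairs."""
    pairs = []
    seen = set(exclude)
    attempts = 0
    limit = 1000 * max(count, 1)
    while len(pairs) < count:
        attempts += 1
        if attempts > limit:
            raise ValueError(
                f"could not place {count} pairs from pools of size "
                f"{len(pool_a)}x{len(pool_b)}; requested counts infeasible"
            )
        a = pool_a[rng.integers(len(pool_a))]
        b = pool_b[rng.integers(len(pool_b))]
        if a == b:
            continue
        key = pair_key(a, b)
        if key in seen:
            continue
        seen.add(key)
        pairs.append((a, b))
    return pairs


def generate_grn(spec: SimulationSpec) -> tuple[GRN, pd.DataFrame]:
    """Generate the typed network and its per-unit effect (truth) table.

    Returns ``(grn, units)`` where *units* has one row per scoring unit
    (reciprocal pairs once, canonical orientation) with planted
    ``rho_normal``/``rho_tumor`` and a ``planted`` flag on the loop pair and
    its module edges.  Regulator out-degrees for unidirectional edges follow
    a preferential-attachment scheme (weight = out-degree + 1), giving the
    heavy-tailed regulator degree distributions regulatory networks show.
    """
    if spec.n_bitm_pairs > spec.n_tf * spec.n_mirna:
        raise ValueError("n_bitm_pairs exceeds available TF x miRNA pairs")
    if spec.n_bitt_pairs > spec.n_tf * (spec.n_tf - 1) // 2:
        raise ValueError("n_bitt_pairs exceeds available TF pairs")
    rng = np.random.default_rng([spec.seed % (2**31), 1])
    tfs = [f"TF{i:02d}" for i in range(1, spec.n_tf + 1)]
    mirs = [f"mir{i:03d}" for i in range(1, spec.n_mirna + 1)]
    genes = [f"g{i:04d}" for i in range(1, spec.n_gene + 1)]
    kinds = {**{t: "TF" for t in tfs}, **{m: "miRNA" for m in mirs},
             **{g: "gene" for g in genes}}
    class_rho = spec.class_rho_map
    loop = spec.planted_loop

    units = []  # (reg, tgt, cls, rho_n, rho_t, planted)
    connected: set[str] = set()

    bitm_pairs = []
    if loop is not None:
        bitm_pairs.append((tfs[0], mirs[0]))
        connected.add(pair_key(tfs[0], mirs[0]))
    bitm_pairs += _sample_distinct_pairs(
        rng, tfs, mirs, spec.n_bitm_pairs - len(bitm_pairs), exclude=connected
    )
    for i, (tf, mir) in enumerate(bitm_pairs):
        connected.add(pair_key(tf, mir))
        planted = loop is not None and i == 0
        rho_n, rho_t = (
            (loop.rho_normal, loop.rho_tumor) if planted else class_rho["BiTM"]
        )
        units.append((tf, mir, "BiTM", rho_n, rho_t, planted))

    for a, b in _sample_distinct_pairs(rng, tfs, tfs, spec.n_bitt_pairs, exclude=connected):
        a, b = sorted((a, b))
        connected.add(pair_key(a, b))
        rho_n, rho_t = class_rho["BiTT"]
        units.append((a, b, "BiTT", rho_n, rho_t, False))

    out_degree = {t: 0 for t in tfs}
    n_module = loop.n_module_targets if loop is not None else 0
    module_genes = genes[:n_module]
    for g in module_genes:
        connected.add(pair_key(tfs[0], g))
        out_degree[tfs[0]] += 1
        units.append((tfs[0], g, "TFout", loop.module_rho_normal, loop.module_rho_tumor, True))

    def draw_unidirectional(regulators, degree, count, target_kind_probs):
        kinds_pool = {"gene": genes, "TF": tfs, "miRNA": mirs}
        placed = 0
        attempts = 0
        limit = 2000 * max(count, 1)
        out = []
        while placed < count:
            attempts += 1
            if attempts > limit:
                raise ValueError(
                    f"could not place {count} unidirectional edges; "
                    "requested counts infeasible for the node pools"
                )
            weights = np.array([degree[r] + 1.0 for r in regulators])
            reg = regulators[rng.choice(len(regulators), p=weights / weights.sum())]
            kind = rng.choice(
                list(target_kind_probs), p=list(target_kind_probs.values())
            )
            pool = kinds_pool[kind]
            tgt = pool[rng.integers(len(pool))]
            if tgt == reg or pair_key(reg, tgt) in connected:
                continue
            connected.add(pair_key(reg, tgt))
            degree[reg] += 1
            out.append((reg, tgt))
            placed += 1
        return out

    rho_n, rho_t = class_rho["TFout"]
    for reg, tgt in draw_unidirectional(
        tfs, out_degree, spec.n_tfout - n_module, {"gene": 0.8, "TF": 0.1, "miRNA": 0.1}
    ):
        units.append((reg, tgt, "TFout", rho_n, rho_t, False))
    mir_degree = {m: 0 for m in mirs}
    rho_n, rho_t = class_rho["miRout"]
    for reg, tgt in draw_unidirectional(
        mirs, mir_degree, spec.n_mirout, {"gene": 0.9, "TF": 0.1}
    ):
        units.append((reg, tgt, "miRout", rho_n, rho_t, False))

    edge_rows = []
    for reg, tgt, cls, *_ in units:
        edge_rows.append((reg, kinds[reg], tgt, kinds[tgt]))
        if cls in ("BiTT", "BiTM"):
            edge_rows.append((tgt, kinds[tgt], reg, kinds[reg]))
    edges = pd.DataFrame(
        edge_rows, columns=["regulator_id", "regulator_kind", "target_id", "target_kind"]
    )
    node_kinds = {n: kinds[n] for n in pd.unique(pd.concat([edges["regulator_id"],
                                                            edges["target_id"]]))}
    grn = classify_edges(GRN(node_kinds=node_kinds, edges=edges))

    unit_df = pd.DataFrame(
        units, columns=["regulator_id", "target_id", "reg_class",
                        "rho_normal", "rho_tumor", "planted"]
    )
    unit_df["pair_key"] = [
        pair_key(a, b) for a, b in zip(unit_df["regulator_id"], unit_df["target_id"])
    ]
    unit_df["edge_key"] = np.where(
        unit_df["reg_class"].isin(["BiTT", "BiTM"]),
        unit_df["pair_key"],
        unit_df["regulator_id"] + ">" + unit_df["target_id"],
    )
    return grn, unit_df


def _tumor_shifts(spec: SimulationSpec, units: pd.DataFrame) -> dict[str, float]:
    loop = spec.planted_loop
    if loop is None:
        return {}
    shifts = {units.iloc[0]["regulator_id"]: loop.tf_shift_log2}
    module = units[(units["reg_class"] == "TFout") & units["planted"]]
    for g in module["target_id"]:
        shifts[g] = loop.target_shift_log2
    return shifts


def generate_expression(
    grn: GRN,
    spec: SimulationSpec,
    cohort: CohortSpec,
    units: pd.DataFrame,
    cohort_index: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """Expression matrices and sample sheet rows for one cohort.

    Returns ``(mrna_values, mirna_values, sheet_rows, conflicts)``.  Sample
    ids are shared between modalities for exactly
    ``round(overlap * n)`` samples per condition; each modality has the full
    per-condition count of columns.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 2, cohort_index])
    shifts = _tumor_shifts(spec, units)
    mrna_feats = sorted(n for n, k in grn.node_kinds.items() if k != "miRNA")
    mirna_feats = sorted(n for n, k in grn.node_kinds.items() if k == "miRNA")

    mrna_blocks, mirna_blocks, sheet_rows, conflicts = [], [], [], []
    for condition, n in (("normal", cohort.n_normal), ("tumor", cohort.n_tumor)):
        shared = round(cohort.mirna_sample_overlap_fraction * n)
        n_slots = 2 * n - shared
        slots = [f"{cohort.name}.{condition}.s{j:03d}" for j in range(n_slots)]
        rho_col = "rho_normal" if condition == "normal" else "rho_tumor"

        latent: dict[str, np.ndarray] = {}
        for row in units.itertuples(index=False):
            rho = getattr(row, rho_col)
            r_p = 2.0 * math.sin(math.pi * rho / 6.0)
            if row.regulator_id not in latent:
                latent[row.regulator_id] = rng.standard_normal(n_slots)
            if row.target_id in latent:
                conflicts.append(
                    {"cohort": cohort.name, "condition": condition,
                     "edge_key": row.edge_key, "reason": "target_already_generated"}
                )
                continue
            latent[row.target_id] = (
                r_p * latent[row.regulator_id]
                + math.sqrt(max(0.0, 1.0 - r_p**2)) * rng.standard_normal(n_slots)
            )
        for feat in mrna_feats + mirna_feats:
            if feat not in latent:
                latent[feat] = rng.standard_normal(n_slots)
        if condition == "tumor":
            for feat, shift in shifts.items():
                if feat in latent:
                    latent[feat] = latent[feat] + shift * LN2

        mrna_vals = np.exp(spec.log_mean + np.vstack([latent[f] for f in mrna_feats]))
        mirna_vals = np.exp(spec.log_mean + np.vstack([latent[f] for f in mirna_feats]))
        mrna_idx = np.arange(n)
        mirna_idx = np.concatenate([np.arange(shared), np.arange(n, n_slots)])
        mrna_blocks.append(
            pd.DataFrame(mrna_vals[:, mrna_idx], index=mrna_feats,
                         columns=[slots[i] for i in mrna_idx])
        )
        mirna_blocks.append(
            pd.DataFrame(mirna_vals[:, mirna_idx], index=mirna_feats,
                         columns=[slots[i] for i in mirna_idx])
        )
        sheet_rows += [
            {"sample_id": s, "patient_id": s, "condition": condition, "cohort": cohort.name}
            for s in slots
        ]
    mrna = pd.concat(mrna_blocks, axis=1)
    mirna = pd.concat(mirna_blocks, axis=1)
    sheet = pd.DataFrame(sheet_rows)
    return mrna, mirna, sheet, conflicts


def generate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate the network and all cohorts' expression data with truth."""
    grn, units = generate_grn(spec)
    mrna_parts, mirna_parts, sheets, conflicts = [], [], [], []
    for i, cohort in enumerate(spec.cohorts):
        m, mi, sh, cf = generate_expression(grn, spec, cohort, units, cohort_index=i)
        mrna_parts.append(m)
        mirna_parts.append(mi)
        sheets.append(sh)
        conflicts += cf
    planted = units[units["planted"] & (units["reg_class"] == "BiTM")]
    truth = {
        "units": units,
        "tumor_shifts_log2": _tumor_shifts(spec, units),
        "planted_pair_key": planted["pair_key"].iloc[0] if len(planted) else None,
        "module_genes": sorted(
            units.loc[(units["reg_class"] == "TFout") & units["planted"], "target_id"]
        ),
        "conflicts": conflicts,
    }
    return SimulatedDataset(
        spec=spec,
        grn=grn,
        mrna=ExpressionMatrix("mRNA", pd.concat(mrna_parts, axis=1)),
        mirna=ExpressionMatrix("miRNA", pd.concat(mirna_parts, axis=1)),
        sheet=pd.concat(sheets, ignore_index=True),
        truth=truth,
    )


def generate_annotations(
    grn: GRN,
    spec: SimulationSpec,
    truth: dict | None = None,
    force_pairs: pd.DataFrame | None = None,
) -> Annotations:
    """Cancer labels, gene-set collection, and drug fixtures with truth.

    Each node is labeled cancer-associated with probability
    ``spec.cancer_fraction``; the planted loop endpoints are forced to be
    labeled when ``spec.force_planted_labels`` is set, as are the endpoints
    of any *force_pairs* rows (columns ``regulator_id``/``target_id``).  The
    gene-set collection contains one set enriched for the planted module
    genes plus random decoys.  The drug fixture covers up, down, neutral,
    boundary (t = 2c, amplitude exactly 2/3) and undefined (t = c = 0)
    signatures, and the interaction list contains one exact duplicate.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 3])
    genes_like = sorted(n for n, k in grn.node_kinds.items() if k != "miRNA")
    mirnas = sorted(n for n, k in grn.node_kinds.items() if k == "miRNA")
    cancer_genes = {g for g in genes_like if rng.random() < spec.cancer_fraction}
    cancer_mirnas = {m for m in mirnas if rng.random() < spec.cancer_fraction}

    module_genes: list[str] = (truth or {}).get("module_genes", [])
    planted_pair = (truth or {}).get("planted_pair_key")
    if spec.force_planted_labels and planted_pair:
        a, b = planted_pair.split("|")
        for node in (a, b):
            (cancer_mirnas if grn.node_kinds[node] == "miRNA" else cancer_genes).add(node)
    if force_pairs is not None:
        for row in force_pairs.itertuples(index=False):
            for node in (row.regulator_id, row.target_id):
                (cancer_mirnas if grn.node_kinds[node] == "miRNA" else cancer_genes).add(node)

    plain_genes = sorted(n for n, k in grn.node_kinds.items() if k == "gene")
    gene_sets: dict[str, set[str]] = {}
    if module_genes:
        extras = [g for g in plain_genes if g not in module_genes][:3]
        gene_sets["planted_module"] = set(module_genes) | set(extras)
    for i in range(8):
        size = min(12, len(plain_genes))
        gene_sets[f"decoy_set_{i:02d}"] = set(
            rng.choice(plain_genes, size=size, replace=False)
        )

    sig_rows = []
    expected = {"up": 0, "down": 0, "neutral": 0, "undefined": 0}
    for i in range(4):
        c = float(rng.uniform(0.5, 2.0))
        sig_rows.append((f"drug{len(sig_rows):02d}", c * (2.5 + i), c))
        expected["up"] += 1
    for i in range(4):
        c = float(rng.uniform(0.5, 2.0))
        sig_rows.append((f"drug{len(sig_rows):02d}", c, c * (2.5 + i)))
        expected["down"] += 1
    c = float(rng.uniform(0.5, 2.0))
    sig_rows.append((f"drug{len(sig_rows):02d}", 2 * c, c))  # a = 2/3, strict cutoff
    sig_rows.append((f"drug{len(sig_rows):02d}", c, c))
    sig_rows.append((f"drug{len(sig_rows):02d}", 1.1 * c, c))
    expected["neutral"] += 3
    sig_rows.append((f"drug{len(sig_rows):02d}", 0.0, 0.0))
    expected["undefined"] += 1
    signatures = pd.DataFrame(sig_rows, columns=["drug_id", "t", "c"])

    inter_rows = []
    for drug_id, _, _ in sig_rows:
        k = int(rng.integers(1, 4))
        for g in rng.choice(plain_genes, size=k, replace=False):
            inter_rows.append((drug_id, g, "synthetic"))
    inter_rows.append(inter_rows[0])  # planted duplicate pair
    interactions = pd.DataFrame(inter_rows, columns=["drug_id", "gene_id", "source"])

    active = [r for r in sig_rows[:8]]  # up + down drugs enter the subnetwork
    active_ids = {d for d, _, _ in active}
    sub_edges = {
        (d, g) for d, g, _ in inter_rows if d in active_ids
    }
    target_annotation = {g: "validated" for g in module_genes}
    for g in plain_genes[len(module_genes): len(module_genes) + 5]:
        target_annotation[g] = "predicted"
    drug_annotation = {
        d: f"ATC-{chr(ord('A') + i % 5)}" for i, (d, _, _) in enumerate(sig_rows)
    }
    ann_truth = {
        "expected_signature_classes": expected,
        "expected_subnetwork_drugs": sorted(active_ids & {d for d, _ in sub_edges}),
        "expected_subnetwork_edges": sorted(sub_edges),
        "cancer_fraction": spec.cancer_fraction,
    }
    return Annotations(
        cancer_genes=cancer_genes,
        cancer_mirnas=cancer_mirnas,
        gene_sets=gene_sets,
        drug_signatures=signatures,
        drug_interactions=interactions,
        target_annotation=target_annotation,
        drug_annotation=drug_annotation,
        truth=ann_truth,
    )
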