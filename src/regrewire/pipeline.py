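"""End-to-end orchestration: simulate/load -> correlate -> rewire -> rank -> enrich -> drugnet.

``run_pipeline`` executes the full analysis for one study (simulated or
file-based), writing deterministic TSV/GraphML outputs plus a JSON manifest
recording parameters, per-stage counts and SHA-256 digests of every output
file.  Given fixed inputs and seed, every output file is reproducible
byte-for-byte (all randomness flows from the single config seed through
named substreams; tables are explicitly sorted and floats formatted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    Z_THRESHOLD,
    score_network,
    significant_edges,
    sign_activity,
    top_percent,
)
from .drugnet import AMPLITUDE_CUTOFF, build_subnetwork, classify_signatures, export_subnetwork
from .enrichment import (
    DE_ALPHA,
    cancer_assoc_enrichment,
    de_test,
    fisher_combined,
    geneset_enrichment,
    read_gmt,
    regulator_module,
)
from .expression import load_expression, load_sample_sheet, samples_for
from .grn import classify_edges, load_grn
from .rewiring import (
    DC_FRACTION,
    classify_rewiring,
    compare_overlap_across_cohorts,
    dc_select,
    dz,
    overlap_stats,
    rank_bitm_across_cohorts,
)
from .simulate import SimulationSpec, default_spec, generate_annotations, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

FLOAT_FMT = "%.8g"


@dataclass
class RunConfig:
    """Parameters and input locations of one pipeline run."""

    outdir: Path
    seed: int = 0
    simulate: bool = True
    sim_spec: SimulationSpec | None = None
    # file-based inputs (used when simulate=False)
    grn_path: Path | None = None
    node_kinds_path: Path | None = None
    mrna_path: Path | None = None
    mirna_path: Path | None = None
    sheet_path: Path | None = None
    cancer_genes_path: Path | None = None
    cancer_mirnas_path: Path | None = None
    gmt_path: Path | None = None
    signatures_path: Path | None = None
    interactions_path: Path | None = None
    # analysis parameters
    z_thresh: float = Z_THRESHOLD
    top_ks: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    dc_fraction: float = DC_FRACTION
    amplitude_cutoff: float = AMPLITUDE_CUTOFF
    de_alpha: float = DE_ALPHA
    module_regulator: str | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (0 < self.dc_fraction <= 1):
            raise ValueError("dc_fraction must be in (0, 1]")
        for k in self.top_ks:
            if not (0 < k <= 1):
                raise ValueError("top-k fractions must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if outdir is not None:
            raw["outdir"] = outdir
        if "top_ks" in raw:
            raw["top_ks"] = tuple(raw["top_ks"])
        return cls(**raw)


def _read_id_list(path: Path | None) -> set[str]:
    if path is None:
        return set()
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a result bundle and writes all outputs.

    The bundle maps stage names to in-memory results; all tables are also
    written under ``config.outdir`` along with ``manifest.json``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages: list[str] = []
    results: dict = {}

    def stage(name: str):
        stages.append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("inputs")
        if config.simulate:
            spec = replace(config.sim_spec or default_spec(), seed=config.seed)
            dataset = generate_dataset(spec)
            grn = dataset.grn
            mrna, mirna, sheet = dataset.mrna, dataset.mirna, dataset.sheet
            ann = generate_annotations(grn, spec, dataset.truth)
            cancer_genes, cancer_mirnas = ann.cancer_genes, ann.cancer_mirnas
            gene_sets = ann.gene_sets
            signatures, interactions = ann.drug_signatures, ann.drug_interactions
            target_annotation, drug_annotation = ann.target_annotation, ann.drug_annotation
            results["truth"] = dataset.truth
        else:
            grn = classify_edges(load_grn(config.grn_path, config.node_kinds_path))
            mrna = load_expression(config.mrna_path, "mRNA")
            mirna = load_expression(config.mirna_path, "miRNA")
            sheet = load_sample_sheet(config.sheet_path)
            cancer_genes = _read_id_list(config.cancer_genes_path)
            cancer_mirnas = _read_id_list(config.cancer_mirnas_path)
            gene_sets = read_gmt(config.gmt_path) if config.gmt_path else {}
            signatures = (
                pd.read_csv(config.signatures_path, sep="\t")
                if config.signatures_path else None
            )
            interactions = (
                pd.read_csv(config.interactions_path, sep="\t")
                if config.interactions_path else None
            )
            target_annotation, drug_annotation = {}, {}
        cohorts = sorted(sheet["cohort"].unique())
        results["grn"] = grn
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise StageError("inputs", exc) from exc

    scored: dict[tuple[str, str], pd.DataFrame] = {}
    dc_by_cohort: dict[str, pd.DataFrame] = {}
    overlap_rows, rewiring_frames, sign_frames, assoc_rows, cat_frames = [], [], [], [], []
    try:
        stage("correlate")
        for cohort in cohorts:
            for condition in ("normal", "tumor"):
                recs, skips = score_network(grn, mrna, mirna, sheet, cohort, condition)
                scored[(cohort, condition)] = recs
                written.append(_write(recs, out / f"scored_{cohort}_{condition}.tsv"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("correlate", exc) from exc

    try:
        stage("rewire")
        for cohort in cohorts:
            recs_n, recs_t = scored[(cohort, "normal")], scored[(cohort, "tumor")]
            for k in config.top_ks:
                net_n = top_percent(recs_n, k, condition="normal")
                net_t = top_percent(recs_t, k, condition="tumor")
                ov = overlap_stats(net_n, net_t)
                overlap_rows.append(
                    {"cohort": cohort, "k": k, **dataclasses.asdict(ov)}
                )
                rw = classify_rewiring(net_n, net_t)
                rw.insert(0, "cohort", cohort)
                rw.insert(1, "k", k)
                rewiring_frames.append(rw)
            top10_t = top_percent(recs_t, 0.10, condition="tumor")
            full_t = top_percent(recs_t, 1.0, condition="tumor")
            sa = sign_activity(top10_t, full_t)
            sa.insert(0, "cohort", cohort)
            sign_frames.append(sa)
        overlap_df = pd.DataFrame(overlap_rows)
        written.append(_write(overlap_df, out / "overlap.tsv"))
        written.append(_write(pd.concat(rewiring_frames, ignore_index=True),
                              out / "rewiring.tsv"))
        written.append(_write(pd.concat(sign_frames, ignore_index=True),
                              out / "sign_activity.tsv"))
        pvals = [
            {
                "k": k,
                "p_ranksum": compare_overlap_across_cohorts(
                    overlap_df.loc[overlap_df["k"] == k, "jaccard_interactors"].to_numpy(),
                    overlap_df.loc[overlap_df["k"] == k, "jaccard_interactions"].to_numpy(),
                ),
            }
            for k in config.top_ks
        ]
        written.append(_write(pd.DataFrame(pvals), out / "overlap_tests.tsv"))
        results["overlap"] = overlap_df
    except Exception as exc:
        raise StageError("rewire", exc) from exc

    try:
        stage("dc-rank")
        for cohort in cohorts:
            records, omitted = dz(
                scored[(cohort, "normal")], scored[(cohort, "tumor")], config.z_thresh
            )
            flagged = dc_select(records, config.dc_fraction)
            dc_by_cohort[cohort] = flagged
            written.append(_write(flagged, out / f"dc_{cohort}.tsv"))
        ranking, partial = rank_bitm_across_cohorts(dc_by_cohort)
        written.append(_write(ranking, out / "bitm_ranking.tsv"))
        written.append(_write(partial, out / "bitm_partial.tsv"))
        results["bitm_ranking"] = ranking
        results["dc"] = dc_by_cohort
    except Exception as exc:
        raise StageError("dc-rank", exc) from exc

    try:
        stage("enrich")
        for cohort in cohorts:
            flagged = dc_by_cohort[cohort]
            res = cancer_assoc_enrichment(
                flagged[flagged["dc_flag"]], flagged, cancer_genes, cancer_mirnas
            )
            assoc_rows.append({"cohort": cohort, **res["overall"]})
            cats = res["bitm_categories"]
            cats.insert(0, "cohort", cohort)
            cat_frames.append(cats)
        written.append(_write(pd.DataFrame(assoc_rows), out / "cancer_assoc.tsv"))
        written.append(_write(pd.concat(cat_frames, ignore_index=True),
                              out / "cancer_assoc_categories.tsv"))
        results["cancer_assoc"] = pd.DataFrame(assoc_rows)

        regulator = config.module_regulator
        if regulator is None and len(results.get("bitm_ranking", [])):
            regulator = results["bitm_ranking"].iloc[0]["regulator_id"]
        if regulator is not None and gene_sets:
            universe = sorted(set(mrna.features))
            per_set: dict[str, list[float]] = {}
            module_rows = []
            for cohort in cohorts:
                recs_t = scored[(cohort, "tumor")]
                candidates = recs_t[recs_t["regulator_id"] == regulator]
                de_rows = []
                normal_ids = [
                    s for s in samples_for(sheet, cohort, "normal") if s in mrna.samples
                ]
                tumor_ids = [
                    s for s in samples_for(sheet, cohort, "tumor") if s in mrna.samples
                ]
                for gene in candidates["target_id"]:
                    if gene not in mrna.features:
                        continue
                    lfc, p = de_test(
                        mrna.values.loc[gene, normal_ids],
                        mrna.values.loc[gene, tumor_ids],
                    )
                    de_rows.append({"feature": gene, "log2fc": lfc, "p": p})
                de_df = pd.DataFrame(de_rows, columns=["feature", "log2fc", "p"])
                module = regulator_module(
                    regulator, recs_t, de_df, config.z_thresh, config.de_alpha
                )
                module_rows.append(
                    {"cohort": cohort, "n_module_genes": len(module),
                     "genes": ",".join(sorted(module))}
                )
                enr = geneset_enrichment(module & set(universe), gene_sets, universe)
                for row in enr.itertuples(index=False):
                    per_set.setdefault(row.set_id, []).append(row.p)
            combined = pd.DataFrame(
                [
                    {"set_id": sid, "n_cohorts": len(ps),
                     "combined_p": fisher_combined(ps)}
                    for sid, ps in sorted(per_set.items())
                ]
            ).sort_values(["combined_p", "set_id"], kind="mergesort").reset_index(drop=True)
            written.append(_write(pd.DataFrame(module_rows), out / "regulator_module.tsv"))
            written.append(_write(combined, out / "module_enrichment.tsv"))
            results["module_enrichment"] = combined
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    try:
        stage("drugnet")
        if signatures is not None and interactions is not None:
            classed = classify_signatures(signatures, cutoff=config.amplitude_cutoff)
            written.append(_write(classed, out / "drug_signatures.tsv"))
            graph = build_subnetwork(
                classed, interactions, target_annotation, drug_annotation
            )
            written.append(export_subnetwork(graph, out / "drug_subnetwork.graphml"))
            written.append(export_subnetwork(graph, out / "drug_subnetwork.sif", fmt="sif"))
            results["drug_subnetwork"] = graph
    except Exception as exc:
        raise StageError("drugnet", exc) from exc

    stage("manifest")
    manifest = {
        "package": "regrewire",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "z_thresh": config.z_thresh,
            "top_ks": list(config.top_ks),
            "dc_fraction": config.dc_fraction,
            "amplitude_cutoff": config.amplitude_cutoff,
            "de_alpha": config.de_alpha,
        },
        "simulated": config.simulate,
        "cohorts": cohorts,
        "stages_completed": stages,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
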