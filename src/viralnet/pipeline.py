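"""End-to-end orchestration: merge → network → distances → core genes →
weights → modules → significance → hierarchy → gene classes → lifestyle.

All stochastic stages draw their seeds deterministically from a single
master seed, so a fixed configuration reproduces byte-identical outputs.
Every file written is listed in a JSON manifest together with the exact
configuration used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .coregenes import DistanceMatrix, classify_core, distance_matrix
from .genomes import GenomeSet, read_genome_table, write_genome_table
from .geneclass import betweenness_accounting, classify_genes
from .hierarchy import (
    CONNECTOR_THRESHOLD,
    detect_supermodules,
    identify_connectors,
)
from .lifestyle import lifestyle_association_table
from .modularity import (
    AnnealSchedule,
    detect_modules,
    partition_significance,
    robustness_matrices,
)
from .network import (
    BipartiteNetwork,
    build_bipartite_network,
    merge_redundant_genomes,
    restrict_to_core,
    write_network,
)
from .weights import abundance_table, genome_weights

logger = logging.getLogger("viralnet")

STAGES = (
    "merge",
    "network",
    "core",
    "weights",
    "modules",
    "significance",
    "hierarchy",
    "classify",
    "lifestyle",
)


@dataclass
class PipelineConfig:
    """Thresholds, replicate counts and stage toggles for a full run."""

    merge_threshold: float = 0.9
    core_rate_threshold: float = 1.0
    core_min_appearances: int = 3
    max_pair_distance: float = 1.0
    connector_threshold: float = CONNECTOR_THRESHOLD
    hallmark_prevalence: float = 0.35
    signature_best: float = 0.6
    signature_second: float = 0.02
    merge_vote_threshold: float = 0.5
    lifestyle_min_coverage: float = 0.10
    n_replicates: int = 100
    n_null: int = 100
    n_replicates_per_null: int = 5
    seed: int = 0
    giant_only: bool = True
    restrict_core: bool = True
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    skip_stages: tuple[str, ...] = ()
    lifestyle_background: tuple[int, int] | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def summary_table(
    network: BipartiteNetwork,
    abundance: pd.Series | None = None,
    n_modules: int | None = None,
) -> dict:
    """Network-level summary: node/edge counts, edge density, mean degrees."""
    n_g = len(network.genomes)
    n_f = len(network.families)
    n_e = network.n_edges
    out = {
        "genomes": n_g,
        "families": n_f,
        "edges": n_e,
        "edge_density": edge_density(n_g, n_f, n_e),
        "mean_families_per_genome": n_e / n_g if n_g else math.nan,
    }
    if abundance is not None:
        present = abundance.reindex(network.families).dropna()
        out["mean_family_abundance"] = float(present.mean())
    if n_modules is not None:
        out["modules"] = n_modules
    return out


def edge_density(n_genomes: int, n_families: int, n_edges: int) -> float:
    """|edges| / (|genomes| * |families|)."""
    if n_genomes <= 0 or n_families <= 0:
        raise ValueError("counts must be positive")
    return n_edges / (n_genomes * n_families)


@dataclass
class PipelineResult:
    genomes: GenomeSet
    network: BipartiteNetwork
    core_network: BipartiteNetwork | None
    distances: DistanceMatrix
    core_table: pd.DataFrame
    weights: pd.Series
    ensemble: object
    p_value: float | None
    hierarchy: object
    connectors: object
    gene_classes: pd.DataFrame
    betweenness: dict
    lifestyle: pd.DataFrame | None
    summary: dict
    manifest: dict


def run_pipeline(
    genomes: GenomeSet,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute every enabled stage on ``genomes`` and return all artefacts.

    When ``outdir`` is given, standard-format outputs (TSV, GraphML,
    newick) are written and listed in ``manifest.json``.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(cfg), "files": {}, "stages": {}}

    def _stage(name: str) -> bool:
        return name not in cfg.skip_stages

    def _record(stage: str, filename: str) -> Path:
        manifest["files"][filename] = stage
        return out / filename

    t_start = time.time()

    # --- merge redundant genomes into pangenomes -------------------------
    if _stage("merge"):
        merged = merge_redundant_genomes(genomes, cfg.merge_threshold)
        logger.info("merge: %d genomes -> %d pangenomes", genomes.n_genomes, merged.n_genomes)
    else:
        merged = genomes
    manifest["stages"]["merge"] = {"pangenomes": merged.n_genomes}
    if out is not None:
        write_genome_table(
            merged, _record("merge", "pangenomes.tsv"), _record("merge", "pangenome_metadata.tsv")
        )

    # --- full bipartite network ------------------------------------------
    network = build_bipartite_network(merged, giant_only=cfg.giant_only)
    manifest["stages"]["network"] = {
        "genomes": len(network.genomes),
        "families": len(network.families),
        "edges": network.n_edges,
        "dropped": len(network.dropped_nodes),
    }
    if out is not None:
        write_network(network, _record("network", "network_edges.tsv"),
                      _record("network", "network.graphml"))

    # --- distances, weights, abundance -----------------------------------
    net_genomes = GenomeSet(
        {g: dict(merged.memberships[g]) for g in network.genomes},
        taxon=merged.taxon,
        lifestyle=merged.lifestyle,
        members=merged.members,
    )
    distances = distance_matrix(net_genomes)
    weights = genome_weights(distances)
    abundance = abundance_table(net_genomes, weights)
    if out is not None:
        distances.to_frame().to_csv(_record("weights", "distances.tsv"), sep="\t")
        weights.rename("weight").to_csv(_record("weights", "genome_weights.tsv"), sep="\t")
        abundance.rename("abundance").to_csv(_record("weights", "family_abundance.tsv"), sep="\t")

    # --- core genes -------------------------------------------------------
    core_network = None
    if _stage("core"):
        core_table = classify_core(
            net_genomes,
            distances,
            max_distance=cfg.max_pair_distance,
            core_rate_threshold=cfg.core_rate_threshold,
            min_appearances=cfg.core_min_appearances,
        )
        core_fams = set(core_table.loc[core_table["core"], "family_id"])
        manifest["stages"]["core"] = {
            "families": int(len(core_table)),
            "core_families": int(len(core_fams)),
        }
        if core_fams:
            core_network = restrict_to_core(network, core_fams)
        if out is not None:
            export = core_table.assign(
                abundance=core_table["family_id"].map(abundance)
            ).sort_values("abundance", ascending=False)
            export.to_csv(_record("core", "core_genes.tsv"), sep="\t", index=False)
    else:
        core_table = pd.DataFrame()
        manifest["stages"]["core"] = {"skipped": True}

    analysis_net = core_network if core_network is not None else network
    analysis_genomes = GenomeSet(
        {g: dict(net_genomes.memberships[g]) for g in analysis_net.genomes},
        taxon=net_genomes.taxon,
        lifestyle=net_genomes.lifestyle,
        members=net_genomes.members,
    )
    analysis_weights = weights.reindex(analysis_net.genomes)
    analysis_weights = analysis_weights / analysis_weights.sum()

    # --- module detection -------------------------------------------------
    ensemble = detect_modules(
        analysis_net, cfg.n_replicates, seed=cfg.stage_seed("modules"),
        schedule=cfg.schedule,
    )
    best = ensemble.best
    robustness, cross = robustness_matrices(ensemble)
    manifest["stages"]["modules"] = {
        "n_modules": best.n_modules,
        "best_q": best.q,
    }
    if out is not None:
        part_rows = [
            (n, "genome" if n in set(analysis_net.genomes) else "family", m)
            for n, m in best.labels.items()
        ]
        pd.DataFrame(part_rows, columns=["node_id", "node_class", "module"]).to_csv(
            _record("modules", "partition.tsv"), sep="\t", index=False
        )
        robustness.to_csv(_record("modules", "module_robustness.tsv"), sep="\t", index=False)
        cross.to_csv(_record("modules", "module_cross_similarity.tsv"), sep="\t")

    # --- significance ------------------------------------------------------
    p_value = None
    if _stage("significance") and cfg.n_null > 0:
        try:
            p_value = partition_significance(
                analysis_net,
                best.q,
                n_null=cfg.n_null,
                seed=cfg.stage_seed("significance"),
                n_replicates_per_null=cfg.n_replicates_per_null,
                schedule=cfg.schedule,
            )
        except ValueError:
            p_value = None
    manifest["stages"]["significance"] = {"p_value": p_value}

    # --- hierarchy ----------------------------------------------------------
    modules_map = {
        str(m): g for m, g in best.genome_modules(analysis_net).items()
    }
    connectors = identify_connectors(
        modules_map, analysis_genomes, analysis_weights, cfg.connector_threshold
    )
    hierarchy = None
    if _stage("hierarchy"):
        hierarchy = detect_supermodules(
            modules_map,
            analysis_genomes,
            analysis_weights,
            seed=cfg.stage_seed("hierarchy"),
            n_replicates=cfg.n_replicates,
            n_null=cfg.n_null,
            n_replicates_per_null=cfg.n_replicates_per_null,
            merge_threshold=cfg.merge_vote_threshold,
            connector_threshold=cfg.connector_threshold,
            schedule=cfg.schedule,
        )
        manifest["stages"]["hierarchy"] = {
            "iterations": hierarchy.iterations,
            "supermodules": len(hierarchy.roots),
            "stop_reason": hierarchy.stop_reason,
        }
        if out is not None:
            _record("hierarchy", "hierarchy.nwk").write_text(hierarchy.to_newick() + "\n")
            hierarchy.near_merges.to_csv(
                _record("hierarchy", "near_merges.tsv"), sep="\t", index=False
            )

    # --- gene classification ------------------------------------------------
    supermods = hierarchy.supermodules() if hierarchy is not None else {}
    gene_classes = classify_genes(
        connectors,
        supermods,
        modules_map,
        analysis_genomes,
        analysis_weights,
        prevalence_threshold=cfg.hallmark_prevalence,
        best_threshold=cfg.signature_best,
        second_threshold=cfg.signature_second,
    )
    betweenness = betweenness_accounting(analysis_net, gene_classes)
    manifest["stages"]["classify"] = {
        "hallmark": int(gene_classes["hallmark"].sum()),
        "connector": int(gene_classes["connector"].sum()),
        "signature": int(gene_classes["signature"].sum()),
    }
    if out is not None:
        gene_classes.to_csv(_record("classify", "gene_classes.tsv"), sep="\t", index=False)
        betweenness["top_table"].to_csv(
            _record("classify", "top_betweenness.tsv"), sep="\t", index=False
        )

    # --- lifestyle -----------------------------------------------------------
    lifestyle = None
    if _stage("lifestyle"):
        lifestyle = lifestyle_association_table(
            modules_map,
            analysis_genomes,
            background=cfg.lifestyle_background,
            min_coverage=cfg.lifestyle_min_coverage,
        )
        if out is not None:
            lifestyle.to_csv(_record("lifestyle", "lifestyle_tests.tsv"), sep="\t", index=False)

    # --- summary ---------------------------------------------------------------
    summary = {
        "full": summary_table(network, abundance),
        "core": summary_table(analysis_net, abundance, n_modules=best.n_modules)
        if core_network is not None
        else None,
    }
    # manifests must be byte-identical across reruns: no timing inside
    manifest["summary"] = summary
    summary = dict(summary, runtime_s=time.time() - t_start)
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))

    return PipelineResult(
        genomes=merged,
        network=network,
        core_network=core_network,
        distances=distances,
        core_table=core_table,
        weights=weights,
        ensemble=ensemble,
        p_value=p_value,
        hierarchy=hierarchy,
        connectors=connectors,
        gene_classes=gene_classes,
        betweenness=betweenness,
        lifestyle=lifestyle,
        summary=summary,
        manifest=manifest,
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["config_hash"] = hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return d


def load_and_run(
    table_path, metadata_path=None, config: PipelineConfig | None = None, outdir=None
) -> PipelineResult:
    genomes = read_genome_table(table_path, metadata_path)
    return run_pipeline(genomes, config, outdir)
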