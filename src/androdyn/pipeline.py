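"""End-to-end pipeline driver: chains the stages and writes every
intermediate table plus a run manifest (seed, config hash, completed stages).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from . import concepts as concepts_mod
from . import enrichment as enrich_mod
from . import markers as markers_mod
from . import network as net_mod
from .config import Config
from .fcm import FuzzyCMeans, select_k_elbow
from .io import (AnnotationTable, GeneSetCollection, RatioTable,
                 write_network)
from .markers import ExpressionDataset
from .preprocess import (compute_ratios, filter_quantified, pca_qc,
                         standardize_profiles)

log = logging.getLogger("androdyn")

STAGES = ("preprocess", "cluster", "enrich", "network", "cascades",
          "concepts", "markers", "report")


@dataclass
class PipelineInputs:
    ratio_table: RatioTable
    annotations: AnnotationTable | None = None
    ppi: nx.Graph | None = None
    concepts: GeneSetCollection | None = None
    marker_datasets: list[ExpressionDataset] | None = None
    paired_dataset: ExpressionDataset | None = None


def run_pipeline(config: Config, inputs: PipelineInputs,
                 outdir: str | Path) -> dict:
    """Execute the stages in order, writing intermediates under ``outdir``.

    Stages without their optional input (e.g. no PPI network) still complete
    by emitting an empty artifact, so the manifest always lists the full
    stage sequence.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {}

    # -- preprocess --------------------------------------------------------
    table = filter_quantified(inputs.ratio_table,
                              config.min_unique_peptides,
                              config.require_all_replicates)
    qc = pca_qc(table)
    if len(qc.coordinates):
        qc.coordinates.to_csv(outdir / "qc_pca.tsv", sep="\t")
    ratios = compute_ratios(table)
    profiles = standardize_profiles(ratios,
                                    median_center=config.median_center,
                                    average=config.replicate_average,
                                    ddof=config.zscore_ddof)
    profiles.to_tsv(outdir / "profiles.tsv")
    summary["n_quantified"] = len(table)
    summary["n_profiles"] = profiles.n_proteins
    summary["qc_silhouette"] = qc.silhouette
    completed.append("preprocess")

    # -- cluster -----------------------------------------------------------
    model = FuzzyCMeans(profiles)
    lo, hi = config.k_range
    k_star, diag = select_k_elbow(model, k_range=range(lo, hi + 1),
                                  m=config.fuzzifier, seed=config.seed,
                                  n_restarts=config.n_restarts,
                                  max_iter=config.max_iter, tol=config.tol)
    diag.to_csv(outdir / "objective_curve.tsv", sep="\t")
    result = model.fit(k=k_star, m=config.fuzzifier, seed=config.seed,
                       n_restarts=config.n_restarts,
                       max_iter=config.max_iter, tol=config.tol)
    result.membership_frame.to_csv(outdir / "membership.tsv", sep="\t")
    labels = result.label_archetypes() if k_star == 5 else None
    assignment = result.assign(threshold=config.membership_threshold,
                               labels=labels)
    assignment.to_tsv(outdir / "assignment.tsv")
    (outdir / "fcm_summary.txt").write_text(result.summary() + "\n")
    summary["k"] = k_star
    summary["m"] = result.params.m
    summary["n_labeled"] = len(assignment.retained)
    summary["n_excluded"] = len(assignment.excluded)
    completed.append("cluster")

    # -- enrich ------------------------------------------------------------
    if inputs.annotations is not None:
        for kind, alpha in (("compartment", config.alpha_compartment),
                            ("molecular_type", config.alpha_type)):
            enr = enrich_mod.hypergeom_enrich(assignment, inputs.annotations,
                                              kind=kind, alpha=alpha)
            enr.to_csv(outdir / f"enrichment_{kind}.tsv", sep="\t",
                       index=False)
            pct = enrich_mod.composition_profile(assignment,
                                                 inputs.annotations, kind)
            pct.to_csv(outdir / f"composition_{kind}.tsv", sep="\t")
            summary[f"n_enriched_{kind}"] = int(enr["significant"].sum())
    completed.append("enrich")

    # -- network -----------------------------------------------------------
    restricted = None
    if inputs.ppi is not None:
        restricted = net_mod.restrict_network(inputs.ppi, assignment,
                                              inputs.annotations)
        write_network(restricted, outdir / "network.graphml")
        hubs = net_mod.hub_degrees(restricted, top_n=15, focus=("AR",))
        hubs.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        pair = net_mod.cluster_pair_stats(restricted, assignment,
                                          alpha=config.alpha_pair)
        pair.table.to_csv(outdir / "cluster_pairs.tsv", sep="\t", index=False)
        summary["flagged_pairs"] = ["/".join(p) for p in pair.flagged]
        if inputs.annotations is not None:
            tmap, tgraph = net_mod.type_interaction_map(
                restricted, inputs.annotations, assignment,
                fraction_threshold=config.type_edge_fraction,
                alpha=config.alpha_type_edge)
            tmap.to_csv(outdir / "type_map.tsv", sep="\t", index=False)
            nx.write_graphml(tgraph, outdir / "type_map.graphml")
    completed.append("network")

    # -- cascades ----------------------------------------------------------
    if restricted is not None and labels is not None:
        casc = net_mod.enumerate_cascades(
            restricted, assignment, inputs.annotations,
            require_terminal_type=(config.cascade_terminal_type
                                   if inputs.annotations is not None
                                   else None))
        casc.to_csv(outdir / "cascades.tsv", sep="\t", index=False)
        summary["cascades"] = net_mod.cascade_counts(casc)
        if inputs.annotations is not None:
            occupancy, placement, cgraph = net_mod.cascade_layout(
                casc, inputs.annotations, config.compartment_row_map)
            occupancy.to_csv(outdir / "cascade_regions.tsv", sep="\t")
            placement.to_csv(outdir / "cascade_placement.tsv", sep="\t",
                             index=False)
            nx.write_graphml(cgraph, outdir / "cascades.graphml")
    completed.append("cascades")

    # -- concepts ----------------------------------------------------------
    if inputs.concepts is not None:
        assoc = concepts_mod.fisher_associate(
            assignment, inputs.concepts,
            alpha=config.alpha_concept,
            odds_ratio_floor=config.odds_ratio_floor)
        assoc.to_csv(outdir / "concept_associations.tsv", sep="\t",
                     index=False)
        cmap = concepts_mod.build_concept_map(assoc, inputs.concepts,
                                              assignment)
        nx.write_graphml(cmap, outdir / "concept_map.graphml")
        summary["n_concept_links"] = int(assoc["retained"].sum())
    completed.append("concepts")

    # -- markers -----------------------------------------------------------
    if inputs.marker_datasets:
        de_tables = [markers_mod.dataset_de(
            markers_mod.normalize_dataset(ds, log_transform=False),
            alpha=config.alpha_marker, welch=config.welch)
            for ds in inputs.marker_datasets]
        marks, conflicts = markers_mod.consensus_markers(de_tables)
        marks.to_csv(outdir / "consensus_markers.tsv", sep="\t", index=False)
        conflicts.to_csv(outdir / "marker_conflicts.tsv", sep="\t",
                         index=False)
        long, counts = markers_mod.intersect_with_clusters(marks, assignment)
        long.to_csv(outdir / "markers_by_cluster.tsv", sep="\t", index=False)
        counts.to_csv(outdir / "marker_counts.tsv", sep="\t", index=False)
        summary["n_consensus_markers"] = len(marks)
        if inputs.paired_dataset is not None:
            pde, zmat = markers_mod.paired_de(
                inputs.paired_dataset, alpha=config.alpha_paired,
                method=config.paired_test)
            pde.to_csv(outdir / "paired_de.tsv", sep="\t")
            zmat.to_csv(outdir / "paired_zscores.tsv", sep="\t")
            summary["n_paired_de"] = int(pde["significant"].sum())
    completed.append("markers")

    # -- report ------------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": completed + ["report"],
        "summary": summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    with open(outdir / "report.txt", "w") as fh:
        fh.write("androdyn pipeline report\n")
        for key, val in summary.items():
            fh.write(f"{key}: {val}\n")
    completed.append("report")
    manifest["stages"] = completed
    return manifest
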