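"""End-to-end orchestration: raw inputs in, species partition and reports out.

Stages run in method order — orthology (hits -> gene clusters), distances
(gene trees -> average patristic matrix), trees (UPGMA core and pan trees),
congruence (RF vs the random-tree null), gain/loss mapping, exclusivity
annotation, species delimitation — and any stage whose inputs are absent is
skipped with a log message.  All stage outputs are plain text files so each
stage can also be run standalone from the command line.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

from . import clustering, delimitation, exclusivity, orthology, treemetrics
from .core import (
    AnalysisConfig,
    RunManifest,
    logger,
    read_distance_matrix,
    read_hit_table,
    read_newick,
    read_pair_similarity,
    read_presence_absence,
    write_newick,
)

__all__ = ["MissingInputError", "run_pipeline", "write_exclusivity_records"]


class MissingInputError(ValueError):
    """A requested stage lacks a required input; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def write_exclusivity_records(records, path: Path) -> None:
    lines = ["group\tmax_in\tmin_out\tscore"]
    for rec in records:
        lines.append(
            f"{';'.join(rec.group)}\t{rec.max_in:.10g}\t{rec.min_out:.10g}\t{rec.score:.10g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(
    out_dir: str | Path,
    cfg: AnalysisConfig | None = None,
    gene_trees: Sequence[str | Path] | None = None,
    dist: str | Path | None = None,
    pa: str | Path | None = None,
    pairs: str | Path | None = None,
    hits: str | Path | None = None,
    sequences: dict[str, str] | None = None,
    complete_genomes: Sequence[str] | None = None,
) -> RunManifest:
    """Run every stage whose inputs are available; returns the run manifest.

    Inputs: either a protein hit table (plus optional sequences) to build
    the presence/absence matrix, or a ready-made matrix; either gene tree
    files or a ready-made average distance matrix; and a pairwise ANI/AF
    table for delimitation.
    """
    cfg = cfg or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=cfg.seed, config=dataclasses.asdict(cfg))
    for p in [dist, pa, pairs, hits, *(gene_trees or [])]:
        if p is not None:
            manifest.add_input(p)

    # --- orthology -> presence/absence
    pa_matrix = None
    if hits is not None:
        hit_df = read_hit_table(hits)
        filtered = orthology.filter_hits(hit_df, cfg)
        graph = orthology.reciprocal_best_hits(filtered, cfg, sequences)
        clusters = orthology.mcl_cluster(graph, cfg.mcl_inflation)
        genomes = sorted(set(hit_df["qgenome"]) | set(hit_df["sgenome"]))
        pa_matrix, single_copy = orthology.assemble_matrix(clusters, genomes)
        if complete_genomes:
            pa_matrix, comp = orthology.completeness_filter(
                pa_matrix, complete_genomes, cfg.core_fraction_min
            )
            logger.info(
                "completeness filter: reference core %d, dropped %d genome(s)",
                comp.reference_core_size,
                len(comp.dropped),
            )
        (out / "cogs.tsv").write_text(clusters.to_tsv())
        pa_matrix.write_tsv(out / "pa_cogs.tsv")
        manifest.outputs["cogs"] = str(out / "cogs.tsv")
        logger.info("orthology: %d clusters, single-copy fraction %.3f", len(clusters.members), single_copy)
    elif pa is not None:
        pa_matrix = read_presence_absence(pa)
    else:
        logger.info("skipping orthology/pan-genome stages: no hits or matrix given")

    # --- average patristic distances
    avg = None
    if dist is not None:
        avg = read_distance_matrix(dist)
    elif gene_trees:
        trees = [read_newick(p) for p in sorted(map(str, gene_trees))]
        avg = treemetrics.average_matrices(
            [treemetrics.patristic_matrix(t) for t in trees]
        )
        avg.write_tsv(out / "avg_dist.tsv")
        manifest.outputs["distances"] = str(out / "avg_dist.tsv")
    else:
        logger.info("skipping distance stage: no gene trees or matrix given")

    core_tree = None
    if avg is not None:
        core_tree, _ = clustering.upgma(avg)
        write_newick(core_tree, out / "core_upgma.nwk")
        manifest.outputs["coretree"] = str(out / "core_upgma.nwk")

    pan_tree = None
    if pa_matrix is not None:
        partition = orthology.core_pan_partition(pa_matrix)
        pan_matrix = pa_matrix.subset_clusters(list(partition.pan))
        pan_tree, _ = clustering.upgma(clustering.jaccard_matrix(pan_matrix))
        write_newick(pan_tree, out / "pan_upgma.nwk")
        manifest.outputs["pantree"] = str(out / "pan_upgma.nwk")
        logger.info(
            "gene clusters: %d core, %d pan, %d genome-unique",
            len(partition.core),
            len(partition.pan),
            len(partition.genome_unique),
        )

    # --- congruence of core and pan trees
    if core_tree is not None and pan_tree is not None:
        rf = treemetrics.robinson_foulds(core_tree, pan_tree)
        n = len(avg.labels)
        null = treemetrics.random_rf_null(n)
        lines = [
            "rf\tmax_rf\texpected_rf\tlog10_p_le",
            f"{rf}\t{null.max_rf}\t{null.expected_rf:.6g}\t{null.log10_p_le(rf):.6g}",
        ]
        (out / "congruence.tsv").write_text("\n".join(lines) + "\n")
        manifest.outputs["congruence"] = str(out / "congruence.tsv")

    # --- gain/loss mapping of the pan-genome on the core tree
    if core_tree is not None and pa_matrix is not None:
        summary = treemetrics.map_pan_genome(core_tree, pa_matrix)
        payload = {
            "total_changes": summary.total,
            "gains": summary.gains,
            "losses": summary.losses,
            "branch_count": summary.branch_count,
            "gains_per_branch": summary.gains_per_branch,
            "losses_per_branch": summary.losses_per_branch,
        }
        (out / "gainloss.json").write_text(json.dumps(payload, indent=2) + "\n")
        manifest.outputs["gainloss"] = str(out / "gainloss.json")

    # --- exclusivity of pan-tree clades under the average distances
    if avg is not None and pan_tree is not None:
        pan_tree, summary = exclusivity.annotate_tree(
            pan_tree, avg, cfg.exclusivity_slack
        )
        records = [rec for _, rec in exclusivity.score_clades(pan_tree, avg)]
        write_exclusivity_records(records, out / "exclusivity.tsv")
        write_newick(pan_tree, out / "pan_upgma_annotated.nwk")
        manifest.outputs["exclusivity"] = str(out / "exclusivity.tsv")
        logger.info(
            "exclusivity: %d/%d internal edges exclusive (%.1f%%)",
            summary.exclusive_edges,
            summary.internal_edges,
            100 * summary.fraction_exclusive,
        )

    # --- species delimitation
    if avg is not None and pairs is not None:
        table = read_pair_similarity(pairs, cfg.ani_symmetrize)
        part = delimitation.delimit_species(avg, table, cfg, tree=core_tree)
        (out / "species.tsv").write_text(part.to_tsv())
        summary = delimitation.summarize_partition(part)
        report = delimitation.split_report(part, table, cfg)
        payload = {
            "species_count": summary.species_count,
            "singleton_count": summary.singleton_count,
            "largest_species": summary.largest_species,
            "mean_genomes_per_species": summary.mean_genomes_per_species,
            "threshold_meeting_pairs": report.meeting_pairs,
            "split_pairs": report.split_pairs,
            "split_ratio": report.ratio,
            "linkage": cfg.linkage,
        }
        (out / "species_summary.json").write_text(json.dumps(payload, indent=2) + "\n")
        manifest.outputs["delimitation"] = str(out / "species.tsv")
    elif pairs is not None:
        raise MissingInputError(
            "delimitation", "a distance matrix or gene trees are required"
        )
    else:
        logger.info("skipping delimitation: no pair similarity table given")

    manifest.write(out / "manifest.json")
    return manifest
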