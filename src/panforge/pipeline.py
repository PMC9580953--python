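"""End-to-end pipeline: cluster -> partition -> curves -> fits -> profiles.

Stages whose inputs are supplied precomputed (an orthogroups TSV, a
presence/absence matrix) are skipped and recorded as "imported" in the run
manifest.  The manifest captures the configuration hash, input file hashes,
seed and per-stage status, so identical configuration and inputs give
byte-identical output bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotations import (
    adhesin_crosstab,
    category_distribution,
    ppi_summary,
    presence_heatmap,
    read_annotation_table,
    read_localization_table,
    read_ppi_table,
)
from .curves import fit_exp_decay, fit_heaps, pan_core_curves, stabilization_summary
from .matrix import PresenceAbsenceMatrix
from .mcl import MCLParams, clusters_to_matrix, mcl_cluster, read_cluster_tsv, write_cluster_tsv
from .partition import (
    genome_summary_stats,
    partition,
    partition_percentages,
    read_genome_summary,
    write_partition_report,
)
from .similarity import compute_similarities, read_genome_fastas, read_similarity_table
from .simulate import SyntheticPanGenomeSpec, generate_presence_absence

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("cluster", "partition", "curves", "fit", "profile")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one source of gene families must be resolvable: a synthetic
    spec, a precomputed matrix TSV, an orthogroups TSV, a similarity table,
    or per-genome protein FASTA files.
    """

    output_dir: str = "panforge_out"
    seed: int = 0
    # gene-family sources (first available wins, in this order)
    simulate: dict | None = None
    matrix_tsv: str | None = None
    cluster_tsv: str | None = None
    similarity_tsv: str | None = None
    protein_fastas: list[str] = field(default_factory=list)
    # clustering parameters
    similarity_cutoff: float = 1e-5
    score_column: str = "neg_log_evalue"
    mcl: dict = field(default_factory=dict)
    # curve parameters
    n_permutations: int = 100
    aggregator: str = "median"
    # profile inputs (all optional)
    genome_summary_csv: str | None = None
    annotation_tsv: str | None = None
    localization_tsv: str | None = None
    ppi_tsv: str | None = None
    trait_genes: list[str] = field(default_factory=list)
    adhesin_threshold: float = 0.7
    ppi_min_score: float = 0.9765

    def __post_init__(self):
        if not (0 < self.adhesin_threshold < 1):
            raise ValueError("adhesin_threshold must be in (0, 1)")
        if not (0 < self.ppi_min_score <= 1):
            raise ValueError("ppi_min_score must be in (0, 1]")
        if self.similarity_cutoff <= 0:
            raise ValueError("similarity_cutoff must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def canonical(self) -> str:
        """Canonical YAML of the config, excluding the output location.

        This is what the manifest hash covers: two runs writing to different
        directories but otherwise identical are the same analysis.
        """
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        return yaml.safe_dump(d, sort_keys=True)


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fit_report_rows(name, heap=None, decay=None):
    if heap is not None:
        return [
            (name, "heap", f"{heap.k:.6f}", f"{heap.gamma:.6f}",
             f"{heap.alpha:.6f}", f"{heap.rss:.6g}", heap.openness),
        ]
    return [
        (name, "expdecay", f"{decay.k:.6f}", f"{decay.t:.6f}",
         f"{decay.tg_theta:.6f}", f"{decay.rss:.6g}",
         "identifiable" if decay.identifiable else "unidentifiable"),
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle under ``config.output_dir``.

    Returns a result dictionary with the in-memory objects (matrix,
    partition, profile, fits) and the manifest.
    """
    outdir = Path(config.output_dir)
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "panforge",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "inputs": {},
        "stages": {},
    }
    for attr in ("matrix_tsv", "cluster_tsv", "similarity_tsv",
                 "genome_summary_csv", "annotation_tsv", "localization_tsv",
                 "ppi_tsv"):
        val = getattr(config, attr)
        if val:
            manifest["inputs"][attr] = _sha256_file(val)
    for p in config.protein_fastas:
        manifest["inputs"][str(p)] = _sha256_file(p)

    results: dict = {}

    # ---- stage: cluster (or import/simulate the family matrix) ----
    truth = None
    if config.simulate is not None:
        spec = SyntheticPanGenomeSpec(seed=config.seed, **config.simulate)
        matrix, truth = generate_presence_absence(spec)
        truth.to_csv(tables / "truth_labels.tsv", sep="\t")
        manifest["stages"]["cluster"] = "skipped (synthetic matrix)"
    elif config.cluster_tsv:
        cluster_set = read_cluster_tsv(config.cluster_tsv)
        genomes = sorted(set(cluster_set.genome_map.values()))
        matrix = clusters_to_matrix(cluster_set, genomes)
        results["clusters"] = cluster_set
        manifest["stages"]["cluster"] = "imported"
    elif config.similarity_tsv or config.protein_fastas:
        params = MCLParams(**config.mcl)
        if config.similarity_tsv:
            graph = read_similarity_table(
                config.similarity_tsv,
                score_column=config.score_column,
                cutoff=config.similarity_cutoff,
            )
            genome_map = {pid: pid.split("|")[0] for pid in graph.graph.nodes}
        else:
            records = read_genome_fastas(config.protein_fastas)
            graph = compute_similarities(records)
            genome_map = {r.protein_id: r.genome_id for r in records}
        cluster_set = mcl_cluster(graph, params, genome_map=genome_map)
        genomes = sorted(set(genome_map.values()))
        matrix = clusters_to_matrix(cluster_set, genomes)
        write_cluster_tsv(cluster_set, genomes, tables / "orthogroups.tsv")
        results["clusters"] = cluster_set
        manifest["stages"]["cluster"] = "run"
    elif config.matrix_tsv:
        matrix = PresenceAbsenceMatrix.from_tsv(config.matrix_tsv)
        manifest["stages"]["cluster"] = "imported"
    else:
        raise ValueError(
            "no gene-family source configured: provide simulate, matrix_tsv, "
            "cluster_tsv, similarity_tsv, or protein_fastas"
        )
    matrix.to_tsv(tables / "presence_absence.tsv")
    results["matrix"] = matrix
    results["truth"] = truth

    # ---- stage: partition ----
    part = partition(matrix)
    write_partition_report(part, tables / "partition.tsv")
    pct = partition_percentages(part)
    venn = pd.DataFrame(
        {
            "subset": ["core", "accessory", "unique", "total"],
            "count": [part.n_core, part.n_accessory, part.n_unique, part.n_total],
            "percent": [pct["core"], pct["accessory"], pct["unique"], 100.0],
        }
    )
    venn.to_csv(tables / "venn_summary.tsv", sep="\t", index=False)
    per_genome = pd.Series(part.per_genome_unique, name="unique_count").sort_index()
    per_genome.rename_axis("genome").to_csv(tables / "unique_per_genome.tsv", sep="\t")
    results["partition"] = part
    manifest["stages"]["partition"] = "run"

    # ---- stage: curves ----
    profile = pan_core_curves(
        matrix,
        n_permutations=config.n_permutations,
        seed=config.seed,
        aggregator=config.aggregator,
    )
    profile.to_frame().to_csv(tables / "curves.tsv", sep="\t", index=False)
    results["profile"] = profile
    manifest["stages"]["curves"] = "run"

    # ---- stage: fit ----
    rows = []
    if matrix.n_genomes >= 2:
        heap = fit_heaps(profile.N, profile.pan_curve)
        rows += _fit_report_rows("pan", heap=heap)
        results["heap_fit"] = heap
        if matrix.n_genomes >= 3:
            core_fit = fit_exp_decay(profile.N, profile.core_curve)
            new_fit = fit_exp_decay(profile.N, profile.new_curve)
            rows += _fit_report_rows("core", decay=core_fit)
            rows += _fit_report_rows("new", decay=new_fit)
            results["core_fit"] = core_fit
            results["new_fit"] = new_fit
            results["stabilization"] = stabilization_summary(core_fit, new_fit)
        manifest["stages"]["fit"] = "run"
    else:
        manifest["stages"]["fit"] = "skipped (single genome)"
    if rows:
        pd.DataFrame(
            rows,
            columns=["curve", "model", "k", "gamma_or_t", "alpha_or_tgtheta",
                     "rss", "call"],
        ).to_csv(tables / "fits.tsv", sep="\t", index=False)
        with open(tables / "fits.txt", "w") as fh:
            if "heap_fit" in results:
                h = results["heap_fit"]
                fh.write(
                    f"pan-genome: n = {h.k:.3f} * N^{h.gamma:.3f} "
                    f"(alpha = {h.alpha:.3f}, {h.openness})\n"
                )
            if "stabilization" in results:
                s = results["stabilization"]
                fh.write(
                    f"core genome stabilizes near {s['core_plateau_genes']} "
                    f"gene families (tg_theta = {s['core_plateau']:.3f})\n"
                )
                fh.write(
                    f"each new genome adds about "
                    f"{s['new_genes_per_genome_genes']} new gene families "
                    f"(tg_theta = {s['new_genes_per_genome']:.3f})\n"
                )

    # ---- stage: profile (annotation cross-tabs) ----
    did_profile = False
    if config.genome_summary_csv:
        stats = genome_summary_stats(read_genome_summary(config.genome_summary_csv))
        stats.rename_axis("feature").to_csv(tables / "genome_stats.tsv", sep="\t")
        results["genome_stats"] = stats
        did_profile = True
    if config.annotation_tsv:
        ann = read_annotation_table(config.annotation_tsv)
        dist_rows = []
        for subset, ids in (
            ("core", part.core_ids),
            ("accessory", part.accessory_ids),
            ("unique", part.unique_ids),
        ):
            if not ids:
                continue
            pcts, n_unann = category_distribution(ann, ids)
            for cat, p in pcts.items():
                dist_rows.append((subset, cat, p))
            dist_rows.append((subset, "unannotated_count", n_unann))
        pd.DataFrame(dist_rows, columns=["subset", "category", "value"]).to_csv(
            tables / "category_distribution.tsv", sep="\t", index=False
        )
        did_profile = True
    if config.trait_genes:
        hm = presence_heatmap(matrix, config.trait_genes)
        hm.data.astype(int).rename_axis("gene").to_csv(
            tables / "trait_heatmap.tsv", sep="\t"
        )
        results["heatmap"] = hm
        did_profile = True
    if config.localization_tsv:
        loc = read_localization_table(config.localization_tsv)
        xtab = adhesin_crosstab(loc, threshold=config.adhesin_threshold)
        pd.Series(xtab, name="count").rename_axis("localization").to_csv(
            tables / "adhesin_crosstab.tsv", sep="\t"
        )
        results["adhesin_crosstab"] = xtab
        did_profile = True
    if config.ppi_tsv:
        ppi = ppi_summary(read_ppi_table(config.ppi_tsv), min_score=config.ppi_min_score)
        ppi.degrees.to_csv(tables / "ppi_degrees.tsv", sep="\t", index=False)
        edge_rows = [
            (u, v, d["score"]) for u, v, d in sorted(ppi.graph.edges(data=True))
        ]
        pd.DataFrame(edge_rows, columns=["node_a", "node_b", "score"]).to_csv(
            tables / "ppi_edges.tsv", sep="\t", index=False
        )
        results["ppi"] = ppi
        did_profile = True
    manifest["stages"]["profile"] = "run" if did_profile else "skipped (no inputs)"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
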