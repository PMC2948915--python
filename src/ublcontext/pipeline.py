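"""Full-analysis orchestration: simulate/load -> motifs -> context -> phyletic -> tree.

A single configuration drives the whole workflow; anchor clusters for the
neighborhood analysis default to the motif-scan hits, mirroring the
discovery flow in which motif-defined ubiquitin-like families become the
anchors of the guilt-by-association step.  All stage outputs are TSV plus
a human-readable summary; reports contain no timestamps so a rerun with
the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import gene_context, genome_io, motif_scan, phyletic, phylo, synthetic_data

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_THRESHOLDS = {
    "k": 3,
    "max_len": 200,
    "cons_min": 0.8,
    "plurality_min": 0.5,
    "d_max": 100,
    "max_gap_frac": 0.5,
    "replicates": 10000,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _sim_config(cfg: dict, seed: int) -> synthetic_data.SimConfig:
    sim = cfg.get("simulate", {})
    return synthetic_data.SimConfig(
        seed=seed,
        n_genomes=int(sim.get("n_genomes", 10)),
        genes_per_genome=int(sim.get("genes_per_genome", 200)),
        n_clusters=int(sim.get("n_clusters", 100)),
        planted_associations=[
            synthetic_data.PlantedAssociation(
                a["anchor"], a["neighbor"], float(a["frequency"]),
                int(a.get("max_offset", 3)))
            for a in sim.get("planted_associations", [])
        ],
        planted_motif_families=[
            synthetic_data.PlantedMotifFamily(
                m["cluster_id"], m["motif"], int(m["length"]),
                float(m["conservation"]), int(m.get("n_members", 20)))
            for m in sim.get("motif_families", [])
        ],
        lineage_assignment=dict(sim.get("lineages", {})),
        tree_spec=sim.get("tree"),
        tree_sites=int(sim.get("tree_sites", 0)),
        bernoulli=bool(sim.get("bernoulli", False)),
        circular=bool(sim.get("circular", False)),
    )


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Run all stages in dependency order; returns a report summary dict.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    written by earlier stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    seed = cfg.get("seed")
    if seed is None:
        raise ConfigError("config must set an integer 'seed'")
    seed = int(seed)
    report: dict = {"seed": seed, "thresholds": thresholds, "stages": {}}

    # ---- inputs: simulate or load -----------------------------------
    stage = "inputs"
    try:
        if "simulate" in cfg:
            sim_cfg = _sim_config(cfg, seed)
            genomes, assignments, truth = synthetic_data.generate_genomes(sim_cfg)
            lineage_map = {g.genome_id: g.lineage for g in genomes}
            rng = np.random.default_rng(seed + 1)
            alignments = [
                synthetic_data.generate_motif_family(
                    f.cluster_id, f.n_members, f.length, f.motif, f.conservation, rng)
                for f in sim_cfg.planted_motif_families
            ]
            tree_aln = None
            if sim_cfg.tree_spec and sim_cfg.tree_sites > 0:
                tree_aln = synthetic_data.evolve_alignment(
                    sim_cfg.tree_spec, sim_cfg.tree_sites, seed + 2)
            inputs_dir = outdir / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            for g in genomes:
                genome_io.write_genome(g, inputs_dir / f"{g.genome_id}.gff3",
                                       inputs_dir / f"{g.genome_id}.faa")
            genome_io.write_cluster_table(assignments, inputs_dir / "clusters.tsv")
            genome_io.write_lineage_map(lineage_map, inputs_dir / "lineages.tsv")
            aln_dir = inputs_dir / "alignments"
            aln_dir.mkdir(exist_ok=True)
            for aln in alignments:
                genome_io.write_alignment(aln, aln_dir / f"{aln.cluster_id}.fa")
            truth_payload = {
                "association_genomes": {
                    f"{a}|{b}": v for (a, b), v in truth.association_genomes.items()},
                "motif_families": [asdict(f) for f in sim_cfg.planted_motif_families],
            }
            (outdir / "truth.json").write_text(
                json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
        else:
            inputs = cfg.get("inputs")
            if not inputs:
                raise ConfigError("config needs either 'simulate' or 'inputs'")
            lineage_map = genome_io.read_lineage_map(inputs["lineages"])
            genomes = []
            for gff3 in sorted(Path(inputs["genomes_dir"]).glob("*.gff3")):
                faa = gff3.with_suffix(".faa")
                g = genome_io.read_genome(gff3, faa)
                g.lineage = lineage_map.get(g.genome_id, "")
                genomes.append(g)
            assignments = genome_io.read_cluster_table(inputs["clusters"])
            alignments = [genome_io.read_alignment(p)
                          for p in sorted(Path(inputs["alignments_dir"]).glob("*.fa"))]
            tree_aln = (genome_io.read_alignment(inputs["tree_alignment"])
                        if "tree_alignment" in inputs else None)
        report["stages"]["inputs"] = {
            "n_genomes": len(genomes), "n_assignments": len(assignments),
            "n_alignments": len(alignments)}
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- motif scan ---------------------------------------------------
    stage = "scan-motifs"
    try:
        hits = motif_scan.scan_clusters(
            alignments, max_len=thresholds["max_len"],
            cons_min=thresholds["cons_min"],
            plurality_min=thresholds["plurality_min"])
        motif_scan.write_hits(hits, outdir / "motif_hits.tsv")
        report["stages"]["scan-motifs"] = {
            "n_hits": len(hits), "hit_clusters": [h.cluster_id for h in hits]}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- gene context -------------------------------------------------
    stage = "context"
    try:
        anchors = cfg.get("anchors")
        if anchors is None:
            anchors = sorted({h.cluster_id for h in hits})
            # planted association anchors are analysis targets too
            for a in cfg.get("simulate", {}).get("planted_associations", []):
                if a["anchor"] not in anchors:
                    anchors.append(a["anchor"])
        if not anchors:
            report["stages"]["context"] = {"skipped": "no anchor clusters"}
        else:
            anchor_set = set(anchors)
            gene_clusters: dict[tuple[str, str], list[str]] = {}
            for a in assignments:
                gene_clusters.setdefault((a.genome_id, a.gene_id), []).append(a.cluster_id)
            neighborhoods = []
            for g in genomes:
                for gene in g.genes():
                    if anchor_set & set(gene_clusters.get((g.genome_id, gene.gene_id), [])):
                        neighborhoods.append(
                            gene_context.extract_neighborhood(g, gene, k=thresholds["k"]))
            records = gene_context.count_associations(neighborhoods, assignments, lineage_map)
            gene_context.write_associations(records, outdir / "associations.tsv")
            fusions = gene_context.detect_fusions(assignments)
            gene_context.write_fusions(fusions, outdir / "fusions.tsv")
            operons = []
            for g in genomes:
                for rep in g.replicons:
                    operons.extend(gene_context.predict_operons(rep, thresholds["d_max"]))
            gene_context.write_operons(operons, outdir / "operons.tsv")
            report["stages"]["context"] = {
                "n_neighborhoods": len(neighborhoods),
                "n_associations": len(records),
                "top_association": (
                    [records[0].anchor_cluster, records[0].neighbor_cluster,
                     len(records[0].genomes)] if records else None),
                "n_fusions": len(fusions), "n_operons": len(operons)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- phyletic patterns ---------------------------------------------
    stage = "phyletic"
    try:
        genome_order = list(lineage_map)
        matrix = phyletic.build_matrix(assignments, genome_order)
        phyletic.write_matrix(matrix, outdir / "phyletic_matrix.tsv")
        query = [c for c in (anchors or []) if c in matrix.clusters]
        absent = phyletic.absence_report(matrix, query) if query else {}
        with open(outdir / "absences.tsv", "w") as fh:
            fh.write("cluster_id\tabsent_genomes\n")
            for c, gs in absent.items():
                fh.write(f"{c}\t{','.join(gs)}\n")
        report["stages"]["phyletic"] = {
            "n_clusters": len(matrix.clusters), "n_genomes": len(matrix.genomes)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- tree -----------------------------------------------------------
    stage = "tree"
    try:
        if tree_aln is None:
            report["stages"]["tree"] = {"skipped": "no tree alignment"}
        else:
            supported = phylo.ml_tree(
                tree_aln, max_gap_frac=thresholds["max_gap_frac"],
                n_replicates=thresholds["replicates"], seed=seed + 3)
            (outdir / "tree.nwk").write_text(supported.newick() + "\n")
            with open(outdir / "sites.tsv", "w") as fh:
                fh.write("column\n")
                for c in supported.siteset.selected_columns:
                    fh.write(f"{c}\n")
            report["stages"]["tree"] = {
                "n_informative_positions": len(supported.siteset),
                "log_likelihood": round(supported.tree.log_likelihood, 6),
                "min_branch_support": round(min(supported.branch_support.values()), 2)
                if supported.branch_support else None}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    _write_summary(report, outdir / "summary.txt")
    return report


def _write_summary(report: dict, path: Path) -> None:
    lines = ["ublcontext pipeline report", "=" * 26, ""]
    for stage, info in report["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    path.write_text("\n".join(lines))
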