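"""End-to-end orchestration: simulate -> hits -> orthology -> ANIb ->
tree -> cluster report -> enrichment, with a reproducible manifest.

One global seed fans out to per-stage seeds through a fixed CRC32-based
derivation, so any stage can be re-run individually with the same
randomness.  Every output file is listed in the run manifest with its
SHA-256 checksum; re-running an identical config reproduces identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import (NucleotideAlignParams, ProteinAlignParams,
                    all_vs_all_protein_hits)
from .anib import AnibParams, ani_to_distance, anib_matrix
from .cluster import ClusterSpec, classify_cluster
from .enrichment import (annotate_genes_go, contig_chi_squared,
                         enrich_gene_set, select_de_genes)
from .errors import ConfigError, ValidationError
from .io import (genes_by_contig, read_de_table, read_gene_pfam_table,
                 read_gene_table, read_genome_fasta, read_pfam2go,
                 read_tabular_hits, write_matrix_tsv, write_newick,
                 write_tabular_hits)
from .njtree import neighbor_joining
from .orthology import (BrbhParams, best_hit_per_target_genome, build_cogs,
                        partition_pangenome, reciprocal_pairs)
from .synthetic import (ClusterPlantSpec, DEPlantSpec, EnrichmentPlantSpec,
                        PangenomeConfig, simulate_de_table,
                        simulate_domain_annotation, simulate_pangenome,
                        write_dataset)

logger = logging.getLogger("panani")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (global seed + CRC32 of the stage name)."""
    return (seed + zlib.crc32(stage.encode())) % 2**31


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulation: PangenomeConfig | None = None
    inputs: dict | None = None  # paths: genomes, gene_table, proteomes?, hits?,
                                # de_table?, gene_pfam?, pfam2go?, cluster?
    brbh: BrbhParams = field(default_factory=BrbhParams)
    anib: AnibParams = field(default_factory=AnibParams)
    alignment: ProteinAlignParams = field(default_factory=ProteinAlignParams)
    alpha: float = 0.05
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "exactly one of {simulation config, real inputs} is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = None
        if "simulation" in raw:
            s = dict(raw["simulation"])
            if "cluster_spec" in s and s["cluster_spec"] is not None:
                c = s["cluster_spec"]
                s["cluster_spec"] = ClusterPlantSpec(
                    member_families=tuple(c["member_families"]),
                    complete_genomes=tuple(c["complete_genomes"]),
                    partial_genomes={k: tuple(v) for k, v in
                                     c.get("partial_genomes", {}).items()})
            if "enrichment_spec" in s and s["enrichment_spec"] is not None:
                s["enrichment_spec"] = EnrichmentPlantSpec(**s["enrichment_spec"])
            if "de_spec" in s and s["de_spec"] is not None:
                s["de_spec"] = DEPlantSpec(**s["de_spec"])
            sim = PangenomeConfig(**s)
        inputs = raw.get("inputs")
        if inputs is not None:
            for key in ("genomes", "gene_table"):
                if key not in inputs:
                    raise ConfigError(f"inputs.{key} is required")
            for key, value in inputs.items():
                if key == "genomes":
                    missing = [p for p in value if not Path(p).exists()]
                    if missing:
                        raise ConfigError(f"inputs.genomes: missing {missing}")
                elif key != "cluster" and value is not None and not Path(value).exists():
                    raise ConfigError(f"inputs.{key}: no such file {value!r}")
        return cls(
            outdir=Path(raw.get("outdir", "panani_run")),
            seed=int(raw.get("seed", 0)),
            simulation=sim,
            inputs=inputs,
            brbh=BrbhParams(**raw.get("brbh", {})),
            anib=AnibParams(**{
                **raw.get("anib", {}),
                **({"alignment": NucleotideAlignParams(
                    **raw["anib"]["alignment"])}
                   if isinstance(raw.get("anib", {}).get("alignment"), dict)
                   else {})}),
            alignment=ProteinAlignParams(**raw.get("alignment", {})),
            alpha=float(raw.get("enrichment_alpha", 0.05)),
            verbosity=str(raw.get("verbosity", "INFO")),
        )

    def dump_effective(self, path: Path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj
        payload = {
            "outdir": str(self.outdir), "seed": self.seed,
            "simulation": plain(self.simulation) if self.simulation else None,
            "inputs": plain(self.inputs) if self.inputs else None,
            "brbh": plain(self.brbh), "anib": plain(self.anib),
            "alignment": plain(self.alignment),
            "enrichment_alpha": self.alpha, "verbosity": self.verbosity,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; return the run manifest."""
    logging.basicConfig(level=config.verbosity)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": [], "outputs": {}}

    def record(stage: str, t0: float, files: dict[str, Path]) -> None:
        manifest["stages"].append(
            {"name": stage, "seconds": round(time.perf_counter() - t0, 3)})
        for name, p in files.items():
            manifest["outputs"][name] = {
                "path": str(p), "sha256": _sha256(Path(p))}
        logger.info("stage %s done (%.2fs)", stage,
                    time.perf_counter() - t0)

    cluster_members: tuple[str, ...] | None = None
    reference_genome: str | None = None

    # ---- stage: inputs / simulation -------------------------------------
    t0 = time.perf_counter()
    if config.simulation is not None:
        sim_config = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate"))
        genomes, genes, proteomes, truth = simulate_pangenome(sim_config)
        de_table = domains = pfam2go = None
        if sim_config.de_spec is not None:
            de_table = simulate_de_table(truth, sim_config)
        if sim_config.enrichment_spec is not None and de_table is not None:
            domains, pfam2go = simulate_domain_annotation(truth, sim_config)
        data_dir = outdir / "data"
        files = write_dataset(data_dir, genomes, genes, proteomes, truth,
                              de_table=de_table, domains=domains,
                              pfam2go=pfam2go)
        reference_genome = truth.reference_genome
        if sim_config.cluster_spec is not None:
            cluster_members = tuple(
                truth.cluster_genes_by_genome[reference_genome])
        hits = None
        record("simulate", t0, files)
    else:
        inputs = config.inputs or {}
        genomes = [read_genome_fasta(p) for p in inputs["genomes"]]
        genome_map = {g.genome_id: g for g in genomes}
        proteomes_seq = {}
        if inputs.get("proteomes"):
            from .io import read_fasta
            prot = dict(read_fasta(inputs["proteomes"]))
        else:
            prot = {}
        genes = read_gene_table(inputs["gene_table"], genomes=genome_map,
                                proteomes=prot)
        proteomes = {}
        for g in genes:
            proteomes.setdefault(g.genome_id, {})[g.gene_id] = g.protein
        hits = (read_tabular_hits(inputs["hits"])
                if inputs.get("hits") else None)
        de_table = None
        domains = (read_gene_pfam_table(inputs["gene_pfam"])
                   if inputs.get("gene_pfam") else None)
        pfam2go = (read_pfam2go(inputs["pfam2go"])
                   if inputs.get("pfam2go") else None)
        if inputs.get("cluster"):
            cluster_members = tuple(inputs["cluster"]["members"])
            reference_genome = inputs["cluster"]["reference_genome"]
        record("load_inputs", t0, {})

    config.dump_effective(outdir / "effective_config.yaml")
    manifest["outputs"]["effective_config"] = {
        "path": str(outdir / "effective_config.yaml"),
        "sha256": _sha256(outdir / "effective_config.yaml")}
    gene_to_genome = {g.gene_id: g.genome_id for g in genes}
    genome_ids = [g.genome_id for g in genomes]

    # ---- stage: hits ------------------------------------------------------
    t0 = time.perf_counter()
    if hits is None:
        hits = all_vs_all_protein_hits(proteomes, config.alignment)
    hits_path = outdir / "hits.tsv"
    write_tabular_hits(hits, hits_path)
    record("hits", t0, {"hits": hits_path})

    # ---- stage: orthology -------------------------------------------------
    t0 = time.perf_counter()
    best = best_hit_per_target_genome(hits, gene_to_genome, config.brbh)
    pairs = reciprocal_pairs(best, gene_to_genome)
    cogs = build_cogs(pairs, gene_to_genome)
    partition = partition_pangenome(cogs, gene_to_genome, best, genome_ids)
    cog_path = outdir / "cog_membership.tsv"
    pd.DataFrame(
        [(c.cog_id, genome, gene) for c in cogs for genome, gene in c.members],
        columns=["cog_id", "genome", "gene_id"],
    ).to_csv(cog_path, sep="\t", index=False)
    summary_path = outdir / "partition_summary.tsv"
    pd.DataFrame([
        ("core_cogs", len(partition.core_cogs)),
        ("accessory_cogs", len(partition.accessory_cogs)),
        ("specific_genes", len(partition.specific_genes)),
        ("unresolved_genes", len(partition.unresolved_genes)),
    ], columns=["quantity", "count"]).to_csv(summary_path, sep="\t", index=False)
    specific_path = outdir / "specific_genes.txt"
    specific_path.write_text("\n".join(partition.specific_genes) + "\n")
    record("orthology", t0, {"cog_membership": cog_path,
                             "partition_summary": summary_path,
                             "specific_genes": specific_path})

    # ---- stage: anib ------------------------------------------------------
    t0 = time.perf_counter()
    matrix = anib_matrix(genomes, config.anib)
    anib_path = outdir / "anib_matrix.tsv"
    write_matrix_tsv(matrix.genome_ids, matrix.values, anib_path)
    labels, distances = ani_to_distance(matrix)
    dist_path = outdir / "distances.tsv"
    write_matrix_tsv(labels, distances, dist_path)
    record("anib", t0, {"anib_matrix": anib_path, "distances": dist_path})

    # ---- stage: tree ------------------------------------------------------
    t0 = time.perf_counter()
    tree = neighbor_joining(labels, distances)
    tree_path = outdir / "tree.nwk"
    write_newick(tree, tree_path)
    record("tree", t0, {"tree": tree_path})

    # ---- stage: cluster conservation --------------------------------------
    if cluster_members and reference_genome:
        t0 = time.perf_counter()
        spec = ClusterSpec(cluster_id="planted_cluster",
                           reference_genome=reference_genome,
                           members=cluster_members)
        report = classify_cluster(spec, cogs, genes, genome_ids)
        cluster_path = outdir / "cluster_report.tsv"
        pd.DataFrame(
            sorted(report.status_by_genome.items()),
            columns=["genome", "status"],
        ).to_csv(cluster_path, sep="\t", index=False)
        record("cluster", t0, {"cluster_report": cluster_path})

    # ---- stage: enrichment -------------------------------------------------
    de_path = manifest["outputs"].get("de_table", {}).get("path") or (
        (config.inputs or {}).get("de_table"))
    if de_path:
        t0 = time.perf_counter()
        de_records = read_de_table(de_path)
        selection = select_de_genes(de_records, config.alpha)
        files: dict[str, Path] = {}
        de_summary = outdir / "de_selection.tsv"
        pd.DataFrame([
            ("up", len(selection.up)), ("down", len(selection.down)),
            ("ambiguous", len(selection.ambiguous)),
        ], columns=["direction", "count"]).to_csv(de_summary, sep="\t",
                                                  index=False)
        files["de_selection"] = de_summary

        if domains is not None and pfam2go is not None:
            annotation = annotate_genes_go(domains, pfam2go)
            background = list(domains)
            for direction, gene_set in (("up", selection.up),
                                        ("down", selection.down)):
                results = enrich_gene_set(gene_set & set(background),
                                          background, annotation.gene_to_go)
                path = outdir / f"enrichment_{direction}.tsv"
                pd.DataFrame(
                    [(r.term_id, r.k, r.n, r.K, r.N,
                      round(r.fold_enrichment, 4), r.p_raw, r.p_adj)
                     for r in results],
                    columns=["term", "k", "n", "K", "N", "fold_enrichment",
                             "p_raw", "p_adj"],
                ).to_csv(path, sep="\t", index=False)
                files[f"enrichment_{direction}"] = path

        # positional test on the two gene-richest contigs of the focal genome
        focal = reference_genome or genome_ids[0]
        by_contig = genes_by_contig(g for g in genes if g.genome_id == focal)
        if len(by_contig) >= 2:
            de_all = selection.up | selection.down
            ranked = sorted(by_contig.items(), key=lambda kv: -len(kv[1]))
            (key_a, genes_a), (key_b, genes_b) = ranked[0], ranked[1]
            test = contig_chi_squared(
                sum(g.gene_id in de_all for g in genes_a), len(genes_a),
                sum(g.gene_id in de_all for g in genes_b), len(genes_b))
            contig_path = outdir / "contig_test.tsv"
            pd.DataFrame([{
                "contig_a": key_a[1], "genes_a": len(genes_a),
                "de_a": test.table[0][0],
                "contig_b": key_b[1], "genes_b": len(genes_b),
                "de_b": test.table[1][0],
                "chi_squared": test.statistic, "dof": test.dof,
                "p_value": test.p_value,
            }]).to_csv(contig_path, sep="\t", index=False)
            files["contig_test"] = contig_path
        record("enrichment", t0, files)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def make_report(manifest: dict) -> str:
    """Human-readable text summary cross-checked against the stage files."""
    lines = [f"panani {manifest['version']} run (seed {manifest['seed']})", ""]
    outputs = manifest["outputs"]
    required = ["partition_summary"]
    for name in required:
        if name not in outputs:
            raise ValidationError(f"manifest is missing stage output {name!r}")
    summary = pd.read_csv(outputs["partition_summary"]["path"], sep="\t")
    for row in summary.itertuples(index=False):
        lines.append(f"{row.quantity}: {row.count}")
    if "cluster_report" in outputs:
        cluster = pd.read_csv(outputs["cluster_report"]["path"], sep="\t")
        counts = cluster["status"].value_counts().to_dict()
        lines.append("cluster conservation: " + ", ".join(
            f"{counts.get(s, 0)} {s}" for s in ("complete", "partial", "absent")))
    if "de_selection" in outputs:
        de = pd.read_csv(outputs["de_selection"]["path"], sep="\t")
        for row in de.itertuples(index=False):
            lines.append(f"DE {row.direction}: {row.count}")
    if "contig_test" in outputs:
        t = pd.read_csv(outputs["contig_test"]["path"], sep="\t").iloc[0]
        lines.append(f"contig chi-squared: {t['chi_squared']:.4f} "
                     f"(p = {t['p_value']:.3e})")
    if "tree" in outputs:
        lines.append("tree: " + Path(outputs["tree"]["path"]).read_text().strip())
    lines.append("")
    lines.append("stages: " + ", ".join(
        f"{s['name']} ({s['seconds']}s)" for s in manifest["stages"]))
    return "\n".join(lines)
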