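"""End-to-end pan-genome pipeline driven by a flat key=value config.

Stages: load-or-simulate panel -> all-vs-all similarity -> homology graph +
Markov clustering -> presence/absence + partition -> gene-content NJ tree ->
optional outgroup subtraction -> optional term enrichment -> optional
pathway conservation report. Every stage writes its output as a re-loadable
text file, and an identical config + seed produces a byte-identical bundle
(the manifest deliberately records no wall-clock state).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .clustering import build_homology_graph, mcl_cluster, write_groups_tsv
from .enrichment import (
    enrich_terms,
    group_terms,
    write_enrichment_tsv,
    write_kappa_edges_tsv,
    write_term_groups_tsv,
)
from .io_formats import (
    GenomePanel,
    read_blast_tabular,
    read_panel_fasta_dir,
    read_protein_fasta,
    read_term_annotations,
    write_blast_tabular,
    write_json_bundle,
    write_newick,
    write_presence_absence_tsv,
)
from .pangenome import (
    annotation_summary,
    partition,
    presence_matrix,
    subtract_outgroups,
)
from .pathway import (
    homology_links,
    load_pathway_model,
    map_pathway,
    write_conservation_tsv,
)
from .phylo import gene_content_distance, neighbor_joining
from .similarity import FilterThresholds, ScoringScheme, all_vs_all, cross_hits
from .synthetic import (
    SimulationParams,
    generate_panel,
    uniform_dispensable_spec,
    write_panel_fastas,
)

logger = logging.getLogger("acetopan")

INPUT_MODES = ("fasta_dir", "simulate", "blast_tab")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the pipeline's standard thresholds."""

    input_mode: str = "simulate"
    fasta_dir: str | None = None
    blast_tab: str | None = None
    outgroup_fastas: tuple[str, ...] = ()
    term_annotations: str | None = None
    reference_fasta: str | None = None
    output_dir: str = "acetopan_out"
    seed: int = 0

    min_score: float = 50.0
    max_evalue: float = 1e-10
    link_evalue: float = 1e-6
    kappa_threshold: float = 0.4
    alpha: float = 0.05
    inflation: float = 1.5
    prefilter_k: int = 4

    n_genomes: int = 14
    n_core: int = 200
    n_dispensable: int = 100
    n_specific_per_genome: int = 3
    protein_length: int = 120
    divergence: float = 0.03
    paralog_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        if self.input_mode == "fasta_dir" and not self.fasta_dir:
            raise ValueError("fasta_dir mode requires fasta_dir")
        if self.input_mode == "blast_tab" and not (self.blast_tab and self.fasta_dir):
            raise ValueError("blast_tab mode requires blast_tab and fasta_dir")
        if self.input_mode == "simulate" and (self.fasta_dir or self.blast_tab):
            raise ValueError(
                "simulate mode must not also set fasta_dir or blast_tab: "
                "exactly one input mode may be active"
            )
        for name in ("min_score",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("max_evalue", "link_evalue", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(self.min_score, self.max_evalue)

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            n_genomes=self.n_genomes,
            n_core=self.n_core,
            dispensable_spec=uniform_dispensable_spec(
                self.n_genomes, self.n_dispensable
            ),
            n_specific_per_genome=self.n_specific_per_genome,
            protein_length=self.protein_length,
            divergence=self.divergence,
            paralog_rate=self.paralog_rate,
            seed=self.seed,
        )


_BOOLISH = {"true": True, "false": False}


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat key=value config file (``#`` comments allowed)."""
    values: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key=value")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key == "outgroup_fastas":
            values[key] = tuple(p for p in raw.split(",") if p)
            continue
        field_types = {f: t for f, t in PipelineConfig.__annotations__.items()}
        if key not in field_types:
            raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
        if raw.lower() in _BOOLISH:
            values[key] = _BOOLISH[raw.lower()]
        else:
            for cast in (int, float):
                try:
                    values[key] = cast(raw)
                    break
                except ValueError:
                    continue
            else:
                values[key] = raw
    return PipelineConfig(**values)


def _load_panel(config: PipelineConfig, outdir: Path):
    truth = None
    if config.input_mode == "simulate":
        panel, truth = generate_panel(config.simulation_params())
        write_panel_fastas(panel, outdir / "fastas")
        truth.write_tsv(outdir / "truth.tsv")
    else:
        fasta_dir = Path(config.fasta_dir)
        paths = sorted(fasta_dir.glob("*.faa")) + sorted(fasta_dir.glob("*.fasta"))
        if not paths:
            raise FileNotFoundError(f"no FASTA files in {fasta_dir}")
        panel = read_panel_fasta_dir({p.stem: p for p in paths})
    return panel, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "acetopan",
        "version": __version__,
        # output_dir is omitted so a bundle is byte-identical wherever it
        # was written
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "output_dir"
        },
        "stages": {},
        "outputs": {},
    }
    scheme = ScoringScheme()
    thresholds = config.thresholds()

    current_stage = {"name": "setup"}

    def stage(name: str):
        current_stage["name"] = name
        logger.info("stage %s", name)
        return time.time()

    try:
        t0 = stage("panel")
        panel, truth = _load_panel(config, outdir)
        manifest["stages"]["panel"] = {
            "n_genomes": panel.n_genomes,
            "n_proteins": len(panel.proteins),
        }

        stage("similarity")
        if config.input_mode == "blast_tab":
            hits = read_blast_tabular(config.blast_tab)
        else:
            hits = all_vs_all(
                panel, scheme, thresholds, prefilter_k=config.prefilter_k
            )
            write_blast_tabular(hits, outdir / "hits.tsv")
            manifest["outputs"]["hits"] = "hits.tsv"
        manifest["stages"]["similarity"] = {"n_hits": len(hits)}

        stage("clustering")
        hg = build_homology_graph(hits, panel)
        hg.write_edge_list(outdir / "homology_edges.tsv")
        groups = mcl_cluster(hg, inflation=config.inflation)
        write_groups_tsv(groups, hg, outdir / "groups.tsv")
        manifest["stages"]["clustering"] = {"n_groups": len(groups)}
        manifest["outputs"]["groups"] = "groups.tsv"

        stage("partition")
        matrix = presence_matrix(groups, panel)
        write_presence_absence_tsv(matrix, outdir / "presence_absence.tsv")
        part = partition(matrix, groups)
        summary = part.to_dict()
        summary["annotation_summary"] = annotation_summary(part, groups, panel)
        write_json_bundle(summary, outdir / "partition.json")
        manifest["stages"]["partition"] = {
            "group_counts": part.group_counts,
            "gene_counts": part.gene_counts,
        }
        manifest["outputs"]["partition"] = "partition.json"
        manifest["outputs"]["presence_absence"] = "presence_absence.tsv"

        stage("tree")
        dm = gene_content_distance(matrix)
        dm.write_tsv(outdir / "distances.tsv")
        tree = neighbor_joining(dm)
        write_newick(tree, outdir / "pangenome_tree.nwk")
        manifest["outputs"]["tree"] = "pangenome_tree.nwk"

        core_groups = [
            g for g in groups if part.group_class[g.group_id] == "core"
        ]
        if config.outgroup_fastas:
            stage("subtract")
            outgroup_proteins = []
            for p in config.outgroup_fastas:
                outgroup_proteins.extend(read_protein_fasta(p, Path(p).stem))
            retained, removed = subtract_outgroups(
                core_groups, panel, outgroup_proteins, scheme, thresholds,
                prefilter_k=config.prefilter_k,
            )
            with open(outdir / "lineage_specific_core.tsv", "w") as fh:
                fh.write("group_id\tretained\n")
                for g in core_groups:
                    fh.write(f"{g.group_id}\t{int(g in retained)}\n")
            manifest["stages"]["subtract"] = {
                "core_in": len(core_groups),
                "retained": len(retained),
                "removed": len(removed),
            }
            manifest["outputs"]["lineage_specific_core"] = (
                "lineage_specific_core.tsv"
            )

        if config.term_annotations:
            stage("enrich")
            annotations = read_term_annotations(config.term_annotations)
            universe = set().union(*annotations.values())
            core_members = {m for g in core_groups for m in g.members}
            study = core_members & universe
            results = enrich_terms(study, annotations, universe, config.alpha)
            write_enrichment_tsv(results, outdir / "enrichment.tsv")
            n_sig = sum(r.significant for r in results)
            manifest["stages"]["enrich"] = {
                "n_terms_tested": len(results),
                "n_significant": n_sig,
            }
            manifest["outputs"]["enrichment"] = "enrichment.tsv"
            if n_sig:
                tgroups = group_terms(
                    results, annotations, universe, config.kappa_threshold
                )
                write_term_groups_tsv(tgroups, outdir / "term_groups.tsv")
                write_kappa_edges_tsv(tgroups, outdir / "term_kappa_edges.tsv")
                manifest["stages"]["enrich"]["n_term_groups"] = len(tgroups)
                manifest["outputs"]["term_groups"] = "term_groups.tsv"

        if config.reference_fasta:
            stage("pathway")
            reference = read_protein_fasta(config.reference_fasta, "reference")
            model = load_pathway_model()
            ref_hits = cross_hits(
                reference, panel.proteins, scheme, thresholds,
                prefilter_k=config.prefilter_k,
            )
            report = map_pathway(groups, panel, model, ref_hits)
            write_conservation_tsv(report, outdir / "pathway_report.tsv")
            links = homology_links(
                reference, panel, scheme, link_evalue=config.link_evalue,
                prefilter_k=config.prefilter_k,
            )
            with open(outdir / "pathway_links.tsv", "w") as fh:
                fh.write("reference_protein\tpanel_protein\tevalue\n")
                for q, s, e in links:
                    fh.write(f"{q}\t{s}\t{e:.3g}\n")
            manifest["stages"]["pathway"] = {
                "n_steps_mapped": len(report.steps),
                "n_steps_absent": len(report.absent_steps),
                "n_links": len(links),
            }
            manifest["outputs"]["pathway_report"] = "pathway_report.tsv"
    except Exception as exc:
        manifest["failed_stage"] = current_stage["name"]
        manifest["error"] = str(exc)
        write_json_bundle(manifest, outdir / "manifest.json")
        raise RuntimeError(
            f"pipeline stage {current_stage['name']!r} failed: {exc}"
        ) from exc

    write_json_bundle(manifest, outdir / "manifest.json")
    manifest["outputs"]["manifest"] = "manifest.json"
    return manifest
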