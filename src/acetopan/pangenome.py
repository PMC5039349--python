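"""Core / dispensable / specific partitioning of ortholog groups.

A group present in every genome of the panel is core; present in a single
genome, strain-specific; anything in between (2..N-1 genomes), dispensable.
Group counts count families once; gene counts include every member, paralogs
included (a core family of 26 members over 14 genomes contributes 26 core
genes). The module also summarises annotation status per class, subtracts
outgroup proteomes from the core to yield a lineage-specific core, and
computes panel-table statistics (mean genome size, GC content range).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import OrthologGroup
from .io_formats import GenomePanel, ProteinRecord
from .similarity import FilterThresholds, ScoringScheme, cross_hits

CLASSES = ("core", "dispensable", "specific")


@dataclass
class PanGenomePartition:
    """Counts and class assignment of the pan-genome partition."""

    n_genomes: int
    group_class: dict[str, str]
    group_counts: dict[str, int]
    gene_counts: dict[str, int]
    specific_genes_per_genome: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_genomes": self.n_genomes,
            "group_counts": dict(self.group_counts),
            "gene_counts": dict(self.gene_counts),
            "specific_genes_per_genome": dict(self.specific_genes_per_genome),
        }


def presence_matrix(
    groups: Sequence[OrthologGroup], panel: GenomePanel
) -> pd.DataFrame:
    """Binary groups x genomes occupancy matrix (paralogs collapse to one 1)."""
    genome_set = set(panel.genomes)
    for g in groups:
        unknown = g.occupancy - genome_set
        if unknown:
            raise ValueError(
                f"group {g.group_id} occupies unknown genomes {sorted(unknown)}"
            )
    data = {
        g.group_id: [1 if genome in g.occupancy else 0 for genome in panel.genomes]
        for g in groups
    }
    matrix = pd.DataFrame.from_dict(
        data, orient="index", columns=list(panel.genomes)
    ).astype(int)
    matrix.index.name = "group_id"
    return matrix


def classify_row_sum(row_sum: int, n_genomes: int) -> str:
    if row_sum == 0:
        raise ValueError("all-zero presence row: every group must occupy a genome")
    if row_sum == n_genomes:
        return "core"
    if row_sum == 1:
        return "specific"
    return "dispensable"


def partition(
    matrix: pd.DataFrame, groups: Sequence[OrthologGroup] | None = None
) -> PanGenomePartition:
    """Classify every group by its genome occupancy.

    Gene counts (member counts, paralogs included) require ``groups``; with
    only the binary matrix they fall back to occupancy sums.
    """
    n_genomes = matrix.shape[1]
    if n_genomes < 3:
        raise ValueError("partitioning needs >= 3 genomes")
    row_sums = matrix.sum(axis=1)
    group_class = {
        gid: classify_row_sum(int(s), n_genomes) for gid, s in row_sums.items()
    }

    group_counts = {c: 0 for c in CLASSES}
    for c in group_class.values():
        group_counts[c] += 1

    gene_counts = {c: 0 for c in CLASSES}
    specific_per_genome = {g: 0 for g in matrix.columns}
    if groups is not None:
        by_id = {g.group_id: g for g in groups}
        if set(by_id) != set(matrix.index):
            raise ValueError("groups do not match the presence matrix rows")
        for gid, c in group_class.items():
            g = by_id[gid]
            gene_counts[c] += g.size
            if c == "specific":
                (genome,) = g.occupancy
                specific_per_genome[genome] += g.size
    else:
        for gid, c in group_class.items():
            gene_counts[c] += int(row_sums[gid])
            if c == "specific":
                genome = matrix.columns[matrix.loc[gid].values.argmax()]
                specific_per_genome[genome] += 1

    return PanGenomePartition(
        n_genomes=n_genomes,
        group_class=group_class,
        group_counts=group_counts,
        gene_counts=gene_counts,
        specific_genes_per_genome=specific_per_genome,
    )


def classify_product(product: str) -> str:
    """Annotation status from a product string.

    'hypothetical' anywhere (case-insensitive) -> hypothetical; empty or
    'unknown'/'uncharacterized' -> unknown; anything else -> annotated.
    """
    low = product.lower()
    if "hypothetical" in low:
        return "hypothetical"
    if not low.strip() or "unknown" in low or "uncharacterized" in low:
        return "unknown"
    return "annotated"


def annotation_summary(
    part: PanGenomePartition,
    groups: Sequence[OrthologGroup],
    panel: GenomePanel,
) -> dict[str, dict[str, float]]:
    """Per-class fractions of hypothetical / unknown / annotated members."""
    products = {rec.protein_id: rec.product for rec in panel.proteins}
    tallies = {c: {"hypothetical": 0, "unknown": 0, "annotated": 0} for c in CLASSES}
    for g in groups:
        c = part.group_class[g.group_id]
        for m in g.members:
            tallies[c][classify_product(products.get(m, ""))] += 1
    out: dict[str, dict[str, float]] = {}
    for c, tally in tallies.items():
        total = sum(tally.values())
        if total == 0:
            out[c] = {k: 0.0 for k in tally}
        else:
            out[c] = {k: v / total for k, v in tally.items()}
    return out


def subtract_outgroups(
    core_groups: Sequence[OrthologGroup],
    panel: GenomePanel,
    outgroup_proteins: Sequence[ProteinRecord],
    scheme: ScoringScheme | None = None,
    thresholds: FilterThresholds | None = None,
    prefilter_k: int | None = 4,
) -> tuple[list[OrthologGroup], list[OrthologGroup]]:
    """Trim the core down to the lineage-specific core.

    A core group is removed as soon as any of its members hits any outgroup
    protein at the same thresholds used for clustering (any-member-any-hit
    semantics); the retained set is the lineage-specific core. Returns
    (retained, removed).
    """
    if not outgroup_proteins:
        raise ValueError(
            "outgroup subtraction requires at least one outgroup protein; "
            "an empty outgroup would be a silent no-op"
        )
    thresholds = thresholds or FilterThresholds()
    by_id = panel.by_id
    members = sorted({m for g in core_groups for m in g.members})
    member_records = [by_id[m] for m in members]
    hits = cross_hits(
        member_records,
        outgroup_proteins,
        scheme=scheme,
        thresholds=thresholds,
        prefilter_k=prefilter_k,
    )
    flagged = {h.query_id for h in hits}
    retained = [g for g in core_groups if not (set(g.members) & flagged)]
    removed = [g for g in core_groups if set(g.members) & flagged]
    return retained, removed


def load_genome_table() -> pd.DataFrame:
    """The packaged 23-row acetogen genome table (strain, size, GC%, ...)."""
    with importlib.resources.files("acetopan.data").joinpath(
        "genome_table.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def table_stats(table: pd.DataFrame) -> dict[str, float]:
    """Mean genome size (Mb, 1 decimal), mean GC%, and the GC range."""
    if len(table) == 0:
        raise ValueError("empty genome table")
    return {
        "n_genomes": int(len(table)),
        "mean_size_mb": round(float(table["genome_size_bp"].mean()) / 1e6, 1),
        "mean_gc_percent": round(float(table["gc_percent"].mean()), 1),
        "gc_min_percent": float(table["gc_percent"].min()),
        "gc_max_percent": float(table["gc_percent"].max()),
    }
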