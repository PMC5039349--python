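"""Pathway-level conservation mapping.

Given a panel's ortholog groups and a curated pathway model (an ordered list
of enzymatic steps, each tied to reference proteins), this module reports
how many panel genomes carry a homolog of each step and classifies each step
as core (all genomes), highly conserved dispensable (at least half the
genomes) or lesser conserved dispensable (under half). A genome "has" a step
when any of its proteins either hits one of the step's reference proteins at
the clustering thresholds or shares an ortholog group with a protein that
does. A looser link threshold (E < 1e-6, strict) produces the
reference-vs-panel homology link table.

The packaged model transcribes a curated set of acetogen pathway steps
(Wood-Ljungdahl methyl/carbonyl branches and acetate production, central
carbon metabolism, tetrahydrofolate and molybdopterin cofactor biosynthesis)
with the strain counts reported for the 14-genome acetogen panel as fixture
expectations in the ``reported_strains`` column; those counts describe the
source panel and are never produced as output.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import OrthologGroup
from .io_formats import GenomePanel, ProteinRecord, SimilarityHit
from .similarity import FilterThresholds, ScoringScheme, cross_hits

CONSERVATION_CLASSES = (
    "core",
    "highly_conserved_dispensable",
    "lesser_conserved_dispensable",
)


@dataclass(frozen=True)
class PathwayStep:
    step_id: str
    pathway: str
    enzyme: str
    gene_symbol: str
    reference_proteins: tuple[str, ...]
    figure: str = ""
    reported_strains: int | None = None
    notes: str = ""


@dataclass
class PathwayModel:
    name: str
    steps: list[PathwayStep]

    def __post_init__(self) -> None:
        for step in self.steps:
            if not step.gene_symbol:
                raise ValueError(f"step {step.step_id}: empty gene symbol")

    def step(self, step_id: str) -> PathwayStep:
        for s in self.steps:
            if s.step_id == step_id:
                return s
        raise KeyError(step_id)


@dataclass
class StepConservation:
    step_id: str
    strain_count: int
    conservation: str
    present_genomes: list[str]
    missing_genomes: list[str]


@dataclass
class ConservationReport:
    n_genomes: int
    steps: dict[str, StepConservation]
    absent_steps: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step_id": s.step_id,
                "strain_count": s.strain_count,
                "conservation": s.conservation,
                "missing_genomes": ",".join(s.missing_genomes),
            }
            for s in self.steps.values()
        ]
        rows += [
            {
                "step_id": sid,
                "strain_count": 0,
                "conservation": "absent",
                "missing_genomes": "",
            }
            for sid in self.absent_steps
        ]
        return pd.DataFrame(rows)


def conservation_class(
    strain_count: int, n_genomes: int, majority_fraction: float = 0.5
) -> str:
    """core at full occupancy; >=50% of strains is highly conserved
    dispensable; below that, lesser conserved dispensable."""
    if not 0 < strain_count <= n_genomes:
        raise ValueError(
            "strain_count must be in 1..n_genomes; absent steps are reported "
            "separately"
        )
    if strain_count == n_genomes:
        return "core"
    if strain_count / n_genomes >= majority_fraction:
        return "highly_conserved_dispensable"
    return "lesser_conserved_dispensable"


def load_pathway_model() -> PathwayModel:
    """The packaged acetogen pathway model (WLP, central carbon, cofactors)."""
    with importlib.resources.files("acetopan.data").joinpath(
        "wlp_pathway_model.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    steps = [
        PathwayStep(
            step_id=row.step_id,
            pathway=row.pathway,
            enzyme=row.enzyme,
            gene_symbol=row.gene_symbol,
            reference_proteins=tuple(
                p for p in str(row.reference_protein).split(";") if p
            ),
            figure=row.figure,
            reported_strains=(
                int(row.reported_strains) if str(row.reported_strains) else None
            ),
            notes=row.notes,
        )
        for row in df.itertuples()
    ]
    return PathwayModel(name="acetogen_conserved_pathways", steps=steps)


def map_pathway(
    groups: Sequence[OrthologGroup],
    panel: GenomePanel,
    model: PathwayModel,
    reference_hits: Sequence[SimilarityHit],
    reference_ids: set[str] | None = None,
) -> ConservationReport:
    """Per-step strain counts and conservation classes for a panel.

    ``reference_hits`` are filtered hits from reference proteins (queries)
    against panel proteins (subjects). Occupancy propagates through ortholog
    groups: a direct hit to one group member marks every genome the group
    occupies. ``reference_ids``, when given, validates that every step's
    reference proteins exist in the supplied reference proteome.
    """
    if reference_ids is not None:
        for step in model.steps:
            missing = [p for p in step.reference_proteins if p not in reference_ids]
            if missing:
                raise ValueError(
                    f"step {step.step_id}: unresolvable reference proteins "
                    f"{missing}"
                )
    genome_of = {rec.protein_id: rec.genome_id for rec in panel.proteins}
    group_of: dict[str, OrthologGroup] = {}
    for g in groups:
        for m in g.members:
            group_of[m] = g

    hits_by_ref: dict[str, set[str]] = {}
    for h in reference_hits:
        hits_by_ref.setdefault(h.query_id, set()).add(h.subject_id)

    steps: dict[str, StepConservation] = {}
    absent: list[str] = []
    for step in model.steps:
        direct: set[str] = set()
        for ref in step.reference_proteins:
            direct |= hits_by_ref.get(ref, set())
        present: set[str] = set()
        for pid in direct:
            present.add(genome_of[pid])
            grp = group_of.get(pid)
            if grp is not None:
                present |= grp.occupancy
        if not present:
            absent.append(step.step_id)
            continue
        count = len(present)
        steps[step.step_id] = StepConservation(
            step_id=step.step_id,
            strain_count=count,
            conservation=conservation_class(count, panel.n_genomes),
            present_genomes=sorted(present),
            missing_genomes=sorted(set(panel.genomes) - present),
        )
    return ConservationReport(
        n_genomes=panel.n_genomes, steps=steps, absent_steps=absent
    )


def homology_links(
    reference_proteome: Sequence[ProteinRecord],
    panel: GenomePanel,
    scheme: ScoringScheme | None = None,
    link_evalue: float = 1e-6,
    prefilter_k: int | None = 4,
) -> list[tuple[str, str, float]]:
    """(reference protein, panel protein, E-value) links at E strictly below
    ``link_evalue`` — the loose threshold used for reference-vs-panel maps,
    independent of the clustering filter."""
    hits = cross_hits(
        reference_proteome,
        panel.proteins,
        scheme=scheme,
        thresholds=FilterThresholds(min_score=0.0, max_evalue=link_evalue),
        prefilter_k=prefilter_k,
        max_evalue_override=link_evalue,
        strict_evalue=True,
    )
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    return [(q, s, e) for (q, s), e in sorted(best.items())]


def write_conservation_tsv(report: ConservationReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
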