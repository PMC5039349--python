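"""Synthetic pan-genome panels with known family structure.

Generates genome panels whose gene families are planted as core (present in
every genome), dispensable (present in 2..N-1 genomes) or strain-specific
(one genome), with within-family sequence divergence and optional
within-genome paralog duplications. The generator is the ground truth for
every downstream stage: family ancestors are drawn uniformly over the 20
residues, which keeps unrelated families far apart in sequence space so that
truth recovery is well posed at desk scale.

All randomness flows through one ``numpy.random.Generator`` seeded from a
single integer, so identical parameters give byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import AMINO_ACIDS, GenomePanel, ProteinRecord, write_protein_fasta

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the planted pan-genome model.

    ``dispensable_spec`` lists (occupancy k, family count) pairs with
    2 <= k <= n_genomes - 1. ``divergence`` is the per-site substitution
    probability applied independently to every family member relative to the
    family ancestor; ``paralog_rate`` is the per-occupying-genome probability
    of a second, further-diverged copy.
    """

    n_genomes: int = 14
    n_core: int = 200
    dispensable_spec: tuple[tuple[int, int], ...] = ()
    n_specific_per_genome: int = 3
    protein_length: int = 120
    divergence: float = 0.03
    paralog_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must lie in [0, 1)")
        if min(self.n_core, self.n_specific_per_genome, self.protein_length) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.paralog_rate <= 1.0:
            raise ValueError("paralog_rate must lie in [0, 1]")
        for k, count in self.dispensable_spec:
            if not 2 <= k <= self.n_genomes - 1:
                raise ValueError(
                    f"dispensable occupancy {k} outside 2..{self.n_genomes - 1}"
                )
            if count < 0:
                raise ValueError("dispensable family count must be >= 0")


@dataclass
class FamilyTruth:
    family_id: str
    family_class: str  # core | dispensable | specific
    member_ids: list[str]
    occupancy: set[str]


@dataclass
class SyntheticTruth:
    """Planted family membership: the answer key for the recovered partition."""

    families: dict[str, FamilyTruth]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam in self.families.values():
            for pid in fam.member_ids:
                if pid in seen:
                    raise ValueError(f"protein {pid!r} assigned to two families")
                seen.add(pid)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {"core": 0, "dispensable": 0, "specific": 0}
        for fam in self.families.values():
            counts[fam.family_class] += 1
        return counts

    def family_of(self) -> dict[str, str]:
        """protein_id -> family_id lookup."""
        return {
            pid: fid for fid, fam in self.families.items() for pid in fam.member_ids
        }

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family_id\tclass\tprotein_id\tgenome_id\n")
            for fid in sorted(self.families):
                fam = self.families[fid]
                for pid in fam.member_ids:
                    gid = pid.rsplit("|", 1)[0]
                    fh.write(f"{fid}\t{fam.family_class}\t{pid}\t{gid}\n")


def random_protein(length: int, rng: np.random.Generator) -> str:
    """An i.i.d.-uniform random sequence over the 20 residues."""
    return _AA[rng.integers(0, len(_AA), size=length)].tobytes().decode()


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``divergence``.

    Replacements are drawn uniformly from the 19 other residues, so at
    divergence approaching 1 the expected identity to the input approaches
    the 1/20 background of unrelated sequences.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    if divergence == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    n_hit = int(hit.sum())
    if n_hit:
        # draw index among the 19 residues != current one
        cur_idx = np.searchsorted(_AA, arr[hit])
        offset = rng.integers(0, len(_AA) - 1, size=n_hit)
        new_idx = np.where(offset >= cur_idx, offset + 1, offset)
        arr[hit] = _AA[new_idx]
    return arr.tobytes().decode()


def generate_panel(params: SimulationParams) -> tuple[GenomePanel, SyntheticTruth]:
    """Generate a panel and its planted family truth.

    For every family an ancestor is drawn uniformly at the configured length;
    each occupying genome gets a diverged copy, and with probability
    ``paralog_rate`` a second copy diverged from the genome's own copy (the
    inparalog convention: duplicates are closer to their within-genome sibling
    than to out-of-genome orthologs).
    """
    rng = np.random.default_rng(params.seed)
    genomes = [f"G{i:02d}" for i in range(1, params.n_genomes + 1)]
    per_genome_counter = {g: 0 for g in genomes}
    proteins: list[ProteinRecord] = []
    families: dict[str, FamilyTruth] = {}

    def next_pid(genome: str) -> str:
        per_genome_counter[genome] += 1
        return f"{genome}|p{per_genome_counter[genome]:05d}"

    def plant_family(fid: str, fclass: str, occupying: list[str]) -> None:
        ancestor = random_protein(params.protein_length, rng)
        members: list[str] = []
        for genome in occupying:
            seq = mutate_sequence(ancestor, params.divergence, rng)
            pid = next_pid(genome)
            proteins.append(
                ProteinRecord(pid, genome, seq, product=f"{fclass} family {fid}")
            )
            members.append(pid)
            if rng.random() < params.paralog_rate:
                dup = mutate_sequence(seq, params.divergence, rng)
                dup_id = next_pid(genome)
                proteins.append(
                    ProteinRecord(
                        dup_id, genome, dup, product=f"{fclass} family {fid} paralog"
                    )
                )
                members.append(dup_id)
        families[fid] = FamilyTruth(fid, fclass, members, set(occupying))

    fam_no = 0
    for _ in range(params.n_core):
        fam_no += 1
        plant_family(f"F{fam_no:05d}", "core", genomes)
    for k, count in params.dispensable_spec:
        for _ in range(count):
            fam_no += 1
            idx = rng.choice(params.n_genomes, size=k, replace=False)
            occupying = [genomes[i] for i in sorted(idx)]
            plant_family(f"F{fam_no:05d}", "dispensable", occupying)
    for genome in genomes:
        for _ in range(params.n_specific_per_genome):
            fam_no += 1
            plant_family(f"F{fam_no:05d}", "specific", [genome])

    truth = SyntheticTruth(families)
    expected = (
        params.n_core
        + sum(c for _, c in params.dispensable_spec)
        + params.n_genomes * params.n_specific_per_genome
    )
    assert len(truth.families) == expected
    for fam in truth.families.values():
        if fam.family_class == "core":
            assert fam.occupancy == set(genomes)
        elif fam.family_class == "specific":
            assert len(fam.occupancy) == 1
        else:
            assert 2 <= len(fam.occupancy) <= params.n_genomes - 1
    return GenomePanel(genomes=genomes, proteins=proteins), truth


def uniform_dispensable_spec(
    n_genomes: int, total: int, occupancies: range | None = None
) -> tuple[tuple[int, int], ...]:
    """Spread ``total`` dispensable families as evenly as possible over the
    given occupancy levels (default 2..N-1)."""
    if occupancies is None:
        occupancies = range(2, n_genomes)
    levels = list(occupancies)
    base, extra = divmod(total, len(levels))
    return tuple(
        (k, base + (1 if i < extra else 0)) for i, k in enumerate(levels)
    )


def write_panel_fastas(panel: GenomePanel, outdir: str | Path) -> dict[str, Path]:
    """One FASTA per genome, named ``<genome_id>.faa``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for genome in panel.genomes:
        path = outdir / f"{genome}.faa"
        write_protein_fasta(panel.proteins_of(genome), path)
        paths[genome] = path
    return paths


def recovery_accuracy(groups, truth: SyntheticTruth) -> float:
    """Fraction of planted families recovered exactly as one group.

    A family counts as correctly recovered (and hence correctly classified,
    since occupancy — and so the core/dispensable/specific label — is a
    function of the member set) iff some recovered group's member set equals
    the family's member set exactly.
    """
    group_of: dict[str, frozenset[str]] = {}
    for g in groups:
        members = frozenset(g.members)
        for m in members:
            group_of[m] = members
    correct = 0
    for fam in truth.families.values():
        members = frozenset(fam.member_ids)
        if group_of.get(fam.member_ids[0]) == members:
            correct += 1
    return correct / len(truth.families)
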