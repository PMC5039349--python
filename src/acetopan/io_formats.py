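"""Readers and writers for the external formats the pipeline touches.

Protein FASTA, 12-column BLAST tabular similarity, TSV presence/absence
matrices, Newick trees, TSV term-annotation maps and JSON result bundles.
Genome identity is supplied by the caller (one FASTA per genome), never
parsed out of headers.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

#: The 20 canonical residues plus the ambiguity placeholder X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

#: Ambiguity codes folded into X (B = D/N, Z = E/Q, U = selenocysteine,
#: J = I/L, O = pyrrolysine).
_AMBIGUOUS = {"B", "Z", "U", "J", "O"}

BLAST_COLUMNS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class BlastTabularParseError(ValueError):
    """Malformed 12-column BLAST tabular input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its genome of origin and annotation."""

    protein_id: str
    genome_id: str
    sequence: str
    product: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: characters outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )


@dataclass
class GenomePanel:
    """An ordered collection of genomes and their proteomes."""

    genomes: list[str]
    proteins: list[ProteinRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        genome_set = set(self.genomes)
        for rec in self.proteins:
            if rec.protein_id in seen:
                raise ValueError(f"duplicate protein_id {rec.protein_id!r} in panel")
            seen.add(rec.protein_id)
            if rec.genome_id not in genome_set:
                raise ValueError(
                    f"protein {rec.protein_id!r} references unknown genome "
                    f"{rec.genome_id!r}"
                )

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def by_id(self) -> dict[str, ProteinRecord]:
        return {rec.protein_id: rec for rec in self.proteins}

    def proteins_of(self, genome_id: str) -> list[ProteinRecord]:
        return [rec for rec in self.proteins if rec.genome_id == genome_id]

    def total_residues(self) -> int:
        return sum(len(rec.sequence) for rec in self.proteins)


@dataclass(frozen=True)
class SimilarityHit:
    """A filtered directional similarity hit between two proteins.

    ``raw_score`` is in substitution-matrix units; it is None when the hit
    was imported from tabular output that carries only the bit score.
    """

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    identity_fraction: float
    raw_score: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.raw_score is not None and self.raw_score < 0:
            raise ValueError("raw_score must be >= 0")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction must lie in [0, 1]")
        if self.query_id == self.subject_id:
            raise ValueError(f"self-hit {self.query_id!r} is not a valid hit")


def _clean_sequence(seq: str, protein_id: str) -> str:
    seq = seq.upper()
    if any(c in _AMBIGUOUS for c in seq):
        warnings.warn(
            f"protein {protein_id!r}: ambiguity codes mapped to X", stacklevel=3
        )
        seq = "".join("X" if c in _AMBIGUOUS else c for c in seq)
    return seq


def read_protein_fasta(path: str | Path, genome_id: str) -> list[ProteinRecord]:
    """Read one genome's protein FASTA into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes ``protein_id``; the
    remainder of the header line becomes the product annotation.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip():
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:40]!r}"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(io.StringIO(text), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein_id {pid!r}")
        seen.add(pid)
        product = entry.description[len(entry.id):].strip()
        seq = _clean_sequence(str(entry.seq), pid)
        if not seq:
            raise ValueError(f"{path}: empty sequence for protein {pid!r}")
        records.append(ProteinRecord(pid, genome_id, seq, product))
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.protein_id}"
            if rec.product:
                header += f" {rec.product}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_panel_fasta_dir(paths: Mapping[str, str | Path]) -> GenomePanel:
    """Assemble a panel from a ``genome_id -> fasta path`` mapping."""
    genomes = list(paths)
    proteins: list[ProteinRecord] = []
    for gid in genomes:
        proteins.extend(read_protein_fasta(paths[gid], gid))
    return GenomePanel(genomes=genomes, proteins=proteins)


def read_blast_tabular(path: str | Path) -> list[SimilarityHit]:
    """Read 12-column BLAST tabular (outfmt 6) similarity hits.

    Extra trailing columns are ignored with a warning; raw scores are left
    unset because the tabular dialect only carries bit scores.
    """
    path = Path(path)
    hits: list[SimilarityHit] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastTabularParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if len(fields) > 12 and not warned_extra:
                warnings.warn(f"{path}: extra columns beyond 12 ignored")
                warned_extra = True
            try:
                pident = float(fields[2])
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise BlastTabularParseError(
                    f"{path}: line {lineno}: non-numeric field: {exc}"
                ) from None
            hits.append(
                SimilarityHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    bit_score=bits,
                    evalue=evalue,
                    identity_fraction=pident / 100.0,
                )
            )
    return hits


def write_blast_tabular(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the conventional 12-column tabular dialect.

    Alignment coordinates are not tracked by the pipeline, so positional
    columns are emitted as the full-length placeholders BLAST-style
    consumers ignore.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_fraction * 100.0:.2f}",
                        "0", "0", "0", "0", "0", "0", "0",
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree as Newick with branch lengths (6 significant digits)."""
    for leaf in tree.tips():
        if not leaf.name:
            raise ValueError("tree contains an unlabeled leaf")
    out = tree_to_newick(tree)
    Path(path).write_text(out + "\n")


def _needs_quoting(label: str) -> bool:
    return any(c in label for c in " \t()[]':;,")


def _format_length(length: float | None) -> str:
    if length is None:
        return ""
    text = f"{length:.6g}"
    if "." not in text and "e" not in text and "n" not in text:
        text += ".0"
    return f":{text}"


def tree_to_newick(tree: TreeNode) -> str:
    """Render a skbio TreeNode as a Newick string, quoting labels that
    contain Newick metacharacters."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            name = node.name or ""
            if _needs_quoting(name):
                name = "'" + name.replace("'", "''") + "'"
            return name + _format_length(node.length)
        inner = ",".join(render(c) for c in node.children)
        label = node.name or ""
        return f"({inner}){label}" + _format_length(node.length)

    return render(tree) + ";"


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_presence_absence_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="group_id")


def read_presence_absence_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="group_id")


def read_term_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column (gene_id, term_id) TSV into ``term -> gene set``."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            gene, term = fields[0], fields[1]
            terms.setdefault(term, set()).add(gene)
    return terms


def write_json_bundle(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
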