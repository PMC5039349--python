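"""All-vs-all protein similarity with local alignment and E-value filtering.

Pairwise scores are optimal Smith-Waterman local alignment scores under
BLOSUM62 with affine gaps (a length-L gap costs gap_open + L*gap_extend).
Raw scores are converted to E-values and bit scores with the Karlin-Altschul
formula E = K * m*n * exp(-lambda * S), using the conventional
gapped-BLOSUM62 constants lambda = 0.267, K = 0.041, and the panel's total
residue count squared as the effective search space. Hits are kept when the
raw score is at least 50 and the E-value at most 1e-10 (both boundaries
inclusive).

An exact k-mer prefilter (default k = 4) restricts alignment to pairs that
share at least one k-mer; at the divergences where a pair could pass the
score/E-value filter this never loses a hit, and it makes desk-scale
all-vs-all runs feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import GenomePanel, ProteinRecord, SimilarityHit

LAMBDA_GAPPED_BLOSUM62 = 0.267
K_GAPPED_BLOSUM62 = 0.041


def _blosum62_x_neutral():
    """BLOSUM62 with X scoring 0 against everything (ambiguity-neutral)."""
    m = substitution_matrices.load("BLOSUM62")
    arr = m.copy()
    if "X" in m.alphabet:
        xi = m.alphabet.index("X")
        for j in range(len(m.alphabet)):
            arr[xi, j] = 0.0
            arr[j, xi] = 0.0
    return arr


@dataclass
class ScoringScheme:
    """Alignment scoring and E-value parameters."""

    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = LAMBDA_GAPPED_BLOSUM62
    karlin_k: float = K_GAPPED_BLOSUM62
    search_space: float | None = None
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        self._matrix = _blosum62_x_neutral()

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self._matrix
        # first gap residue costs open+extend, later residues extend each
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def with_search_space(self, m: int, n: int) -> "ScoringScheme":
        out = ScoringScheme(
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            karlin_lambda=self.karlin_lambda,
            karlin_k=self.karlin_k,
            search_space=float(m) * float(n),
            matrix_name=self.matrix_name,
        )
        return out


@dataclass(frozen=True)
class FilterThresholds:
    """The hit filter: raw score >= min_score and E-value <= max_evalue."""

    min_score: float = 50.0
    max_evalue: float = 1e-10

    def __post_init__(self) -> None:
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


def local_align_score(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> float:
    """Optimal Smith-Waterman local alignment score (0 for empty input)."""
    if not a or not b:
        return 0.0
    scheme = scheme or ScoringScheme()
    return float(scheme.make_aligner().score(a, b))


def evalue_and_bits(raw_score: float, scheme: ScoringScheme) -> tuple[float, float]:
    """Karlin-Altschul E-value and bit score for a raw alignment score."""
    if scheme.search_space is None or scheme.search_space <= 0:
        raise ValueError("scheme.search_space must be set and positive")
    evalue = scheme.karlin_k * scheme.search_space * math.exp(
        -scheme.karlin_lambda * raw_score
    )
    bits = (scheme.karlin_lambda * raw_score - math.log(scheme.karlin_k)) / math.log(2)
    return evalue, bits


def passes_filter(hit: SimilarityHit, thresholds: FilterThresholds) -> bool:
    """True iff raw_score >= min_score and evalue <= max_evalue (inclusive)."""
    if hit.raw_score is None:
        raise ValueError("hit carries no raw score; cannot apply the score filter")
    return hit.raw_score >= thresholds.min_score and hit.evalue <= thresholds.max_evalue


def _identity_fraction(aligner: PairwiseAligner, a: str, b: str) -> float:
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return 0.0
    return counts.identities / aligned


def _kmer_candidate_pairs(
    records: Sequence[ProteinRecord], k: int
) -> set[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        seq = rec.sequence
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(i)
    pairs: set[tuple[int, int]] = set()
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        uniq = sorted(set(bucket))
        for ai in range(len(uniq)):
            for bi in range(ai + 1, len(uniq)):
                pairs.add((uniq[ai], uniq[bi]))
    return pairs


def all_vs_all(
    panel: GenomePanel,
    scheme: ScoringScheme | None = None,
    thresholds: FilterThresholds | None = None,
    prefilter_k: int | None = 4,
) -> list[SimilarityHit]:
    """All-vs-all similarity over a panel, returning filtered directional hits.

    Every unordered pair sharing at least one exact k-mer is aligned once
    (Smith-Waterman is symmetric), self-hits are excluded, and surviving hits
    are emitted in both directions with identical raw score. Pass
    ``prefilter_k=None`` to align every pair (the brute-force oracle path).
    """
    scheme = scheme or ScoringScheme()
    thresholds = thresholds or FilterThresholds()
    records = sorted(panel.proteins, key=lambda r: r.protein_id)
    total = sum(len(r.sequence) for r in records)
    scheme = scheme.with_search_space(total, total)
    aligner = scheme.make_aligner()

    if prefilter_k is None:
        candidates = {
            (i, j) for i in range(len(records)) for j in range(i + 1, len(records))
        }
    else:
        candidates = _kmer_candidate_pairs(records, prefilter_k)

    hits: list[SimilarityHit] = []
    for i, j in sorted(candidates):
        a, b = records[i], records[j]
        raw = float(aligner.score(a.sequence, b.sequence))
        if raw < thresholds.min_score:
            continue
        evalue, bits = evalue_and_bits(raw, scheme)
        if evalue > thresholds.max_evalue:
            continue
        ident = _identity_fraction(aligner, a.sequence, b.sequence)
        hits.append(
            SimilarityHit(a.protein_id, b.protein_id, bits, evalue, ident, raw)
        )
        hits.append(
            SimilarityHit(b.protein_id, a.protein_id, bits, evalue, ident, raw)
        )
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def cross_hits(
    queries: Iterable[ProteinRecord],
    subjects: Iterable[ProteinRecord],
    scheme: ScoringScheme | None = None,
    thresholds: FilterThresholds | None = None,
    prefilter_k: int | None = 4,
    max_evalue_override: float | None = None,
    strict_evalue: bool = False,
) -> list[SimilarityHit]:
    """Filtered hits from one protein set against another (e.g. panel vs
    outgroup proteomes, or reference pathway proteins vs panel).

    ``max_evalue_override`` relaxes or tightens only the E-value ceiling
    (used for the looser reference-linking threshold); ``strict_evalue``
    makes the ceiling exclusive (E strictly below the ceiling).
    """
    scheme = scheme or ScoringScheme()
    thresholds = thresholds or FilterThresholds()
    max_e = thresholds.max_evalue if max_evalue_override is None else max_evalue_override
    qrecs = sorted(queries, key=lambda r: r.protein_id)
    srecs = sorted(subjects, key=lambda r: r.protein_id)
    m = sum(len(r.sequence) for r in qrecs)
    n = sum(len(r.sequence) for r in srecs)
    scheme = scheme.with_search_space(m, n)
    aligner = scheme.make_aligner()

    if prefilter_k is not None:
        sindex: dict[str, set[int]] = {}
        for j, rec in enumerate(srecs):
            seq = rec.sequence
            for pos in range(len(seq) - prefilter_k + 1):
                sindex.setdefault(seq[pos : pos + prefilter_k], set()).add(j)

    hits: list[SimilarityHit] = []
    for q in qrecs:
        if prefilter_k is None:
            cand = range(len(srecs))
        else:
            seen: set[int] = set()
            seq = q.sequence
            for pos in range(len(seq) - prefilter_k + 1):
                seen |= sindex.get(seq[pos : pos + prefilter_k], set())
            cand = sorted(seen)
        for j in cand:
            s = srecs[j]
            if q.protein_id == s.protein_id:
                continue
            raw = float(aligner.score(q.sequence, s.sequence))
            if raw < thresholds.min_score:
                continue
            evalue, bits = evalue_and_bits(raw, scheme)
            if (evalue >= max_e) if strict_evalue else (evalue > max_e):
                continue
            ident = _identity_fraction(aligner, q.sequence, s.sequence)
            hits.append(SimilarityHit(q.protein_id, s.protein_id, bits, evalue, ident, raw))
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits
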