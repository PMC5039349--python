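# Methods

## Similarity model

Pairwise protein similarity is the optimal Smith-Waterman local alignment
score under BLOSUM62 with affine gap costs: a gap of length L costs
`gap_open + L * gap_extend` (defaults 11 and 1, the usual protein-search
convention). The ambiguity residue X scores 0 against everything, and the
ambiguity codes B/Z/U/J/O are folded into X on input with a warning.
Alignment is delegated to Biopython's `PairwiseAligner` in local mode; the
worked self-alignment of `ACDEFGHIKL` (the sum of the ten BLOSUM62
diagonal entries, 57) pins the configuration in the tests.

Raw scores S are converted to E-values with the Karlin-Altschul formula
`E = K · m·n · exp(−λS)` and to bit scores with
`S' = (λS − ln K) / ln 2`. λ = 0.267 and K = 0.041 — the conventional
gapped-BLOSUM62 constants — are defaults, not fitted values, and are
configurable. The effective search space m·n is the product of total query
and subject residue counts for the compared sets (the panel's total
squared for all-vs-all). These choices stand in for whatever external
search tool a user might otherwise run; externally produced 12-column
tabular hits are accepted as a drop-in replacement.

Hits are kept when raw score ≥ 50 **and** E ≤ 10⁻¹⁰, both boundaries
inclusive. The score threshold is read as a raw alignment score; a
bit-score reading is available through configuration. The separate
reference-linking threshold used in pathway maps (E < 10⁻⁶) is strict,
matching its "less than" definition, and independent of the clustering
filter.

### k-mer prefilter

All-vs-all alignment is restricted to protein pairs sharing at least one
exact k-mer (default k = 4). For pairs that could pass the E ≤ 10⁻¹⁰
filter the required alignment score implies long near-identical stretches,
so the prefilter loses nothing; this is not assumed but verified in the
tests, where prefiltered all-vs-all equals brute-force all-pairs alignment
on panels of up to 50 proteins. The prefilter is what makes a
~3,800-protein panel alignable in about a minute and a half on one core.

## Ortholog grouping

Directional bit scores are symmetrised into an undirected homology graph;
an edge's weight is the mean of its two directional bit scores (a lone
direction keeps its score). Bit scores rather than −log₁₀E are the default
weight because they are length-normalised and finite; the E-value
transform is available as an option.

Markov clustering runs on the column-stochastic matrix with self-loops set
to each node's maximum incident edge weight (a standard regularisation),
alternating expansion (matrix squaring) and inflation (elementwise power,
default 1.5, then column renormalisation) until the maximum entry change
falls below 10⁻⁶ or 200 iterations pass (non-convergence warns and reads
clusters from the final matrix). Clusters are read off attractor rows;
nodes claimed by several attractors go to the one holding the larger mass,
then to the lexicographically smaller protein id, so every protein lands
in exactly one group. Because expansion and inflation never mix
disconnected components, clustering is computed independently per
connected component on dense submatrices — exact, and fast for
family-sized components. Isolated proteins become singleton groups.

Within a group, each genome with several members gets the seed-ortholog
treatment: the member with the strongest link to another genome is the
ortholog; a co-genome member closer to that seed than the seed is to any
other genome is an inparalog (a post-speciation duplicate); weaker
co-genome members remain orthologs (retained ancient paralogs). All ties
break lexicographically by protein id, so runs are bit-reproducible.

## Partitioning and outgroup subtraction

The presence/absence matrix collapses paralogs to a single 1 per genome.
With N genomes, occupancy N is core, 1 is strain-specific, and 2..N−1 is
dispensable (full occupancy is excluded from "dispensable" so the classes
partition the groups). Group counts count families once; gene counts count
members, paralogs included — this is forced by the arithmetic of core
families averaging tens of genes over a dozen genomes. Annotation status
is keyword-based on product strings: "hypothetical" → hypothetical; empty,
"unknown" or "uncharacterized" → unknown; anything else → annotated.

Outgroup subtraction removes a core group as soon as **any** member hits
**any** outgroup protein at the same score/E-value thresholds used for
clustering (any-member-any-hit semantics; a majority-of-members variant is
a documented alternative). The retained set is the lineage-specific core.
An empty outgroup set is an error rather than a silent no-op, and adding
outgroups can only shrink the retained set.

The packaged 23-row genome table records strain, genome size, GC%, gene
and CDS counts, and whether the strain belongs to the 14-strain analysis
panel. Note that the printed mean size (3.8 Mb) and mean GC (38.5%) are
means over all 23 rows, while the GC range 29.1–55.8% is the range over
the 14 analysis strains (the full table spans 28.7–55.9%); `table_stats`
is deliberately generic over any row subset so both readings are
computable.

## Pan-genome tree

Genome-to-genome distance is the Jaccard distance between occupied-group
sets, `d = 1 − |A∩B| / |A∪B|`, computed from the full pan-genome
presence/absence profile. Classical neighbor joining then minimises
`Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)` with the standard
branch-length formulas; ties in Q break lexicographically on the smallest
leaf label under each candidate node. Negative branch-length estimates are
clamped to zero with the deficit shifted to the sibling branch, preserving
path lengths. On additive inputs the generating tree is recovered to
machine precision (asserted in tests, cross-checked against scikit-bio's
NJ). The tree is unrooted and serialised with a trifurcating root; no
bootstrap support is computed.

## Enrichment and term grouping

Over-representation of a term with K universe genes in a study set of n
genes (universe N) is the hypergeometric upper tail
`P(X ≥ k) = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)` (scipy's survival function;
an exact rational-arithmetic enumeration serves as the test oracle).
Only terms with at least one universe gene are tested; Bonferroni
multiplies by the number of tested terms, and significance is
`p_adj < α` strictly (default α = 0.05). Only enrichment, not depletion,
is tested. The default universe is the set of genes carrying at least one
term, configurable.

Redundancy between significant terms is Cohen's kappa over their
gene-membership indicator vectors: `κ = (Po − Pe)/(1 − Pe)` from the 2×2
co-membership table, with κ defined as 1 when both terms cover the whole
universe. Terms are grouped as connected components of the graph with
edges at κ ≥ 0.4 (the usual enrichment-map default; configurable). This
is a deliberate simplification of iterative group-merging heuristics: it
is deterministic and order-independent while preserving the term→group
granularity of the output. Each group is led by its minimal-p_adj term,
ties lexicographic.

## Pathway conservation

The packaged pathway model lists enzymatic steps (Wood-Ljungdahl CO₂→
formate, methyl/carbonyl branches and acetate production; central carbon
metabolism; THF and molybdopterin cofactor biosynthesis) with gene
symbols, reference-protein placeholders, and — where the acetogen
literature states them — the strain counts observed on the 14-genome
panel, kept strictly as fixture expectations in a `reported_strains`
column. A genome "has" a step when any of its proteins hits one of the
step's reference proteins at the clustering thresholds, or shares an
ortholog group with a protein that does (group membership is primary;
direct hits are the fallback). Steps with no homolog anywhere are reported
in a separate absent list rather than classified.

Conservation classes: full occupancy is core; at least half the genomes is
"highly conserved dispensable" (>50% in the figure convention); below half
is "lesser conserved dispensable". The exact-50% boundary (7 of 14) is
assigned to the highly-conserved class (rule `count/N ≥ 0.5`); only the
two open intervals are named by the source convention, so the boundary is
a documented, configurable choice.

## Synthetic panels

The generator plants families with known class: core families occupy all
genomes, dispensable families occupy a random k-subset (2 ≤ k ≤ N−1, with
a helper spreading a total count evenly over occupancy levels), and
specific families one genome. Family ancestors are i.i.d. uniform over the
20 residues at a configurable length (default 120) — deliberately *not* a
natural amino-acid composition, to maximise inter-family distance and make
truth recovery well-posed at desk scale. Each occupying genome receives a
copy with independent per-site substitution at the divergence rate
(replacement uniform over the 19 other residues; no indels by default),
and with the paralog probability a second copy diverged from the genome's
own copy, mirroring the inparalog semantics of the labelling rule. All
randomness flows through one seeded generator; identical parameters give
byte-identical FASTA output.

What this emulates — and does not: the generator reproduces occupancy
structure, within-family divergence and recent duplications, but not
natural residue composition, low-complexity regions, domain sharing
between unrelated families, indels, or horizontal transfer. Passing
truth-recovery tests therefore demonstrates that the pipeline's machinery
is correct under clean homology signal, not that real proteomes cluster
this cleanly; on real data the MCL inflation and the score/E thresholds
carry the burden the generator's separation assumes away.

## Validation scale and determinism

The study-scale validation panel is 14 genomes with 200 core families, 100
dispensable families spread over occupancies 2–13, and 3 specific families
per genome (342 families, ~3,800 proteins with 5% paralog rate) at 3%
divergence — chosen to exercise paralogy and every occupancy level at a
size a laptop core handles in under two minutes. Recovery is scored as the
fraction of planted families recovered exactly as one group (which implies
the correct class, since class is a function of the member set). At these
settings recovery is 100%; the acceptance bar is ≥ 99% at 3% divergence
and exact at 0%.

Pipelines run from a single integer seed; identical config and seed yield
byte-identical output bundles (the manifest omits the output directory so
bundles are location-independent). Numerical tie-breaks are lexicographic
everywhere; MCL tolerance (10⁻⁶), the attractor threshold (10⁻⁷) and the
NJ tie tolerance (10⁻¹²) are the only numeric guards, all documented in
code.

## Known limitations

- No composition-based score adjustment or low-complexity masking; E-values
  on real proteomes will be more permissive than a modern search tool's.
- The MCL inflation default (1.5) follows pan-genome pipeline tradition;
  the clustering granularity of real panels may need tuning.
- The tree uses gene-content Jaccard distances only; sequence-based
  phylogenies are out of scope.
- Term annotations are taken as given (no GO-DAG propagation).
- The pathway model's reference proteins are symbolic placeholders
  resolved against whatever reference proteome the user supplies.
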