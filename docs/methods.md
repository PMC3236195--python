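# Methods

## The ortholog model

`panorth` is a pair-based ortholog inference system. It never builds gene
trees; orthology is asserted from sequence similarity, reciprocal-best-hit
structure and taxonomic position, trading some accuracy for a run time
that scales to large genome collections. Two assumptions underpin the
design:

1. **Conspecific genomes are collinear enough for synteny to
   disambiguate co-orthologs.** At species level, orthologs are called by
   bidirectional best hits resolved within syntenic blocks (longest
   first), each CDS pairing at most once. This deliberately yields a 1:1
   matching: when a genome carries two recent copies of a partner's gene,
   only the syntenic/best copy is paired and the other is left for the
   paralog machinery.
2. **A pan-genome is an adequate proxy for a taxon's full CDS
   collection.** Above species level, each taxon is represented by its
   child pan-genomes (singletons plus one representative per homolog
   group). Explicit ortholog pairs found between representatives are
   expanded onto all represented members ("implicit" pairs). The proxy is
   lossy — a poorly chosen representative can hide a family's similarity
   from higher levels — but it is what makes the comparison count shrink
   at exactly the ranks where collections grow.

A pair's recorded level always equals the lowest common ancestor rank of
its two genomes: species pairs come from conspecific BBH, rank-r pairs
from clustering the rank-r taxon's children, and implicit expansion only
combines members from different children.

## Alignment contract

All CDS-vs-CDS comparisons are exact Smith–Waterman local alignments in
protein space (Biopython's C aligner), BLOSUM62, affine gaps costing
`11 + g` for a gap of length `g` (the standard protein-search default).
Derived quantities:

* **identity** = identical column pairs / aligned columns, gap columns
  included in the denominator;
* **coverage** (also the "percent match" of the higher-level filters) =
  residues of the *shorter* sequence inside the alignment / shorter
  length;
* **e-value** = Karlin–Altschul `K·m·n·exp(−λS)` with the published
  gapped BLOSUM62 11/1 constants (λ = 0.267, K = 0.041) and the pairwise
  length product as search space. These are per-pair estimates, not
  database-calibrated BLAST values; they feed a fixed cutoff (1e-5), so
  only their monotone dependence on score and length matters.
* A hit is reported only when the optimal score reaches the **score
  floor** (default 40). This floor is the "no explicit threshold" cutoff
  of the paralog stage — some minimum is unavoidable, since every pair
  has *some* optimal local alignment.

Identity, coverage and score are symmetric under argument swap: the pair
is canonicalised internally before traceback, so co-optimal-alignment
ambiguity cannot produce direction-dependent results. An adapter for an
external search tool can replace the engine wherever hits are consumed,
provided its output respects the same invariants.

No seeding/word prefilter is used. A word filter that provably cannot
lose any hit passing 70/70 identity/coverage would need a word size of
two once gaps are allowed (run-length pigeonhole argument), which filters
essentially nothing; the exact score-only pass (cheap) followed by
traceback only above the floor was fast enough at the intended scales.

## Parameters

| parameter | default | units | notes |
| --- | --- | --- | --- |
| species ortholog cut | 70 / 70 | % identity / % coverage | inclusive |
| paralogy (homolog-group) cut | 90 / 90 | % | same-genome edges |
| orthology (homolog-group) cut | 70 / 70 | % | cross-genome edges |
| syntenic gap limit | 20 000 | nt | max inter-anchor gap in a chain |
| min peptide length | 33 | aa | higher-level candidate filter |
| max internal stop fraction | 2 | % | trailing stop never counted |
| e-value cutoff | 1e-5 | — | higher-level edge filter |
| percent-match cutoff | 65/60/55/50/45/40 | % | genus/family/order/class/phylum/domain |
| MCL inflation | 1.5 | — | lower = coarser clusters |
| core-genome occurrence | 90 | % of genomes | inclusive |
| openness permutations | 100 | — | genome-order resampling |
| fluidity share cut | 70 / 70 | % | same as the orthology cut |

All of these are configurable (YAML config / function arguments); none is
hard-coded at call sites.

## Markov clustering

The similarity graph for a taxon (nodes: admissible child pan-genome
entries; edges: e-value and percent-match filtered hits, weight
−log₁₀(e-value) capped at 300) is reduced to inter-taxon BBH pairs plus
in-paralogs — within-taxon edges at least as heavy as either endpoint's
best cross-taxon edge, in components containing a BBH member. MCL then
alternates expansion (matrix squaring) and inflation (entry-wise power
1.5, column renormalisation), pruning entries below 1e-5, until the
maximum entry change is below 1e-6 or 100 iterations (non-convergence
warns and returns the current interpretation). Self-loops are set to each
node's maximum incident weight before normalisation, which stabilises
attractors. Clusters are the connected components of the limit matrix's
support; columns remain stochastic to 1e-9 after every step, and
disconnected components can never merge (expansion preserves block
structure). One deliberate simplification relative to classic OrthoMCL:
the per-species edge-weight normalisation stage is omitted; the effect is
small when child taxa are sampled comparably, and the hook to add it is a
single transformation of the edge weights.

## Plasticity

The new-CDS series adds genomes in random order and counts, at each
position N ≥ 2, incoming CDSs with no 70/70 hit in any earlier genome.
The "no paralogs (90/90)" clause is read as *within the incoming genome*:
a novel duplicated gene counts once (a switch restores the alternative
reading). All pairwise hit sets are computed once, so the 100
permutations cost set operations only. The per-N medians are fitted with
ordinary least squares on (log N, log n) — exactly what a spreadsheet
power trendline computes — over points with n > 0; α is the negated
slope, κ the exponentiated intercept, and R² is reported from the same
regression. A series that is identically zero is classified closed with
α = ∞ (sentinel) and κ = 0. The open/closed comparison α ≤ 1 vs α > 1
uses a 1e-9 tolerance to absorb regression round-off on exactly-boundary
input. Fluidity uses best-hit sharing at the 70/70 cut (the natural reuse
of the orthology cut; a gene-family formulation would require the
grouping machinery and is intentionally not what this statistic reports).
With an even number of genome pairs the median is the mean of the two
central values.

## The synthetic clade

The generator emulates: vertical descent with uniform residue
substitution at a per-branch divergence (default 2%), gene gain and loss
(default 5% per branch each), optional duplication (default 0), and
synteny (genes laid along one contig in label order; a shuffle switch
breaks it). Defaults follow the reference study conditions for the
simulated clade: 2 genera × 2 species × 2 genomes, 200 ancestral genes,
protein lengths uniform in 50–150 aa. Because substitutions are uniform,
expected identity between genomes separated by branches d₁…dₘ is
analytically ∏(1−dᵢ) plus a small back-mutation term — convenient for
threshold-crossing tests.

It does **not** emulate: indels, codon structure, substitution-matrix
biased replacement, horizontal transfer, rearrangements beyond the
shuffle switch, or annotation error. Passing tests therefore demonstrate
the machinery (matching, clustering, expansion, counting) under clean
conditions, not robustness to real annotation noise or HGT.

The duplication default of zero reflects the species-ortholog contract:
the 1:1 BBH matching cannot recover all co-ortholog truth pairs once
within-species duplicates exist, so the headline recovery conditions
treat turnover as gain + loss and exercise duplication in dedicated
tests instead.

Two analytic fixtures support the plasticity statistics. The fluidity
fixture builds genomes of sizes (12, 8) with 8 byte-identical shared
CDSs and unique CDSs rejection-sampled below 40% pairwise identity, so
U_k = 4, U_l = 0 and the fluidity is exactly (4+0)/(12+8) = 0.2. The
openness fixture must produce a power-law *median* curve under the
random orderings the estimator prescribes; per-genome unique gene counts
cannot do that (the genome at position N is uniform over genomes, making
the median flat), so instead each accessory gene is assigned a random
genome subset, with occupancy counts solved by non-negative least
squares against the first-occurrence kernel C(G−N, k−1)/C(G, k). The
expected new-CDS curve then follows κ·N^(−α) under any ordering.

## Numerical and tie-breaking choices

* Canonical pair order is lexicographic on CDS id; pair sets compare as
  sets.
* Best-hit ties: higher score, then higher identity, then smallest
  partner id. Block ties: length desc, then (contig_a, contig_b,
  start_a). Representative ties: larger ortholog count, then longer
  protein, then smallest id. These invented tie-breaks are what make
  pan-genome construction byte-identical under genome input permutation.
* Coordinates are 1-based inclusive; trailing stop symbols are stripped
  before alignment but preserved on disk.
* Six-frame translation uses the standard code, `X` for ambiguous
  codons, `*` for stops; the rescue search aligns frames independently
  (no frameshift stitching), so a frameshifted gene shows up as a
  partial-coverage hit — a documented limitation, not a bug.

## Problem sizes in the test suite

The reference clade for recovery tests uses 200 ancestral genes over 8
genomes (~1,600 CDSs, ~0.6 M pairwise comparisons, about a minute on one
CPU); structural tests reuse a 30-gene clade, and the openness end-to-end
check uses 6 genomes with ~45 genes each and 50 permutations. These
sizes keep every statistic well away from its acceptance margin while
the whole suite stays in the minutes range.

## Known limitations

* E-values are per-pair estimates; absolute values differ from
  database-corrected BLAST e-values (the fixed cutoff compensates in
  practice).
* Representative choice is greedy per level; a distinct-but-related
  family can be split if its representative drifts (the classic failure
  mode of proxy-based schemes, visible in real data as split ribosomal
  protein families).
* Synteny chaining is greedy (not LIS-optimal); adequate for prokaryotic
  gene orders and the constructed fixtures, but a heavily rearranged
  pair may fragment into more blocks than necessary.
* No HGT modelling: mobile elements will be called orthologous when they
  satisfy the similarity criteria.
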