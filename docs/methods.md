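# Methods

This note documents the models, parameter choices and numerical
conventions behind `cvescreen`, and what the synthetic benchmarks do and
do not demonstrate.

## Translated search

Contigs are translated in all six conceptual frames under the standard
genetic code; any codon containing a non-ACGT character yields `X`, and
trailing partial codons are dropped. IUPAC ambiguity codes other than N
are collapsed to N at FASTA ingestion. Coordinates are 0-based half-open
on the forward strand everywhere inside the package; GFF3 export converts
to 1-based inclusive.

Probe-vs-frame matching uses exact local alignment (Gotoh affine-gap
Smith–Waterman, via Biopython's `PairwiseAligner`) rather than a seeded
heuristic. Exactness costs little at the scales this package targets and
buys two things: bit-level determinism, and oracle-testability — the test
suite checks alignment scores against an independently written dynamic
program, which is itself validated against an exhaustive enumeration of
all local alignments at tiny sizes.

Scoring defaults:

| parameter | default | rationale |
| --- | --- | --- |
| matrix | BLOSUM62 with X ↦ −1 vs everything | standard protein matrix; the X override keeps translated N-runs from seeding or extending matches |
| gap cost | 11 + k for a gap of length k | the conventional 11/1 affine penalty |
| `min_score` | 100 (raw score) | see below |

The reporting threshold is a raw alignment score, not an E-value;
Karlin–Altschul statistics are deliberately out of scope. The default of
100 was set so that chance matches are not expected at the package's
working scale: for a ~250 aa probe against random translated sequence,
the Karlin–Altschul estimate with gapped BLOSUM62 parameters
(λ ≈ 0.267, K ≈ 0.041) puts the expected number of chance matches in
10 Mb of double-stranded sequence below one only for scores above ~75–85,
and empirically the best chance score observed for a random probe against
2 Mb-equivalent of random translated sequence was 76. A screen of five
100 kb probe-assembly pairs at the default threshold produces zero hits
in the test suite. True matches are far above this threshold: even at 20%
amino-acid divergence a 200-codon element scores several hundred.

Multiple matches per frame are found by iterated masking: the best local
alignment is reported, its target span removed from the search space
(splitting the frame into sub-segments, so later matches can never
overlap or bridge earlier ones), and the search repeated until the best
remaining score drops below threshold. Score ties break toward the
smaller start coordinate, then '+' strand, then frame index.

## Classification (screen step 2)

The matched peptide (the contiguous translated target segment of the hit)
is scored against every reference; the best-scoring reference wins, ties
breaking to the lexicographically smaller id, and the hit inherits its
gene and group. The runner-up score is defined *cross-group* — the best
score among references of a different group — because its purpose is
confidence in the group assignment, not in the particular reference.
Extraction takes the hit span only; flanks are the annotation stage's
concern.

## Locus rules

Same-strand hits with a nucleotide gap ≤ `max_gap` (default 100) merge
into one locus; hits overlapping a higher-scoring retained hit within a
cluster are dropped as redundant-probe duplicates (so a locus's fragments
are non-overlapping; a dropped fragment can in principle shave a locus
boundary, which is acceptable because downstream truth comparisons are by
overlap). Merging is idempotent and never joins strands.

**Status.** `confirmed_cve` requires *both* flanks to exceed 3000 nt
strictly. The one-sided reading would confirm an element at a contig edge;
requiring both sides is the conservative choice for claiming germline
integration over contamination, and is applied uniformly to the truth
generator and the caller. Anything else is `unconfirmed` (potentially
derived from contaminating virus).

**Intactness.** A locus is intact when (i) its span is ≥ 200 nt (raw
span, alignment gaps not removed), (ii) all fragments lie in a single
reading frame — fragments in different frames imply a frameshifting indel
between them; frame identity is compared via the global frame index, so
gap length is accounted for automatically — and (iii) the translation of
the full span in that frame contains no internal stop (a stop in the
final codon counts as terminal). Translating the *full* span, gaps
included, is what makes a decayed element's premature stop visible even
when the alignment fragments themselves avoid it.

**Orthology and ids.** Two confirmed loci are orthologous when they share
gene and group and a same-side flank comparison (upstream-vs-upstream or
downstream-vs-downstream in locus orientation, 500 nt windows) reaches
0.7 global-alignment nucleotide identity (edlib edit distance over the
longer window). Orthology is the transitive closure of this relation.
Orthologous flanks at a few percent divergence sit near identity ≥ 0.9;
unrelated random flanks align near 0.4–0.5, so the 0.7 default separates
the two regimes widely. Ids follow `CVe-<Group>.<n>-<SpeciesCode>` with
`n` shared within an ortholog group, species codes taken from the input
manifest (auto-deriving codes from binomials invites collisions), and new
numbers allocated deterministically (groups ordered by their smallest
(species, contig, start) member) continuing from the registry maximum, so
ids are stable under re-runs and input reordering.

## Host-association analysis

Host-switch counting uses unordered, equal-cost parsimony. On binary
trees this is Fitch's algorithm; on multifurcations the package uses
Hartigan-style counting (each internal node keeps the states contained in
the maximum number k of child state sets and adds children − k to the
cost), which remains exact — the test suite verifies equality with
exhaustive enumeration over all internal labelings on hundreds of random
trees including polytomies. A pairwise-intersection generalization was
considered and rejected because it undercounts on polytomies (four
children {A},{A},{B},{B} cost 1 instead of the true 2).

*Host-label inflation* is fitch(all tips) − fitch(anchored tips only).
Pruning tips can never increase a parsimony minimum, so inflation ≥ 0;
a large value means the implied host switching is carried almost entirely
by metagenomic labels — the expected signature of cross-group sample
contamination.

*Conflict detection*: for each metagenomic tip, ascend to the smallest
ancestor with support > 70 containing at least one anchored tip; the root
qualifies regardless of support (otherwise trees whose roots carry no
support value could anchor nothing). The clade consensus is the majority
higher rank (via a caller-supplied rank map, e.g. host class →
vertebrate/invertebrate) among anchored tips; ties give "ambiguous" and
no flag. The rank map exists because the biologically defensible claim
level is coarse (arthropod vs vertebrate), while tip labels may be finer.

*Minimum ages*: each ortholog group constrains the MRCA of its tips to
the maximum divergence time among member host pairs; constraints
propagate rootward so every ancestor is at least as old as any
constrained descendant, giving a monotone non-increasing age profile
along any root-to-tip path. Trees are consumed as rooted inputs; no
branch-length dating is attempted.

## Synthetic data and what the benchmarks show

The generator emulates the features the pipeline's decisions depend on,
not genome realism. Host sequence is i.i.d. nucleotides at a set GC
(default 0.42); there are no repeats, isochores, or codon-usage biases.
Planted elements are back-translations (uniform synonymous codon choice)
of reference-derived peptides, spliced into the host sequence (displacing
it, as integration does), then decayed *post-insertion at the nucleotide
level*: a set proportion of codons replaced non-synonymously, an integer
number of premature stops at internal codons, and an integer number of
1–2 nt indels (edit positions kept ≥ 6 nt apart so each frameshift
produces a distinguishable frame segment). Truth labels are computed from
the realized sequence, never from the requested rates, and a validator
re-derives status/intactness from the emitted FASTA plus the recorded
frame-segment structure. Stop/frameshift counts are deterministic
(rounded) rather than Poisson draws so that boundary grids — flanks
2999/3000/3001 nt, spans 199/200 nt, exactly 0 or 1 stops and shifts —
are exactly realizable.

Default study conditions: 3 species × 2 rep-derived plants (220 aa ≙
660 nt) at 0.15 amino-acid substitution, flanks drawn uniformly from
2–8 kb so both status classes occur, one unrelated distractor element per
species, plus 20 kb background contigs. The reference library has three
rep groups (Circovirus/Cyclovirus at 0.35 from a common root, CRESS
further out, members at 0.08 within groups) and an unrelated cap family,
with one rep probe per group and one cap probe. Larger configurations
(~105 elements over 5 species with 0.8–1.5 kb flanks) are used where
accuracy percentages need denominators; these sizes keep the full test
suite and the acceptance script around a minute each on one CPU.

Labeled-tree simulation grows a random binary rooted tree, switches the
host label on exactly k distinct edges (so the realized labeling implies
exactly k changes and parsimony can be checked against a planted truth),
and duplicates a fraction of tips as metagenomic siblings: contaminants
get a wrong group label, clean duplicates keep the true one (the clean
fraction exists so the false-flag rate is measurable). Internal supports
default to 75–100, above the conflict threshold, so detection rates
measure the consensus logic rather than support sparsity.

Passing these benchmarks shows the machinery is correct under its own
assumptions — recall and classification on i.i.d. backgrounds, exact rule
application, exact parsimony, near-perfect contaminant flagging when
every clade is well supported. It does not show robustness to real-genome
features (repeats, low-complexity tracts, compositional bias), to real
BLAST-style heuristics, or to poorly supported phylogenies.

## Known limitations

- Raw-score thresholding only; no E-values, no composition-based score
  adjustment.
- Orthology rests on flank identity within a fixed window; ancient
  orthologs whose flanks have diverged past ~30% or been rearranged will
  split into separate groups.
- Intactness uses the raw merged span; a 200 nt threshold applied after
  gap removal would differ for heavily gapped alignments.
- Two loci of one ortholog group in the *same* species (tandem
  paralogs) would collide under the id convention and raise an error
  rather than being auto-disambiguated.
- The conflict test treats the root as maximally supported; on trees with
  rootward support erosion this is permissive.
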