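# Methods

This note documents the models, conventions, and numerical choices behind
`plastocomp`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Coordinates and gene names

All user-facing coordinates are 1-based inclusive (the GenBank
convention); algorithms convert to 0-based half-open slices internally.
Genomes are treated as circles: rotation of the deposited origin permutes
spacers and junction coordinates but leaves every derived quantity (region
lengths, locus multisets, boundary type) unchanged, and the test suite
asserts this.

Gene names are normalized before any cross-genome comparison: separators
are unified, tRNA anticodons are upper-cased with a hyphen (`trnL-UAG`),
canonical casing is restored from a bundled symbol table
(`data/gene_aliases.yaml`), and an alias map absorbs legacy names. The
trans-spliced rps12 gene is split into `rps12_5'` (exon 1) and `rps12_3'`
(exons 2–3), which are treated as distinct genic regions when extracting
spacers — without this the spacer inventory around rps12 is wrong.
Pseudogenes are excluded from gene counts but are treated as genic (not
spacer) territory during intergenic extraction, so that spacer boundaries
remain biological.

Intergenic regions are one per adjacent gene pair around the circle;
overlapping genes produce an empty region with a warning rather than an
error, because deposited annotations do contain genuine overlaps. With a
quadripartite partition available, a region lying wholly inside IRa whose
flanking-gene pair also occurs inside IRb is flagged as an IR duplicate;
the IRb copy is kept as the unique representative.

## Quadripartite structure

The inverted repeat is found as the longest pair of *disjoint*
reverse-complement segments. Along an ungapped reverse-complement match
the pairing constant c = i + j (position plus partner position, mod n) is
invariant; exact 20-mer anchors between the genome and its reverse
complement vote for candidate constants, and the best candidates are
evaluated by a full circular match scan. Because the partner map
t ↦ (c − t) mod n is an involution, maximal match runs come in disjoint
pairs (the IR) or map onto themselves (palindromic stretches, which are
skipped). The reported IR is the exact-match core: deposited plastome IRs
are perfect or within a handful of bases of perfect, and an exact core
keeps region lengths reproducible. The LSC is defined as the longer
single-copy arc, and IRb as the IR that follows it in forward orientation.
Genomes without an IR of at least `min_ir` (default 1,000 bp; some
lineages have lost the IR) raise `NoIRFound`.

### Junction typing

Published junction nomenclature (JSA/JSB) is used inconsistently across
the literature — the same junction is attached to different gene anchors
in different sentences. The typing rules therefore address junctions by
their anchor side: the LSC–IR junction near rps19/rpl2, the IR–SSC-side
junction nearer ndhF/trnN-GUU, and the SSC–IR-side junction nearer ycf1
(the assignment of the two SSC-flanking junctions to sides is decided by
proximity to ndhF). Junction context consults functional genes only:
IR-mirror pseudogene fragments (the ψycf1 fragment always ends exactly at
the IR–SSC boundary whenever ycf1 spans the SSC–IR junction, so including
it would make every Type I genome "junction inside ycf1" on both sides
and destroy the subtype contrast).

The default rule table (`data/boundary_rules.yaml`, first match wins)
encodes the common Type I organization (ycf1 spanning the SSC–IR
boundary) and its four subtypes as the 2×2 grid over {LSC–IR junction in
rps19 vs in the rps19–rpl2 spacer} × {IR–SSC-side junction in ndhF vs in
the trnN–ndhF spacer}. Exact predicates distinguishing rarer
organizations vary by study, so types II/III/V ship as coarse, editable
expansion/contraction defaults, and large-rearrangement types (VI, VII)
are deliberately not encoded — a junction profile alone cannot establish
synteny rearrangement. The JLA junction is recorded but unused in typing,
as IR boundary shifts at JLA are not a recognized typing dimension.

## Composition

Percentages are reported to two decimals with round-half-up. IUPAC
ambiguity codes count toward length but are excluded from base fractions,
so consensus-containing inputs do not distort GC. Codon-position
composition concatenates CDS parts in translation order (strand-aware),
skips genes whose coding length is not a multiple of three (with a
warning), and by default includes both IR copies of duplicated genes —
the convention that matches published per-position codon totals, which
exceed the unique CDS content.

## SSR scanning

For each unit size u ∈ 1..6 the sequence decomposes into maximal period-u
tracts (maximal runs of positions x with s[x] = s[x+u]; N breaks tracts).
Each tract yields at most one locus: anchored at the tract start, motif
reported in starting phase (A-runs and T-runs are distinct loci), count in
whole units, reported when the count meets the per-unit-size threshold
(default 10, 5, 4, 3, 3, 3). Tracts whose starting motif is a whole-number
repetition of a shorter motif belong to the smaller unit size and are
skipped (primitivity), which is what prevents a poly-A tract from also
being called as AA/AAA/… runs, and an (ACGT)ₙ tract from being called at
period 8. A shorter-unit locus wholly inside a reported longer-unit locus
is suppressed unless it independently meets its threshold outside that
locus. Only perfect runs are detected; compound SSRs are reported as
separate adjacent loci, matching the single-motif rows of published SSR
tables. The scanner is proven equal, case by case, to a position-by-
position brute-force oracle on hundreds of random AT-rich sequences.

## Long repeats

A repeat hit is an ungapped pairing of two equal-length windows under one
of three relations: direct, inverted (reverse complement) or reversed
(plain character reversal, included because reversal-symmetric loci are a
recognized structural class). Hit semantics are *maximal bounded-mismatch
windows*: on every alignment diagonal, for each mismatch budget
j ≤ `max_mismatches` (default 3), the windows containing exactly j
mismatches whose flanks are mismatches or boundaries are enumerated;
windows below `min_len` (26) or `min_identity` (0.90) are discarded; a
window contained in a surviving window on the same diagonal is pruned —
except that an exactly self-symmetric window (a perfect palindrome or
reversal core) is never sacrificed to an asymmetric superwindow, because
the symmetric core is the classification evidence.

Search is seed-and-extend: exact 8-mer anchors (8 is the largest seed that
cannot miss a 26 bp window with two mismatches), a vectorized prefilter
that measures budgeted extension around each anchor and keeps only
anchors that could lie inside a valid window, then exhaustive window
enumeration on the surviving diagonal segments. The finder is tested for
exact hit-set equality against a brute-force oracle that re-counts every
candidate window by direct string comparison.

Before scanning a genome, SSR loci are masked (they are reported by the
SSR scanner, not the repeat table) and one IR copy (IRa) is masked to
suppress the genome-scale IRa/IRb self-match; hits inside IRb are then
mirrored into IRa as parenthetical positions, matching how published
repeat tables report IR-resident repeats once.

Hits are grouped into families by transitive closure, merging occurrences
that overlap by ≥ 80 % of the shorter; the consensus uses minimal covering
IUPAC codes at mismatch columns. Classification follows a fixed decision
order: single occurrence equal to its own reverse complement → P; single
occurrence equal to its own reversal → R; ≥ 2 same-strand occurrences
abutting or overlapping (gap ≤ 2 bp, negative gaps included so that
overlapping tandem windows stay tandem) → T; occurrences on opposite
strands → I; otherwise → D.

## Spacer divergence and markers

Spacers are paired across genomes by their normalized flanking-gene pair;
a spacer annotated in the opposite orientation in the comparator is
reverse-complemented first. Pairs are globally aligned with an affine
scheme (match +2, mismatch −1, gap open −10, extend −0.5; first optimal
alignment in the aligner's canonical order for determinism).

Distances use closed-form estimators with pairwise deletion (columns with
a gap or ambiguity in either row are excluded): Jukes-Cantor, Kimura
two-parameter, and F84 (the default, matching the classic
distance-program default) with empirical base frequencies pooled over
both rows. The F84 closed form is Felsenstein's
d = −2A ln(1 − P/2A − (A−B)Q/2AC) + 2(A−B−C) ln(1 − Q/2C) with
A = π_Cπ_T/π_Y + π_Aπ_G/π_R, B = π_Cπ_T + π_Aπ_G, C = π_Rπ_Y; the implementation is frozen against independently computed
reference values (cross-checked with ape's `dist.dna` before freezing).
A non-positive logarithm argument (saturation) or a degenerate base
composition flags the result and leaves the distance undefined rather
than raising.

Marker selection ranks each comparison's spacers by distance (stable sort
on distance then name, so row order is irrelevant), takes the top-n most
divergent (default 20) from both comparisons against the common
reference, intersects them by name, and keeps those longer than
`min_marker_len` (default 500 bp) in the reference genome — short spacers
carry too few characters to be useful markers regardless of rate.

## Gene content and loss mapping

Orthology is by normalized gene name — plastid genes are effectively
single-copy and name-stable — with an optional similarity rescue: a gene
annotated in the reference but missing from a comparator is locally
aligned against the comparator's full sequence, and ≥ 60 % identity over
≥ 60 % of the gene length counts as present ("similarity-rescued"),
catching misannotation-driven false absences. Gains from extra annotated
copies are copy-number observations, not parsimony inferences, and are
read directly from annotation counts.

Loss mapping is unit-cost small parsimony on each binary
presence/absence character over a fixed tree, computed with an
inside–outside dynamic program. Every branch that carries a change in at
least one minimal reconstruction is reported; when more branches qualify
than the minimal event count (e.g. a root-adjacent loss/gain ambiguity on
an effectively unrooted four-taxon tree) the events are flagged ambiguous
and cross-listed rather than arbitrarily resolved. Event counts are
verified against exhaustive enumeration of all ancestral labelings on
hundreds of ≤ 6-leaf instances.

The supermatrix builder concatenates per-gene alignments over the taxa
shared by all genes (genes absent in any selected taxon are excluded) and
emits relaxed PHYLIP/FASTA plus a `DNA, gene = start-end` partition
table. Tree inference itself is delegated to external likelihood
software.

## Synthetic plastomes

The generator's defaults are the study conditions of the package: a
156,506 bp circle with LSC/IRb/SSC/IRa of 86,078 / 26,050 / 18,328 /
26,050 bp, background GC of 34.9 / 43.0 / 30.2 % in LSC / IR / SSC (the
within-genome GC gradient the composition stage must detect), a ~60-gene
complement including the junction anchor genes, 17 planted SSRs with the
A/T-homopolymer-dominated size spectrum typical of plastomes, and one
planted long-repeat family of each structural class at published-table
lengths (42 bp D, 36 bp T, 29 bp I, 30 bp P, 30 bp R). Gene lengths and
positions scale with the configured region lengths so miniature test
genomes keep the full geometry; the default complement needs an SSC of
roughly 2.5 kb or more.

Construction details that make the truth table exact:

- IRa is built as the literal reverse complement of IRb, and annotations
  of IRb-internal genes are mirrored into IRa (IR duplicates); genes that
  span an IR boundary (rps19 at JLB in subtypes I-2/I-4, ycf1 at the
  SSC–IR boundary) get mirrored pseudogene fragments, reproducing the
  ψycf1/ψrps19 arrangement of real Type I genomes.
- Planted SSR flanks are set so the run is maximal exactly as planted,
  and the bases pairing across both IR boundaries are forced to mismatch
  so the maximal exact reverse-complement match equals the planted IR.
- The i.i.d. background is screened post hoc: any accidental SSR reaching
  the thresholds is destroyed by resampling a base near its centre
  (edits inside IRa are applied to the IRb mirror), iterating to a fixed
  point. Accidental ≥ 26 bp repeats are not screened; at these lengths
  and compositions their expected count per genome is ≪ 1.
- The junction subtype (I-1…I-4) is a constructor parameter that moves
  the rps19 and ndhF anchors relative to the boundaries.

`evolve_pair` evolves a copy of a genome along a branch of given expected
substitutions/site under JC, K2P(κ) or F84(κ, frequencies), using the
matrix exponential of the normalized rate matrix; an optional per-site
rate multiplier array creates fast and slow spacers for marker-selection
tests. Indels (Poisson per site, geometric lengths with mean 2) are
applied only outside annotated features and shift downstream coordinates,
so annotations remain exactly correct.

What passing on synthetic data does *not* show: real plastomes have
codon structure, transcription-unit organization, compositional
heterogeneity within regions, imperfect IRs, and annotation
idiosyncrasies (fuzzy boundaries, missing anticodons, inconsistent
pseudo flags) that the generator only partially emulates via the
normalization and rescue layers. The two reproduction tests against a
deposited genome exist precisely to cover that gap and require the
deposited records to run.

## Problem sizes and determinism

The shipped validation uses full-scale (156.5 kb) genomes for structure,
composition, inventory and marker selection; 10–50 kb random sequences
for SSR oracle equivalence; ≤ 2 kb instances for repeat-oracle
equivalence (the oracle is quadratic); 10 kb × 50 replicates per branch
length for distance recovery; and ≤ 6-leaf trees for exhaustive parsimony
checks, sizes at which the exhaustive references are themselves fast.
Every stochastic component takes an explicit integer seed, and identical
seeds give byte-identical outputs; report tables are sorted by coordinate
then name so reruns reproduce identical files.
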