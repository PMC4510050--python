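# Methods

This note documents the models, algorithms and numerical choices behind
napusmap, and what the synthetic studies do and do not establish about
real data.

## DH genetics and two-point statistics

A doubled-haploid line is one gamete doubled, so genotypes are the two
parental alleles A/B (never heterozygous) plus missing.  For two scoring
strings the informative set is the lines where both calls are present;
the two-point estimate is r̂ = R/N with R the number of differing calls,
and the LOD against free recombination is
R·log₁₀ r̃ + (N−R)·log₁₀(1−r̃) + N·log₁₀ 2 with r̃ = min(r̂, 0.5).  At
R = 0 the expression is evaluated as its limit N·log₁₀ 2 exactly, rather
than through an epsilon floor.  Pairs with no informative line raise an
error at the API surface and behave as unlinked (r̂ = 0.5, LOD 0) inside
pairwise tables.

Map functions: Haldane d = −50·ln(1−2r) and Kosambi
d = 25·ln((1+2r)/(1−2r)), both in cM, defined on 0 ≤ r < 0.5.  The
simulator inverts Haldane (its meiosis model has no interference);
reported maps use Kosambi by default, a conventional reporting choice.
Adjacent r̂ is clamped at 0.4999 before the map function so that a
degenerate unlinked adjacency cannot produce an infinite distance.

## Bin calling

Markers are processed in input order within each linkage group: the
first unassigned marker seeds a bin, candidates are added greedily when
they conflict with the bin's running consensus at ≤ `error_tolerance`
(default 0) jointly non-missing positions, and the consensus (majority
of non-missing calls, ties → missing) is updated after every addition.
At tolerance 0 a non-missing consensus call can never flip, which makes
the pass order-stable for conflict-free data and guarantees every
member agrees with the final consensus wherever both are non-missing.

Missing data makes compatibility non-transitive, and a marker masked at
the single line that separates two adjacent bins is *intrinsically
ambiguous*: it is compatible with both consensuses, and no algorithm
can place it from the data alone.  The growth pass alone would always
leave such a marker in the earlier-seeded (left) bin — the wrong side
whenever the marker truly belongs to the later bin.  A deterministic
reassignment pass therefore moves every marker compatible with more
than one final consensus to the largest compatible bin (ties by bin
creation order): the maximum-prior choice, since a marker is
proportionally more likely to belong to a bin with more members.
Consensuses are recomputed from the final membership.  On the default
mapping panel this raises the adjusted Rand index against truth from
≈ 0.936 to ≈ 0.95–0.96; the residual error is dominated by the
genuinely undecidable maskings.

## Grouping, ordering, cM

Grouping is single-linkage clustering on edges with LOD ≥ 6 and
r̂ ≤ 0.35; when bins carry prior linkage-group tags the tags define the
partition and clustering only validates it (qualifying cross-tag edges
are reported as conflicts).

Within a group the order minimises the total number of adjacent-pair
recombination events.  Groups of ≤ 8 bins are solved exhaustively
(each path equals its reverse, so only canonical permutations are
enumerated).  Larger groups use a heuristic: greedy nearest-neighbour
from the bin with the largest mean r̂ (a terminus), then repeated
2-opt (segment reversal) and or-opt (relocation of segments of 1–4
bins, optionally reversed) until no improving move exists.  Segment
relocation matters: single-bin moves cannot repair a short block
attached to the wrong chromosome end, the dominant failure mode of
plain 2-opt on DH data.  Orientation is canonicalised so the first bin
id sorts before the last.  cM positions are the cumulative map function
over adjacent two-point estimates, starting at 0.

## Scaffold stage

Marker anchors are the midpoints of best hits (lowest e-value, then
highest bitscore, then lexicographic target, then smallest start — a
fully deterministic tie-break).  Chimera detection scans consecutive
anchors on a scaffold: a split is declared when the maximal internally
consistent runs on each side (same linkage group, cM range ≤ 20)
contain ≥ 2 anchors each and the sides disagree in group or by > 20 cM;
the cut is the floor midpoint between the flanking anchors, so its
resolution is bounded by the local marker spacing.  One stray anchor
never triggers a split; multiple junctions per scaffold are allowed.

A scaffold's chromosome is the modal linkage group of its anchors, its
position key the median anchor cM (ties by descending length then id),
and its orientation the sign of the Spearman correlation between anchor
scaffold positions and cM; scaffolds with fewer than two distinct
positions or cM values are placed '+' and flagged rather than dropped.
Pseudomolecules concatenate components with a fixed 100-bp N gap
(configurable; no data-driven gap estimate is attempted), emit AGP 2.0
(W/N rows, gap type "scaffold", evidence "map"), and expose a bijective
1-based coordinate lift over all placed ranges.  Coordinates are
0-based half-open internally and 1-based inclusive in AGP/BLAST
dialects.

## Feature anchoring

A feature is anchored at its best hit iff evalue ≤ 1e-30, with the
boundary inclusive (the conventional reading of a reporting threshold);
anchored and unanchored sets partition the input exactly and output
order is deterministic.  The dual table is the inner join of unigene
anchors across the two genomes and carries each anchor's e-value
exponent, which downstream shadow detection uses.

## Collinearity

Chaining is greedy sparse chaining per (A chromosome, C chromosome)
pair: points sorted by A position; a point joins the best eligible open
chain (score = member count, ties by A span then earliest creation)
where eligibility requires the A gap and the signed C gap each in
(0, 2 Mb]; a chain's sign is fixed by its second member; chains with
< 5 points are discarded.  On monotone instances with isolated noise
the greedy result equals an exhaustive optimal-chain search; on heavily
entangled instances it is a heuristic.

Shadow detection distinguishes two C-disjoint geometries that look
identical by position alone: a *paralogue shadow* (the best match of
genes whose homoeologue was lost) and a *displaced block* (a segmental
rearrangement).  Both overlap a main chain's A interval while mapping
elsewhere in C.  The discriminators are (i) anchor weakness — shadow
members are anchored through paralogue matches, and paralogues diverged
at the ancestral hexaploidy, long before the A/C split, so the shadow's
median weaker-anchor e-value exponent must exceed the host's by ≥ 25 —
and (ii), when no exponents are available, sparsity (shadow density
≤ 0.5× the host's, since only lost-homoeologue genes populate it).
The two-shadows-per-block expectation from the two retained paralogous
tracks is applied per A locus and per distinct paralogous location, and
is waived when anchor-strength evidence is decisive, because segmental
rearrangements can split or relocate a paralogous segment.  Labels are
iterated to a fixpoint so that a fragmented host ranked below its
shadow still claims it.

Diagnosis applies ordered rules to unigenes outside the main chains:
(1) ≥ 3 hits within 5 exponents of the best in either genome →
repetitive; (2) best cross-genome hit ≥ 25 exponents weaker than the
within-genome best and no qualifying hit within 2 Mb of the
homoeologous position predicted by interpolating the local main chain →
lost homoeologue anchored to a paralogue (membership of a detected
shadow block is recorded as supporting evidence but not required, since
a sparse shadow can fall below the chaining minimum); (3) coherent
membership of a non-main chain → true rearrangement; else ambiguous.
The 25-exponent margin sits between the anchor-strength noise of the
generator (s.d. ≈ 8 exponents per genome) and its paralogue penalty
(60 exponents); on real alignments the analogous quantity is the gap
between orthologue- and paralogue-level similarity.

## The synthetic generator

The generator emulates the allopolyploid situation: an ancestral order
of n genes in proto-chromosomes is triplicated into three subgenome
tracks with per-track retention (defaults 0.7/0.3/0.2, biased
fractionation), duplicated into A and C lineages, then each lineage
independently loses copies (default rate 0.15 — differential gene loss
of this order is realistic for the ~3.7-My-diverged *Brassica* A and C
lineages) and suffers inversions and translocations of contiguous
blocks (default 3 + 3 per lineage, 250–400 genes ≈ 2.5–4 Mb at the
10-kb gene spacing; segmental rearrangements at multi-Mb scale form
their own collinear blocks rather than being bridged over by the 2-Mb
chain gap cap).  Chromosome *c* carries track-1 copies of proto *c*,
track-2 of proto *c+1* and track-3 of proto *c+2*, so the paralogous
copies of every block sit on two other chromosomes — which is what
produces up to two shadow segments per collinear block after losses.

Similarity searches are emulated directly as BLAST-tabular hit tables:
true-position hits with e-value exponents ~N(−120, 8) (clipped below
−40), paralogue hits weakened by +60 exponents, repetitive features
(2% of unigenes) with ≥ 3 near-equal hits scattered genome-wide.
Sequence content is random nucleotides; homology lives only in the hit
tables.  Scaffolds are exponential fragments of chromosomes; injected
chimeras join fragments from different chromosomes, restricted to
fragments spanning ≥ 2 gene positions so that every junction is
flanked by markers on both sides (a junction without flanking markers
is invisible to any map-based detector).  DH meiosis is a Markov chain
along each group with Haldane switch probabilities, then masking
(default 5%) and optional call errors; truth records bins (identical
unmasked gamete patterns), scaffold order/orientation/junctions,
homoeologue pairs, and per-unigene non-collinearity causes
(repetitive > missing-homoeologue > rearranged).

The default study sizes — mapping panel of 10 groups × 200 markers ×
75 lines on 100-cM groups (a realistic per-group length for *B.
napus*), scaffold study of 2,000 ancestral genes in 10 chromosomes cut
into ~200 scaffolds with 5 chimeras, collinearity study of 6,000
ancestral genes — were chosen so that every stage is exercised with
meaningful statistics while a full acceptance run completes in well
under a minute.

What passing these studies does *not* show: the generator has uniform
gene spacing, iid losses, clean block rearrangements, no tandem
duplication, no assembly base errors, and an idealised e-value model
with a fixed paralogue penalty.  Real scoring data have genotyping
error (the bin caller's `error_tolerance` exists for that, default 0),
real chimeras need not break between two clean map segments, and real
paralogue similarity varies continuously — the 25-exponent margins
would need tuning against real BLAST output.

## Determinism

Every simulation is a function of its seed; every pipeline stage uses
documented, total tie-breaks (input order, lexicographic ids, creation
order), so reruns are bit-identical.  Randomised checks in the tests
and the acceptance script derive all randomness from the single
supplied seed.

## Known limitations

* Bin-order recovery is a heuristic; the exhaustive guarantee covers
  groups of ≤ 8 bins only.
* The greedy chainer can absorb a sparse shadow run into a dense mixed
  chain when their diagonals interleave within the gap cap; such runs
  are not separable downstream.
* Grouping thresholds (LOD ≥ 6, r̂ ≤ 0.35) are standard but not
  calibrated to any particular population size.
* The pseudomolecule total length depends on the gap policy; with a
  different inter-scaffold gap the totals change by
  gap × (components − chromosomes).
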