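# napusmap

Doubled-haploid (DH) linkage mapping, genetic-map-guided pseudomolecule
assembly, and A-vs-C genome collinearity analysis for allopolyploid
*Brassica*, with a synthetic-data generator that supplies every input
with known truth.

## Who this is for

Researchers working with mRNAseq-derived SNP scoring of DH mapping
populations (such as the *B. napus* TNDH panel) who need to:

1. collapse markers into **recombination bins** with consensus scoring
   strings and build an updated linkage map as the population grows;
2. use that map to **anchor genome-sequence scaffolds**, detect and
   split chimeric assemblies, order and orient scaffolds, and emit
   chromosome-scale **pseudomolecules** (FASTA + AGP 2.0 + coordinate
   lift);
3. **anchor unigenes and SNP-array probes** onto the pseudomolecules by
   best similarity hit and analyse **A/C genome collinearity**,
   including the paralogous "shadow" blocks produced by homoeologue
   loss and the diagnosis of non-collinear genes.

## The model in brief

Every DH line is a single doubled gamete, so a marker's scoring string
over lines is a word over {A, B, missing}.  For two strings the
two-point recombination fraction is r̂ = R/N over the N jointly
non-missing lines (R = differing calls), with

    LOD = R·log₁₀ r̂ + (N−R)·log₁₀(1−r̂) + N·log₁₀ 2,

which is exactly N·log₁₀ 2 at R = 0.  Markers with no observed
recombination form a bin; bins are grouped by single-linkage clustering
on confident edges (LOD ≥ 6, r̂ ≤ 0.35), ordered by minimising total
adjacent recombination events (exhaustively for ≤ 8 bins, greedy +
2-opt/segment-relocation otherwise), and placed on a cM scale by a map
function (Kosambi by default, d = 25·ln((1+2r)/(1−2r))).

Scaffolds inherit map positions from their anchored markers; a scaffold
whose anchors split into two internally consistent but mutually
inconsistent runs is chimeric and is cut at the midpoint between the
flanking anchors.  Orientation is the sign of the Spearman correlation
between anchor scaffold positions and cM.

Dual-anchored unigenes form an A-vs-C dot set that is chained into
collinear blocks (greedy sparse chaining; gaps capped at 2 Mb, blocks of
≥ 5 points).  Because the diploid *Brassica* genomes descend from a
hexaploid ancestor, loss of a homoeologue leaves a paralogue as the best
cross-genome match, producing up to two displaced *shadow* copies of
each collinear block; shadows are recognised by geometry (A-overlap,
C-disjoint) plus paralogue-grade anchor weakness.  Non-collinear
unigenes are diagnosed as repetitive (multiple near-best hits), lost
homoeologue anchored to a paralogue, true rearrangement, or ambiguous.

## Worked example

```python
from napusmap import bin_markers, build_linkage_map
from napusmap.simulate import simulate_mapping_panel

panel = simulate_mapping_panel(seed=1)          # 10 groups x 200 markers, 75 DH lines
bins = bin_markers(panel.matrix)
print(len(bins))                                 # 533
print(len(bin_markers(panel.matrix.subset_lines(range(37)))))   # 294

lmap = build_linkage_map(bins)
print(lmap.to_frame().head(3).to_string(index=False))
```

prints

```
533
294
linkage_group   bin_id       cM                                                        member_markers
          A01 bin00001 0.000000 mA01_0001,mA01_0002,mA01_0003,mA01_0004,mA01_0005,mA01_0006,mA01_0007
          A01 bin00002 1.333650                               mA01_0008,mA01_0009,mA01_0010,mA01_0011
          A01 bin00003 2.722896                                                             mA01_0012
```

Raising the panel from 37 to 75 lines nearly doubles the number of
recombination bins (294 → 533): each extra line contributes new
crossovers that split previously unresolved bins.  The map orders the
bins per linkage group and assigns cumulative Kosambi cM from adjacent
two-point estimates.

The same flow is available from the shell:

```bash
napusmap simulate --n-genes 2000 --n-chromosomes 10 --n-chimeras 5 \
    --seed 1 --outdir sim/
napusmap bin sim/scoring.tsv --out bins.tsv
napusmap build-pseudo sim/scaffolds.fasta sim/marker_hits.tsv \
    sim/marker_map.tsv --outdir pseudo/
```

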