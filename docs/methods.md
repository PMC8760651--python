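# Methods

## Problem and approach

Extrachromosomal circular DNA (eccDNA) is enriched experimentally by
exonuclease digestion of linear DNA followed by random rolling-circle
amplification (rRCA), then short-read sequenced ("circSeq").  An amplified
circle leaves three signatures when its reads are mapped to a linear
reference:

1. **Split reads** crossing the circular junction align in two segments in
   *wrap-around* order: the later part of the read aligns upstream of the
   earlier part.  This distinguishes a circle from a deletion, whose split
   segments stay colinear.
2. **Discordant pairs** whose mates fall into different concatemer copies
   violate the forward–reverse inward geometry or the expected insert size.
3. **A coverage peak** over the circle's locus, because rRCA multiplies
   the circular template far above genomic copy number.

`eccscout` intersects these three per-region evidence tracks: regions
meeting all three criteria are *high*-confidence candidates, any two give
*low* confidence, and low-confidence candidates enter downstream analysis
only when no high-confidence candidate exists.  Candidate boundaries are
taken primarily from the split-read junctions (the only base-precise
signal); discordant∩peak overlaps without a split junction use the
intersection of the two intervals (the conservative choice of the two
defensible options).

Independently of any reference, rRCA makes every circle look like a
high-copy repeat.  Clustering circSeq and control reads *together* by
sequence similarity therefore separates amplified circles from genomic
background: clusters with a circSeq read proportion strictly above 80% are
candidate eccDNAs.  Candidates found by both routes — a mapped region and
an enriched cluster whose contigs match the region's sequence — are
reported with *very high* confidence.

## Evidence extraction

**Split junctions.** A primary alignment with exactly one
supplementary-alignment anchor on the same chromosome and strand
contributes support for junction `(s, e)` when the segments are in
wrap-around order; `s` is the start of the upstream segment and `e` the
end of the downstream segment.  Supports agreeing within the breakpoint
tolerance (default 5 bp, absorbing clip-placement ambiguity at homologous
junction bases) are pooled; a junction needs at least five supporting
split reads; consensus boundaries are per-end medians.  The pooling is
order-independent (supports are sorted before grouping) and groups are
constrained so every member lies within the tolerance of the consensus.

**Discordant pairs.** A primary, mapped, mate-mapped pair is discordant
when its proper-pair flag is unset, its mates map to different
chromosomes, |TLEN| exceeds the insert cutoff, or the orientation is not
forward–reverse inward.  The insert cutoff defaults to mean + 3 SD of
proper-pair |TLEN| (estimated from the first 100,000 pairs) because no
universal threshold exists across library preparations.  Same-chromosome
discordant pairs contribute the interval from the leftmost mate start to
the rightmost mate end; intervals are merged (0 bp merge distance by
default) with pair counts retained.

**Coverage and peaks.** Per-base depth counts every reference-consuming
CIGAR base of primary and supplementary alignments.  Depth is normalized
to bases per million bases (BPM): `depth x 1e6 / total aligned bases`, so
a track always sums to 1e6 and regional means are comparable across
libraries of different read lengths and sizes.  Peaks are local maxima
(plateaus allowed; apex = leftmost plateau position) with prominence of at
least 1 BPM, computed with `scipy.signal.find_peaks`; the prominence base
on each side is the minimum between the apex and the nearest higher
position or the chromosome boundary.  The peak region extends while depth
stays above apex height minus prominence — a definition of peak extent
this package chose itself; it has little downstream effect because final
boundaries come from split junctions.  Note that the 1-BPM threshold is a
*library-relative* unit: in a small library one read contributes many BPM
and background noise clears the threshold easily, while in a 20-Mb-base
library it corresponds to ~20 read depths.

**Enrichment score.** With a control library, the score of a region is
its mean BPM in circSeq divided by its mean BPM in the control (floored
at epsilon = 0.1 BPM to avoid division by zero).  Without a control, the
score is computed globally: region mean divided by the global mean of the
circSeq track.  The ratio-of-regional-means form is this package's own
concrete definition; scores are used to rank candidates by estimated
abundance, not as calibrated copy numbers — rRCA amplification bias
precludes quantitative interpretation.

**Annotation.** Candidate sequences are searched against an optional
FASTA database of known repeats/genes with an internal ungapped
seed-and-extend engine (13-mer exact seeds, +1/−2 scoring, X-drop 20, both
strands); hits need ≥80% identity over ≥39 aligned bases.  The engine is
deliberately ungapped and hermetic; it reports score/identity-ranked hits
rather than E-values.

## Comparative read clustering

Reads from both datasets are sub-sampled (default 6000 pairs per dataset,
the number corresponding to 4x coverage of a 0.6 Mb reference at 200 bp
reads; a helper converts desired coverage to pair counts), renamed with
dataset prefixes and mate suffixes, truncated to the minimum read length
in the sample, and interlaced.

Two reads are connected when they share at least `min_shared` distinct
canonical (strand-collapsed) 15-mers; clusters are connected components
of this graph.  Defaults were calibrated on the package's own simulations:

- `min_shared = 40` requires roughly a 68 bp overlap between 200 bp reads
  at 1% error — an edge criterion analogous to the ~55%-of-read-length
  overlap used by established read-clustering pipelines, scaled slightly
  more permissive.  A far looser criterion (a handful of shared k-mers,
  i.e. a ~17 bp overlap) lets chance repeats of that length, which occur
  hundreds of times in a 0.6 Mb random genome, bridge unrelated coverage
  chains into a single giant component, destroying the comparative
  signal.
- `min_cluster = 25` discards components too small for the 80% rule to be
  statistically meaningful: in a null cluster with equal sampling from
  both datasets, the probability of exceeding 80% circSeq proportion by
  chance falls below ~1e-3 only at about 24 reads.  With the cutoff at 25,
  a 20-run false-positive control (enrichment switched off) is clean.

Connected components are deliberately used instead of modularity-based
graph refinement: they preserve the one property the pipeline consumes —
co-clustering of reads from the same amplified sequence — at desk scale.
The cost is coarser granularity: an element that an all-vs-all similarity
pipeline splits into a dozen clusters typically appears here as one
cluster, so cluster *counts* are not comparable across engines.

Clusters bridged by at least two cross-cluster mate pairs are joined into
superclusters.  Candidate clusters (proportion strictly > 0.8, counting
individual reads, not pairs) are assembled into contigs by greedy
overlap-layout: repeatedly merge the pair of sequences with the longest
exact suffix–prefix overlap ≥ 31 bp, trying both orientations, after
collapsing exact duplicates; clusters are down-sampled deterministically
to 400 reads before assembly.  Exact-overlap assembly fragments in the
presence of sequencing errors — this is accepted, since unmerged reads
are emitted as contigs and the downstream similarity search only needs
≥ 50 bp matches.

## Comparative linking

Each candidate cluster's contigs are searched (same seed-and-extend
engine; ≥80% identity over ≥50 bp) against the sequence of every eligible
candidate region *and* against the region's rotated junction sequence —
the region's second half concatenated with its first half.  A match that
crosses the concatenation seam can only arise from a template in which
the region's end is joined to its start, i.e. from the circle itself, so
such clusters are flagged as covering the circular break-point.  Regions
linked by at least one cluster are reported with very high confidence;
duplicate region↔cluster links are collapsed.

## The simulator

The simulator emulates a semi-artificial circSeq experiment with full
ground truth:

- a seeded i.i.d.-random reference (default three chromosomes, 0.6 Mb
  total).  Random sequence replaces real genomic sequence deliberately:
  recovery behavior depends on the geometry of the evidence, not on
  nucleotide composition, and it guarantees the planted element occurs
  exactly once;
- one planted circular element (default 6695 bp) whose locus is recorded
  as a BED ground-truth interval;
- a tandem concatemer of the element (default nine copies, head-to-tail)
  modeling the rRCA product; junction variants are modeled as plain copy
  boundaries, whose split-read signature is identical;
- paired-end reads (default 50,000 pairs of 200 bp per dataset) with
  uniform fragment starts, truncated-normal insert sizes (mean 500 bp,
  SD 50 bp), substitution errors at 1% per base, constant quality 'I'.
  A fraction of circSeq pairs (default 0.5) is drawn from the concatemer,
  the rest from the genome; control pairs come from the genome only.  The
  0.5 default was chosen because the resulting evidence geometry
  reproduces the enrichment-score magnitude (~45) reported for this
  experimental design in the literature this package's defaults emulate;
- *oracle* SAM alignments computed from read provenance: concatemer
  offsets project into the planted locus modulo the element length;
  boundary-crossing reads become primary + supplementary records with
  soft-clipped CIGARs and reciprocal SA tags anchored exactly at the
  circle's ends; cross-copy pairs have the proper-pair bit unset.

Insert-size and error parameters are declared defaults, not values
inferred from any publication.

**What the simulator does not model** — and hence what passing tests do
not show about real data: alignment noise (the oracle mapper never
misplaces a read, so spurious split/discordant evidence from repeats or
assembly errors is absent), indels, quality-dependent errors, GC and
amplification bias, chimeric reads, and real repeat landscapes.  The
false-positive control therefore measures the statistics of the
comparative clustering, not mapper artifacts.

## Problem sizes used by the test suite and acceptance script

The full proof-of-concept run uses the complete default geometry (0.6 Mb,
50,000 pairs per dataset, 6000 pairs per dataset sampled for clustering).
The repeated experiments (20-run false-positive control, 4-point
monotonicity sweep) use a proportionally scaled geometry — 100 kb
reference, 3 kb element, 2500 pairs per dataset, 1000 pairs sampled — that
preserves the full design's clustering coverage (~8x combined) and
concatemer geometry, chosen so the whole suite completes comfortably on a
single CPU.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally and in BED
  output; SAM positions are converted on parse.
- Strand is collapsed for all evidence; circles are strand-symmetric.
- Secondary alignments are ignored everywhere; supplementary alignments
  count for split detection and coverage.
- Median consensus uses the lower median for even support counts.
- Ties in candidate ranking break by confidence tier, then descending
  enrichment score, then descending length, then position.
- `normalize_bpm` on an empty track raises (no enrichment can be
  computed); `annotate_region` with an absent database returns no hits
  and the candidate is reported unannotated.
- Low-confidence candidates are capped at 10,000 in reports.

## Known limitations

- The oracle aligner is for simulation only; real data must be mapped
  with a split-read-aware mapper and provided as SAM.
- Quality trimming is out of scope; the pipeline expects pre-trimmed
  reads.
- Cluster granularity differs from modularity-refined clustering engines
  (see above); supercluster composition, not cluster count, is the
  comparable quantity.
- The enrichment score is a ranking statistic, not an abundance estimate.
- Exact-overlap contig assembly fragments at realistic error rates; the
  comparative search is designed to tolerate this.
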