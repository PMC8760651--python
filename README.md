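# eccscout

Detection of **extrachromosomal circular DNA (eccDNA)** from circSeq
short-read data.  eccDNAs — ring-like DNA molecules from 100 bp to
megabase scale, carrying tandem repeats, gene copies or freshly
mobilized transposable elements — are enriched experimentally by
exonuclease digestion and random rolling-circle amplification (rRCA),
then Illumina-sequenced.  `eccscout` turns such a read set into a ranked
list of eccDNA candidate regions, for researchers studying transposon
activation, organellar minicircles or gene amplification in model and
non-model organisms alike.

## Method

Two independent detection routes are combined:

**Reference-guided (mapping) route.** An amplified circle mapped to a
linear reference produces three signatures, which are intersected:

- *split reads* in wrap-around order — the later part of the read aligns
  upstream of the earlier part — anchoring the circular junction
  `(s, e)`; a junction needs ≥ 5 supporting split reads;
- *discordant read pairs* (proper-pair flag unset, mates on different
  chromosomes, oversized insert, or non-FR orientation);
- *coverage peaks* with prominence ≥ 1 BPM on the depth track normalized
  to bases per million bases, `BPM_i = depth_i × 10⁶ / Σ aligned bases`.

Regions meeting all three criteria are **high-confidence** candidates;
any two give **low** confidence.  Each candidate gets an enrichment
score

    score = mean BPM(region, circSeq) / mean BPM(region, control)

(or, without a control, the region mean over the *global* circSeq mean),
used to rank candidates by estimated abundance, plus an optional
annotation from a similarity search against a user database of known
repeats and genes.

**Reference-free (clustering) route.** rRCA makes every circle look like
a high-copy repeat, so circSeq and control reads are clustered *jointly*
by sequence similarity (shared canonical k-mers, connected components);
clusters with a circSeq read proportion **> 80%** are candidate circles.
Clusters are joined into superclusters by mate-pair links and assembled
into contigs.

**Comparative route.** Contigs of candidate clusters are searched against
the candidate regions' sequences and against each region's *rotated
junction sequence* (second half + first half): a match crossing the
rotation seam can only come from a circle.  Candidates supported by both
routes are reported with **very high confidence**.

A built-in circSeq simulator (random reference, planted circular element,
tandem-concatemer amplification, paired-end reads with errors, and oracle
SAM alignments derived from read provenance) makes the whole pipeline
testable without an external mapper.  See `docs/methods.md` for model
details, parameter defaults and limitations.

## Worked example

Simulate a small experiment (120 kb reference, 3 kb planted circle
amplified nine-fold, 8000 read pairs per dataset), then run the full
pipeline:

```sh
eccscout simulate --seed 1 --out demo/sim \
    --total-ref-length 120000 --element-length 3000 --n-pairs 8000
# reference: demo/sim/reference.fasta
# planted circle: chr3:15834-18834 (element1)

eccscout run --mode all \
    --circ demo/sim/circ_1.fastq,demo/sim/circ_2.fastq \
    --control demo/sim/ctrl_1.fastq,demo/sim/ctrl_2.fastq \
    --reference demo/sim/reference.fasta \
    --alignments demo/sim/circ.sam --control-alignments demo/sim/ctrl.sam \
    --annotation demo/sim/annotation.fasta \
    --out demo/out --seed 1 --sample-pairs 1200
# candidate regions: 1 high confidence, 35 low confidence
# clusters: 39 total, 1 candidate (circSeq-enriched)
# very-high-confidence candidates: 1
```

The top of `demo/out/candidates.tsv`:

```text
chrom  start  end    name              enrichment_score  strand  confidence  evidence               split_reads
chr3   15834  18834  chr3:15834-18834  19.2544           .       high        discordant,peak,split  464
chr3   9461   9742   chr3:9461-9742    0.8234            .       low         discordant,peak        0
```

The one high-confidence candidate is exactly the planted circle: its
boundaries match the ground truth base-for-base (split-read junction
consensus), 464 split reads support the junction, and its coverage is
19-fold enriched over the control.  `demo/out/linked_candidates.tsv`
shows the comparative result: the candidate region is linked to the one
circSeq-enriched read cluster (`CL0001`), whose contigs also cross the
circular break-point (junction-spanning), and is annotated as `element1`
— a very-high-confidence eccDNA call.

Mode `map` (reference + alignments, no control reads) and mode `clu`
(circSeq + control reads, no reference) run each route alone.
Alignments of real data should come from a split-read-aware mapper and be
supplied as SAM; reads are expected pre-trimmed.

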