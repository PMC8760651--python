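"""eccDNA candidate regions from intersected evidence tracks.

Candidate calling follows a 3-of-3 / 2-of-3 rule: a region supported by
split reads, discordant pairs and a coverage peak is a *high*-confidence
candidate; any two of the three give *low* confidence.  Boundaries are
taken primarily from the split-read junctions; discordant-peak overlaps
without a split junction are emitted with the intersection of the two
intervals.  When at least one high-confidence candidate exists,
low-confidence candidates are retained in output but excluded from
downstream comparative linking.

Each candidate carries an enrichment score -- the ratio of its mean BPM
coverage in the circSeq library to the control library (or to the global
circSeq mean when no control is available) -- used to rank candidates by
estimated abundance, and optional annotation hits from a similarity
search against a database of known repeats/genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

from .evidence import CoverageTrack, CoveragePeakRegion, DiscordantRegion, SplitJunction
from .seedextend import LocalMatch, seed_and_extend


@dataclass(frozen=True)
class AnnotationHit:
    subject_id: str
    identity: float
    aligned_length: int
    score: int
    subject_strand: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@dataclass
class CandidateRegion:
    """A 0-based half-open interval with >= 2 evidence types.

    ``support`` bundles the raw evidence strengths: pooled split-read
    count, discordant pair count and peak prominence (BPM).
    """

    chrom: str
    start: int
    end: int
    evidence: frozenset[str]
    confidence: str  # "high" | "low"
    support: tuple[int, int, float] = (0, 0, 0.0)
    enrichment_score: float = float("nan")
    annotation: list[AnnotationHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("require start < end")
        if not self.evidence <= {"split", "discordant", "peak"}:
            raise ValueError(f"unknown evidence type in {self.evidence}")
        if len(self.evidence) < 2:
            raise ValueError("a candidate requires at least two evidence types")
        expected = "high" if len(self.evidence) == 3 else "low"
        if self.confidence != expected:
            raise ValueError(f"{len(self.evidence)} evidence types imply {expected} confidence")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def _tree(items: Iterable, chrom: str) -> IntervalTree:
    tree = IntervalTree()
    for item in items:
        if item.chrom == chrom:
            tree.addi(item.start, item.end, item)
    return tree


def intersect_evidence(
    splits: Sequence[SplitJunction],
    discordants: Sequence[DiscordantRegion],
    peaks: Sequence[CoveragePeakRegion],
) -> list[CandidateRegion]:
    """Combine the three evidence tracks into confidence-tiered candidates.

    Two intervals match if they overlap by at least one base.  Every split
    junction overlapped by at least one other evidence type becomes a
    candidate with the junction's boundaries; discordant/peak overlaps not
    touched by any split junction are emitted as low-confidence candidates
    bounded by the intersection of the two intervals.
    """
    chroms = sorted(
        {s.chrom for s in splits}
        | {d.chrom for d in discordants}
        | {p.chrom for p in peaks}
    )
    candidates: list[CandidateRegion] = []
    for chrom in chroms:
        d_tree = _tree(discordants, chrom)
        p_tree = _tree(peaks, chrom)
        s_tree = _tree(splits, chrom)
        for split in splits:
            if split.chrom != chrom:
                continue
            d_hits = d_tree.overlap(split.start, split.end)
            p_hits = p_tree.overlap(split.start, split.end)
            evidence = {"split"}
            if d_hits:
                evidence.add("discordant")
            if p_hits:
                evidence.add("peak")
            if len(evidence) < 2:
                continue
            candidates.append(
                CandidateRegion(
                    chrom=chrom,
                    start=split.start,
                    end=split.end,
                    evidence=frozenset(evidence),
                    confidence="high" if len(evidence) == 3 else "low",
                    support=(
                        split.support,
                        sum(iv.data.pair_count for iv in d_hits),
                        max((iv.data.prominence for iv in p_hits), default=0.0),
                    ),
                )
            )
        seen: set[tuple[int, int]] = set()
        for disc in discordants:
            if disc.chrom != chrom:
                continue
            for iv in p_tree.overlap(disc.start, disc.end):
                start = max(disc.start, iv.begin)
                end = min(disc.end, iv.end)
                if start >= end or (start, end) in seen:
                    continue
                if s_tree.overlap(start, end):
                    continue
                seen.add((start, end))
                candidates.append(
                    CandidateRegion(
                        chrom=chrom,
                        start=start,
                        end=end,
                        evidence=frozenset({"discordant", "peak"}),
                        confidence="low",
                        support=(0, disc.pair_count, iv.data.prominence),
                    )
                )
    candidates.sort(key=lambda c: (c.chrom, c.start, c.end))
    return candidates


def eligible_for_linking(candidates: Sequence[CandidateRegion]) -> list[CandidateRegion]:
    """High-confidence candidates; low confidence only as a fallback.

    Low-confidence candidates take part in downstream analysis only when
    no high-confidence candidate exists.
    """
    high = [c for c in candidates if c.confidence == "high"]
    return high if high else [c for c in candidates if c.confidence == "low"]


def score_enrichment(
    region: CandidateRegion,
    circ_bpm: CoverageTrack,
    ctrl_bpm: CoverageTrack | None = None,
    epsilon: float = 0.1,
) -> float:
    """Enrichment of the region in the circSeq library.

    With a control library: mean BPM over the region in circSeq divided by
    the same quantity in the control (floored at ``epsilon`` BPM to avoid
    division by zero).  Without control the score is computed *globally*:
    region mean divided by the global mean of the circSeq track.
    """
    if not circ_bpm.normalized or (ctrl_bpm is not None and not ctrl_bpm.normalized):
        raise ValueError("enrichment requires BPM-normalized tracks")
    mean_circ = circ_bpm.region_mean(region.chrom, region.start, region.end)
    if ctrl_bpm is not None:
        denom = max(ctrl_bpm.region_mean(region.chrom, region.start, region.end), epsilon)
    else:
        denom = circ_bpm.global_mean()
    return mean_circ / denom


def _load_db(db) -> list[tuple[str, str]]:
    if db is None:
        return []
    if isinstance(db, (str, Path)):
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(db), "fasta")]
    if isinstance(db, dict):
        return list(db.items())
    return list(db)


def annotate_region(
    region_sequence: str,
    db,
    min_identity: float = 0.8,
    seed_k: int = 13,
) -> list[AnnotationHit]:
    """Similarity search of a candidate's sequence against an annotation DB.

    ``db`` may be a FASTA path, a mapping id -> sequence, or (id, seq)
    pairs; an absent/empty database yields no hits (the candidate is then
    reported unannotated).  Hits need >= min_identity over >= 3 * seed_k
    aligned bases and are returned best-first (score, identity, then
    subject id).
    """
    hits: list[AnnotationHit] = []
    for subject_id, subject_seq in _load_db(db):
        for m in seed_and_extend(
            region_sequence,
            subject_seq,
            seed_k=seed_k,
            min_identity=min_identity,
            min_length=3 * seed_k,
        ):
            hits.append(
                AnnotationHit(
                    subject_id=subject_id,
                    identity=m.identity,
                    aligned_length=m.aligned_length,
                    score=m.score,
                    subject_strand=m.strand,
                )
            )
    hits.sort(key=lambda h: (-h.score, -h.identity, h.subject_id))
    return hits


def rank_candidates(candidates: Sequence[CandidateRegion]) -> list[CandidateRegion]:
    """High confidence first; within a tier by descending enrichment score,
    then descending length, then position."""
    return sorted(
        candidates,
        key=lambda c: (
            0 if c.confidence == "high" else 1,
            -(c.enrichment_score if c.enrichment_score == c.enrichment_score else 0.0),
            -c.length,
            c.chrom,
            c.start,
        ),
    )
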