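"""Read-level eccDNA evidence from SAM alignments.

Three signatures distinguish an amplified DNA circle mapped onto a linear
reference: (1) split reads whose two segments align in wrap-around order
(the later part of the read upstream of the earlier part), anchoring the
circular junction; (2) discordant read pairs violating the expected
forward-reverse inward geometry; (3) a coverage peak over the circle's
locus.  Coverage is normalized to bases per million bases (BPM) so that
read sets of different lengths and depths are directly comparable, and
peaks are called by prominence with a minimum prominence of one BPM.

Coordinates are 0-based half-open throughout; SAM input is converted on
parse.  Strand is collapsed for all evidence (circles are
strand-symmetric).  Secondary alignments are excluded everywhere;
supplementary alignments contribute to split detection and coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
import scipy.signal

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or sum(len(n) + 1 for n, _ in _CIGAR_RE.findall(cigar)) != len(cigar):
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def cigar_query_length(ops: list[tuple[str, int]], with_clips: bool = True) -> int:
    include = _QUERY_OPS | ({"H"} if with_clips else set())
    return sum(n for op, n in ops if op in include)


def cigar_reference_length(ops: list[tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in _REF_OPS)


def cigar_clip_left(ops: list[tuple[str, int]]) -> int:
    clip = 0
    for op, n in ops:
        if op in "SH":
            clip += n
        else:
            break
    return clip


@dataclass(frozen=True)
class SupplementaryAnchor:
    """One partner segment from an SA tag ('rname,pos,strand,CIGAR,mapq,NM;')."""

    chrom: str
    pos: int  # 0-based
    strand: str
    cigar: str


@dataclass
class AlignmentRecord:
    """One SAM alignment line with decoded flags, 0-based coordinates."""

    query_name: str
    paired: bool
    proper_pair: bool
    unmapped: bool
    mate_unmapped: bool
    reverse: bool
    mate_reverse: bool
    secondary: bool
    supplementary: bool
    is_read1: bool
    chrom: str | None
    pos: int
    cigar: list[tuple[str, int]]
    mapq: int
    mate_chrom: str | None
    mate_pos: int
    tlen: int
    supplementary_anchors: list[SupplementaryAnchor] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return "-" if self.reverse else "+"

    @property
    def is_primary(self) -> bool:
        return not (self.secondary or self.supplementary)

    @property
    def query_length(self) -> int:
        return cigar_query_length(self.cigar)

    @property
    def query_start(self) -> int:
        """Start of the aligned part on the stored (reference-oriented) read."""
        return cigar_clip_left(self.cigar)

    @property
    def reference_end(self) -> int:
        return self.pos + cigar_reference_length(self.cigar)


def _decode_sa(tag: str) -> list[SupplementaryAnchor]:
    anchors = []
    for chunk in tag.strip(";").split(";"):
        if not chunk:
            continue
        rname, pos, strand, cigar, _mapq, _nm = chunk.split(",")
        anchors.append(SupplementaryAnchor(rname, int(pos) - 1, strand, cigar))
    return anchors


def parse_alignments(source: str | Path | Iterable[pysam.AlignedSegment]) -> Iterator[AlignmentRecord]:
    """Stream ``AlignmentRecord`` objects from a SAM file (or pysam iterator).

    Requires @SQ header lines; malformed input raises the underlying
    parser's error, which reports the offending line.
    """
    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source), "r") as fh:
            yield from parse_alignments(fh)
        return
    for aln in source:
        anchors = _decode_sa(aln.get_tag("SA")) if aln.has_tag("SA") else []
        yield AlignmentRecord(
            query_name=aln.query_name,
            paired=aln.is_paired,
            proper_pair=aln.is_proper_pair,
            unmapped=aln.is_unmapped,
            mate_unmapped=aln.mate_is_unmapped if aln.is_paired else False,
            reverse=aln.is_reverse,
            mate_reverse=aln.mate_is_reverse if aln.is_paired else False,
            secondary=aln.is_secondary,
            supplementary=aln.is_supplementary,
            is_read1=aln.is_read1,
            chrom=aln.reference_name,
            pos=aln.reference_start,
            cigar=(
                [] if aln.cigartuples is None
                else [("MIDNSHP=X"[op], n) for op, n in aln.cigartuples]
            ),
            mapq=aln.mapping_quality,
            mate_chrom=aln.next_reference_name,
            mate_pos=aln.next_reference_start,
            tlen=aln.template_length,
            supplementary_anchors=anchors,
        )


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Materialize a SAM file: (records, chromosome lengths from @SQ)."""
    with pysam.AlignmentFile(str(path), "r") as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        records = list(parse_alignments(fh))
    return records, lengths


# ---------------------------------------------------------------------------
# split-read junctions


@dataclass(frozen=True)
class SplitJunction:
    """Candidate circular junction (0-based half-open) with split support."""

    chrom: str
    start: int
    end: int
    support: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("require start < end")
        if self.support < 1:
            raise ValueError("support must be >= 1")


def _split_support(rec: AlignmentRecord) -> tuple[str, int, int] | None:
    """Circular-junction interval supported by one split read, if any.

    The read's primary segment and its supplementary anchor must lie on
    one chromosome and strand.  In stored (reference) orientation the
    segment covering the earlier part of the read must align *downstream*
    of the one covering the later part -- the wrap-around order a circle
    produces.  Colinear splits (deletion signature) yield None.
    """
    if rec.unmapped or not rec.is_primary or len(rec.supplementary_anchors) != 1:
        return None
    anchor = rec.supplementary_anchors[0]
    if anchor.chrom != rec.chrom or anchor.strand != rec.strand:
        return None
    a_ops = parse_cigar(anchor.cigar)
    seg1 = (rec.query_start, rec.pos, rec.reference_end)
    seg2 = (cigar_clip_left(a_ops), anchor.pos, anchor.pos + cigar_reference_length(a_ops))
    if seg1[0] == seg2[0]:
        return None
    earlier, later = (seg1, seg2) if seg1[0] < seg2[0] else (seg2, seg1)
    if later[1] >= earlier[1]:  # colinear order: deletion, not a circle
        return None
    return (rec.chrom, later[1], earlier[2])


def call_split_junctions(
    records: Iterable[AlignmentRecord],
    min_split: int = 5,
    breakpoint_tolerance: int = 5,
) -> list[SplitJunction]:
    """Pool wrap-around split reads into junctions with >= min_split support.

    Supports whose breakpoints agree within ``breakpoint_tolerance`` on
    both ends are pooled; consensus boundaries are the per-end medians.
    Output is independent of record order.
    """
    if min_split < 1:
        raise ValueError("min_split must be >= 1")
    supports: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        hit = _split_support(rec)
        if hit is not None:
            supports.setdefault(hit[0], []).append((hit[1], hit[2]))
    junctions = []
    for chrom in sorted(supports):
        pts = sorted(supports[chrom])
        group: list[tuple[int, int]] = []
        e_min = e_max = 0

        def _flush() -> None:
            if len(group) >= min_split:
                ss = sorted(s for s, _ in group)
                es = sorted(e for _, e in group)
                junctions.append(
                    SplitJunction(
                        chrom=chrom,
                        start=ss[(len(ss) - 1) // 2],
                        end=es[(len(es) - 1) // 2],
                        support=len(group),
                    )
                )

        for s, e in pts:
            if group and (
                s - group[0][0] > breakpoint_tolerance
                or max(e, e_max) - min(e, e_min) > breakpoint_tolerance
            ):
                _flush()
                group = []
            if not group:
                e_min = e_max = e
            group.append((s, e))
            e_min, e_max = min(e_min, e), max(e_max, e)
        if group:
            _flush()
    junctions.sort(key=lambda j: (j.chrom, j.start, j.end))
    return junctions


# ---------------------------------------------------------------------------
# discordant pairs


@dataclass(frozen=True)
class DiscordantRegion:
    chrom: str
    start: int
    end: int
    pair_count: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("require start < end")
        if self.pair_count < 1:
            raise ValueError("pair_count must be >= 1")


def estimate_max_insert(records: Iterable[AlignmentRecord], sample: int = 100_000) -> float:
    """mean + 3*SD of |tlen| over the first ``sample`` proper pairs."""
    tlens = []
    for rec in records:
        if rec.is_primary and rec.proper_pair and not rec.unmapped and rec.tlen != 0:
            tlens.append(abs(rec.tlen))
            if len(tlens) >= sample:
                break
    if not tlens:
        return float("inf")
    arr = np.asarray(tlens, dtype=float)
    return float(arr.mean() + 3.0 * arr.std())


def _orientation_fr(rec: AlignmentRecord) -> bool:
    """True if the pair is in forward-reverse inward orientation."""
    if rec.pos < rec.mate_pos:
        return (not rec.reverse) and rec.mate_reverse
    if rec.pos > rec.mate_pos:
        return rec.reverse and (not rec.mate_reverse)
    return rec.reverse != rec.mate_reverse


def call_discordant_regions(
    records: Iterable[AlignmentRecord],
    max_insert: float | None = None,
    merge_distance: int = 0,
) -> list[DiscordantRegion]:
    """Merge intervals spanned by discordantly mapping read pairs.

    A primary, mapped, mate-mapped pair is discordant if its proper-pair
    flag is unset, its mates sit on different chromosomes, |tlen| exceeds
    ``max_insert``, or the orientation is not forward-reverse inward.
    Same-chromosome discordant pairs contribute [min(pos), max(mate end));
    intervals within ``merge_distance`` are merged, keeping pair counts.
    If ``max_insert`` is None it is estimated as mean + 3*SD of proper-pair
    |tlen|.
    """
    records = list(records) if not isinstance(records, list) else records
    if max_insert is None:
        max_insert = estimate_max_insert(records)
    intervals: dict[str, list[tuple[int, int]]] = {}
    seen: set[str] = set()
    for rec in records:
        if (
            not rec.paired or not rec.is_primary or rec.unmapped
            or rec.mate_unmapped or rec.query_name in seen
        ):
            continue
        seen.add(rec.query_name)
        different_chrom = rec.mate_chrom is not None and rec.mate_chrom != rec.chrom
        discordant = (
            not rec.proper_pair
            or different_chrom
            or abs(rec.tlen) > max_insert
            or not _orientation_fr(rec)
        )
        if not discordant or different_chrom:
            continue
        start = min(rec.pos, rec.mate_pos)
        end = max(rec.reference_end, rec.mate_pos + rec.query_length)
        intervals.setdefault(rec.chrom, []).append((start, end))
    regions = []
    for chrom in sorted(intervals):
        spans = sorted(intervals[chrom])
        cur_start, cur_end, count = spans[0][0], spans[0][1], 1
        for start, end in spans[1:]:
            if start <= cur_end + merge_distance:
                cur_end = max(cur_end, end)
                count += 1
            else:
                regions.append(DiscordantRegion(chrom, cur_start, cur_end, count))
                cur_start, cur_end, count = start, end, 1
        regions.append(DiscordantRegion(chrom, cur_start, cur_end, count))
    return regions


# ---------------------------------------------------------------------------
# coverage and peaks


@dataclass
class CoverageTrack:
    """Per-base depth per chromosome, raw or BPM-normalized.

    In BPM units the track sums to 1e6 over all positions, so regional
    means are comparable between libraries of different read lengths and
    sizes.
    """

    depths: dict[str, np.ndarray]
    total_aligned_bases: int
    normalized: bool = False

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        arr = self.depths[chrom]
        if not (0 <= start < end <= arr.size):
            raise ValueError(f"region {chrom}:{start}-{end} outside track bounds")
        return float(arr[start:end].mean())

    def global_mean(self) -> float:
        total = sum(float(a.sum()) for a in self.depths.values())
        positions = sum(a.size for a in self.depths.values())
        return total / positions

    def total_sum(self) -> float:
        return sum(float(a.sum()) for a in self.depths.values())


def compute_coverage(
    records: Iterable[AlignmentRecord],
    chrom_lengths: dict[str, int],
) -> CoverageTrack:
    """Raw per-base depth from primary and supplementary alignments.

    Every reference-consuming CIGAR base of a mapped, non-secondary
    alignment adds one to the track; ``total_aligned_bases`` accumulates
    the same quantity.
    """
    depths = {name: np.zeros(length, dtype=np.float64) for name, length in chrom_lengths.items()}
    total = 0
    for rec in records:
        if rec.unmapped or rec.secondary:
            continue
        arr = depths[rec.chrom]
        pos = rec.pos
        for op, n in rec.cigar:
            if op in _REF_OPS:
                if pos + n > arr.size:
                    raise ValueError(
                        f"alignment of {rec.query_name} extends beyond end of {rec.chrom}"
                    )
                arr[pos:pos + n] += 1.0
                total += n
                pos += n
    return CoverageTrack(depths=depths, total_aligned_bases=total, normalized=False)


def normalize_bpm(track: CoverageTrack) -> CoverageTrack:
    """Scale depths to bases per million bases: depth * 1e6 / total aligned."""
    if track.total_aligned_bases == 0:
        raise ValueError(
            "no aligned bases: coverage cannot be normalized and no "
            "enrichment score can be computed"
        )
    factor = 1e6 / track.total_aligned_bases
    return CoverageTrack(
        depths={name: arr * factor for name, arr in track.depths.items()},
        total_aligned_bases=track.total_aligned_bases,
        normalized=True,
    )


@dataclass(frozen=True)
class CoveragePeakRegion:
    chrom: str
    start: int
    end: int
    apex_position: int
    apex_height: float
    prominence: float

    def __post_init__(self) -> None:
        if not self.start <= self.apex_position < self.end:
            raise ValueError("apex must lie within the region")


def find_peaks(track: CoverageTrack, min_prominence: float = 1.0) -> list[CoveragePeakRegion]:
    """Prominence-filtered coverage peaks on a BPM-normalized track.

    A local maximum (plateaus allowed; the apex is the leftmost plateau
    position) is reported if its prominence -- height above the higher of
    the two bases, where each base is the minimum between the apex and the
    nearest higher position (or chromosome boundary) -- reaches
    ``min_prominence``.  The region extent is the maximal interval around
    the apex where depth stays above apex height minus prominence.
    """
    if not track.normalized:
        raise ValueError("find_peaks expects a BPM-normalized track")
    peaks = []
    for chrom in track.depths:
        x = track.depths[chrom]
        if x.size < 3:
            continue
        idx, props = scipy.signal.find_peaks(
            x, prominence=min_prominence, plateau_size=(1, None)
        )
        for i in range(idx.size):
            apex = int(props["left_edges"][i])
            height = float(x[apex])
            prominence = float(props["prominences"][i])
            threshold = height - prominence
            left = apex
            while left > 0 and x[left - 1] > threshold:
                left -= 1
            right = int(props["right_edges"][i])
            while right + 1 < x.size and x[right + 1] > threshold:
                right += 1
            peaks.append(
                CoveragePeakRegion(
                    chrom=chrom,
                    start=left,
                    end=right + 1,
                    apex_position=apex,
                    apex_height=height,
                    prominence=prominence,
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks
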