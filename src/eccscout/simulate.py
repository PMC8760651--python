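"""Semi-artificial circSeq data with known ground truth.

Circle-enrichment sequencing (circSeq) amplifies circular DNA by random
rolling-circle amplification (rRCA), producing tandem concatemers of the
circular template.  Short paired-end reads from such a concatemer carry the
three mapping signatures a circle leaves on a linear reference: reads that
straddle a copy boundary align as split reads anchored at the circle's two
ends, read pairs whose mates fall into different copies align discordantly,
and the circle's locus accumulates coverage far above background.

This module builds a seeded random multi-chromosome reference with one
planted circular element, amplifies the element as a head-to-tail tandem
concatemer, simulates paired-end reads with substitution errors from both
the concatemer and the genomic background, and emits *oracle* SAM
alignments computed directly from read provenance -- so the whole evidence
engine is testable without an external read mapper.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(raw.shape, dtype=np.uint8)
    codes[raw == ord("C")] = 1
    codes[raw == ord("G")] = 2
    codes[raw == ord("T")] = 3
    return codes


# ---------------------------------------------------------------------------
# configuration and domain types


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry and noise parameters of one simulated circSeq experiment.

    Defaults reproduce the semi-artificial proof-of-concept dataset: a
    ~0.6 Mb three-chromosome reference carrying one 6695 bp circular
    element amplified as a nine-copy tandem concatemer, 50,000 read pairs
    of 200 bp per dataset, with half of the circSeq pairs drawn from the
    concatemer.
    """

    seed: int = 1
    n_chromosomes: int = 3
    total_ref_length: int = 600_000
    element_length: int = 6_695
    tandem_copies: int = 9
    n_pairs_circ: int = 50_000
    n_pairs_control: int = 50_000
    read_length: int = 200
    insert_mean: int = 500
    insert_sd: int = 50
    error_rate: float = 0.01
    enrichment_fraction: float = 0.5

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "total_ref_length": self.total_ref_length,
            "element_length": self.element_length,
            "tandem_copies": self.tandem_copies,
            "n_pairs_circ": self.n_pairs_circ,
            "n_pairs_control": self.n_pairs_control,
            "read_length": self.read_length,
            "insert_mean": self.insert_mean,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0 (got {value})")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.enrichment_fraction <= 1.0:
            raise ValueError("enrichment_fraction must be in [0, 1]")
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be smaller than insert_mean")
        if self.element_length >= self.total_ref_length:
            raise ValueError("element_length must be smaller than total_ref_length")


@dataclass
class SimulatedGenome:
    """Ordered chromosomes of a simulated reference, as (id, sequence)."""

    chromosomes: list[tuple[str, str]]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)


@dataclass(frozen=True)
class GroundTruthCircle:
    """The planted circular element: 0-based half-open reference interval.

    ``junction_position`` is the coordinate where the circle's end wraps
    back to its start (equal to ``start`` on the linear reference).
    """

    chrom: str
    start: int
    end: int
    element_id: str
    junction_position: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadPair:
    """One simulated pair with full provenance.

    ``offset`` is the 0-based template coordinate of the leftmost base of
    the fragment; the fragment spans ``[offset, offset + insert)``.  The
    left window is sequenced forward, the right window reverse; ``strand``
    records which of the two windows is mate 1 ('+': left, '-': right).
    ``seq_left``/``seq_right`` are template-forward sequences including
    substitution errors; error offsets (window-relative) are recorded.
    """

    name: str
    template_id: str
    offset: int
    insert: int
    strand: str
    seq_left: str
    seq_right: str
    err_left: tuple[int, ...] = ()
    err_right: tuple[int, ...] = ()

    @property
    def mate1(self) -> str:
        return self.seq_left if self.strand == "+" else revcomp(self.seq_right)

    @property
    def mate2(self) -> str:
        return revcomp(self.seq_right) if self.strand == "+" else self.seq_left


@dataclass
class ReadPairSet:
    pairs: list[ReadPair]
    read_length: int

    def __post_init__(self) -> None:
        names = [p.name for p in self.pairs]
        if len(set(names)) != len(names):
            raise ValueError("read pair names must be unique within a set")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# reference and concatemer


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per simulation stage
    return np.random.default_rng([config.seed, stream])


def simulate_reference(config: SimulationConfig) -> tuple[SimulatedGenome, GroundTruthCircle]:
    """Build a seeded random reference with one planted circular element.

    Chromosome lengths split ``total_ref_length`` near-equally.  The
    element is the substring of the last chromosome at a random locus, so
    the genome contains exactly one embedded copy, recorded as the ground
    truth circle.
    """
    rng = _rng(config, 0)
    base = config.total_ref_length // config.n_chromosomes
    lengths = [base] * config.n_chromosomes
    lengths[-1] += config.total_ref_length - base * config.n_chromosomes
    chromosomes = []
    for i, length in enumerate(lengths):
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        chromosomes.append((f"chr{i + 1}", _codes_to_str(codes)))
    host_name, host_seq = chromosomes[-1]
    if config.element_length > len(host_seq):
        raise ValueError(
            f"element_length {config.element_length} exceeds host chromosome "
            f"{host_name} length {len(host_seq)}"
        )
    start = int(rng.integers(0, len(host_seq) - config.element_length + 1))
    truth = GroundTruthCircle(
        chrom=host_name,
        start=start,
        end=start + config.element_length,
        element_id="element1",
        junction_position=start,
    )
    return SimulatedGenome(chromosomes), truth


def element_sequence(genome: SimulatedGenome, truth: GroundTruthCircle) -> str:
    return genome.sequence(truth.chrom)[truth.start:truth.end]


def build_concatemer(genome: SimulatedGenome, truth: GroundTruthCircle, copies: int) -> str:
    """Head-to-tail tandem repeat of the circular element (rRCA product)."""
    if copies < 1:
        raise ValueError(f"copies must be >= 1 (got {copies})")
    return element_sequence(genome, truth) * copies


# ---------------------------------------------------------------------------
# read simulation


def simulate_read_pairs(
    template: str,
    n_pairs: int,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
    template_id: str = "template",
    name_prefix: str = "read",
) -> ReadPairSet:
    """Paired-end reads from uniform fragment starts on ``template``.

    Insert sizes are Normal(insert_mean, insert_sd) truncated to
    [2*read_length, template length]; mate 2 is the reverse complement of
    the fragment's other end; substitution errors are applied per base at
    ``error_rate``.  Provenance (template id, offset, strand, error
    offsets) is recorded on every pair.
    """
    if rng is None:
        rng = _rng(config, 99)
    length = len(template)
    r = config.read_length
    lo, hi = 2 * r, length
    if length < config.insert_mean + 4 * config.insert_sd or length < lo:
        raise ValueError(
            f"template of length {length} too short for insert distribution "
            f"(need >= {max(lo, config.insert_mean + 4 * config.insert_sd)})"
        )
    inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    for _ in range(100):
        bad = (inserts < lo) | (inserts > hi)
        if not bad.any():
            break
        inserts[bad] = rng.normal(config.insert_mean, config.insert_sd, size=int(bad.sum()))
    inserts = np.clip(np.rint(inserts), lo, hi).astype(np.int64)
    starts = np.floor(rng.random(n_pairs) * (length - inserts + 1)).astype(np.int64)

    codes = _str_to_codes(template)
    win = np.arange(r)
    left = codes[starts[:, None] + win]
    right = codes[(starts + inserts - r)[:, None] + win]

    def _apply_errors(mat: np.ndarray) -> np.ndarray:
        if config.error_rate == 0.0:
            return np.zeros((0, 2), dtype=np.int64)
        mask = rng.random(mat.shape) < config.error_rate
        rows, cols = np.nonzero(mask)
        shift = rng.integers(1, 4, size=rows.size, dtype=np.uint8)
        mat[rows, cols] = (mat[rows, cols] + shift) % 4
        return np.column_stack([rows, cols])

    err_l = _apply_errors(left)
    err_r = _apply_errors(right)
    strands = np.where(rng.random(n_pairs) < 0.5, "+", "-")

    def _group(err: np.ndarray) -> dict[int, tuple[int, ...]]:
        out: dict[int, list[int]] = {}
        for row, col in err:
            out.setdefault(int(row), []).append(int(col))
        return {k: tuple(sorted(v)) for k, v in out.items()}

    gl, gr = _group(err_l), _group(err_r)
    pairs = []
    for i in range(n_pairs):
        pairs.append(
            ReadPair(
                name=f"{name_prefix}{i:06d}",
                template_id=template_id,
                offset=int(starts[i]),
                insert=int(inserts[i]),
                strand=str(strands[i]),
                seq_left=_codes_to_str(left[i]),
                seq_right=_codes_to_str(right[i]),
                err_left=gl.get(i, ()),
                err_right=gr.get(i, ()),
            )
        )
    return ReadPairSet(pairs, config.read_length)


def _simulate_background(
    genome: SimulatedGenome,
    n_pairs: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    name_prefix: str,
) -> list[ReadPair]:
    """Pairs drawn from the reference chromosomes, proportionally to length."""
    lengths = np.array([len(seq) for _, seq in genome.chromosomes], dtype=float)
    counts = rng.multinomial(n_pairs, lengths / lengths.sum())
    pairs: list[ReadPair] = []
    offset = 0
    for (name, seq), count in zip(genome.chromosomes, counts):
        if count == 0:
            continue
        sub = simulate_read_pairs(
            seq, int(count), config, rng=rng, template_id=name,
            name_prefix=f"{name_prefix}{offset:06d}_",
        )
        pairs.extend(sub.pairs)
        offset += int(count)
    return pairs


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: SimulatedGenome
    truth: GroundTruthCircle
    concatemer: str
    circ: ReadPairSet
    control: ReadPairSet


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Full circSeq experiment: reference, concatemer, circSeq + control reads.

    circSeq pairs are a mixture of ``enrichment_fraction`` concatemer pairs
    (the rRCA-amplified circle) and genomic background; control pairs come
    from the reference only.
    """
    genome, truth = simulate_reference(config)
    concatemer = build_concatemer(genome, truth, config.tandem_copies)
    rng_circ = _rng(config, 1)
    rng_ctrl = _rng(config, 2)
    n_enriched = int(round(config.n_pairs_circ * config.enrichment_fraction))
    circ_pairs: list[ReadPair] = []
    if n_enriched > 0:
        circ_pairs.extend(
            simulate_read_pairs(
                concatemer, n_enriched, config, rng=rng_circ,
                template_id="concatemer", name_prefix="circ_ecc",
            ).pairs
        )
    n_bg = config.n_pairs_circ - n_enriched
    if n_bg > 0:
        circ_pairs.extend(_simulate_background(genome, n_bg, config, rng_circ, "circ_bg"))
    ctrl_pairs = _simulate_background(genome, config.n_pairs_control, config, rng_ctrl, "ctrl_")
    return SimulationResult(
        config=config,
        genome=genome,
        truth=truth,
        concatemer=concatemer,
        circ=ReadPairSet(circ_pairs, config.read_length),
        control=ReadPairSet(ctrl_pairs, config.read_length),
    )


# ---------------------------------------------------------------------------
# oracle alignments


def _project_segments(
    template_id: str,
    truth: GroundTruthCircle,
    t_start: int,
    length: int,
) -> list[tuple[str, int, int, int]]:
    """Map a template window to reference segments (chrom, ref_start, len, qstart).

    Concatemer offsets map into the planted locus modulo the element
    length; windows crossing a copy boundary yield one segment per copy.
    """
    if template_id != "concatemer":
        return [(template_id, t_start, length, 0)]
    circle = truth.length
    segments = []
    qstart = 0
    pos = t_start
    while length > 0:
        off = pos % circle
        take = min(circle - off, length)
        segments.append((truth.chrom, truth.start + off, take, qstart))
        qstart += take
        pos += take
        length -= take
    return segments


def _cigar(qstart: int, seg_len: int, read_len: int) -> str:
    parts = []
    if qstart:
        parts.append(f"{qstart}S")
    parts.append(f"{seg_len}M")
    tail = read_len - qstart - seg_len
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts)


def _nm(errors: tuple[int, ...], qstart: int, seg_len: int) -> int:
    return sum(1 for e in errors if qstart <= e < qstart + seg_len)


def emit_oracle_alignments(
    genome: SimulatedGenome,
    reads: ReadPairSet,
    truth: GroundTruthCircle,
    path: str | Path,
) -> int:
    """Write a valid SAM file of provenance-derived alignments.

    Reads fully inside one element copy get a single full-match primary
    alignment at the planted locus; reads straddling a copy boundary get a
    primary plus a soft-clipped supplementary alignment whose anchors are
    the ground-truth start and end (the circular split signature).  Pairs
    whose mates fall into different copies carry the proper-pair bit unset.
    Returns the number of reads skipped as unmappable (always 0 for
    provenance produced by this module).
    """
    r = reads.read_length
    names = [name for name, _ in genome.chromosomes]
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.lengths.items()],
    }
    tid = {name: i for i, name in enumerate(names)}
    skipped = 0
    qual = pysam.qualitystring_to_array("I" * r)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in reads.pairs:
            try:
                segs_left = _project_segments(pair.template_id, truth, pair.offset, r)
                segs_right = _project_segments(
                    pair.template_id, truth, pair.offset + pair.insert - r, r
                )
            except KeyError:
                skipped += 1
                continue
            circle = truth.length
            if pair.template_id == "concatemer":
                same_copy = (pair.offset // circle) == ((pair.offset + pair.insert - 1) // circle)
            else:
                same_copy = True
            proper = same_copy

            def primary_of(segs):
                return max(segs, key=lambda s: s[2])

            p_left = primary_of(segs_left)
            p_right = primary_of(segs_right)
            # template-length from projected primary anchors
            span_lo = min(p_left[1], p_right[1])
            span_hi = max(p_left[1] + p_left[2], p_right[1] + p_right[2])
            tlen = span_hi - span_lo

            for mate_is_left in (True, False):
                segs = segs_left if mate_is_left else segs_right
                mate_segs = p_right if mate_is_left else p_left
                seq = pair.seq_left if mate_is_left else pair.seq_right
                errors = pair.err_left if mate_is_left else pair.err_right
                reverse = not mate_is_left
                is_read1 = (pair.strand == "+") == mate_is_left
                prim = primary_of(segs)
                my_pos = prim[1]
                sign = 1 if (my_pos < mate_segs[1]) or (my_pos == mate_segs[1] and mate_is_left) else -1
                sa_parts = {
                    id(s): f"{s[0]},{s[1] + 1},{'-' if reverse else '+'},"
                    f"{_cigar(s[3], s[2], r)},60,{_nm(errors, s[3], s[2])};"
                    for s in segs
                }
                for seg in segs:
                    chrom, ref_start, seg_len, qstart = seg
                    a = pysam.AlignedSegment()
                    a.query_name = pair.name
                    a.query_sequence = seq
                    a.query_qualities = qual
                    a.reference_id = tid[chrom]
                    a.reference_start = ref_start
                    a.mapping_quality = 60
                    a.cigarstring = _cigar(qstart, seg_len, r)
                    flag = 0x1  # paired
                    if proper:
                        flag |= 0x2
                    if reverse:
                        flag |= 0x10
                    if not reverse:
                        flag |= 0x20  # mate on reverse strand (other mate)
                    flag |= 0x40 if is_read1 else 0x80
                    if seg is not prim:
                        flag |= 0x800
                    a.flag = flag
                    a.next_reference_id = tid[mate_segs[0]]
                    a.next_reference_start = mate_segs[1]
                    a.template_length = sign * tlen
                    tags = [("NM", _nm(errors, qstart, seg_len))]
                    if len(segs) > 1:
                        others = "".join(v for k, v in sa_parts.items() if k != id(seg))
                        tags.append(("SA", others))
                    a.set_tags(tags)
                    out.write(a)
    if skipped:
        logger.warning("emit_oracle_alignments: skipped %d unmappable reads", skipped)
    return skipped


# ---------------------------------------------------------------------------
# file output


def write_fasta(genome: SimulatedGenome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq_pair(reads: ReadPairSet, path1: str | Path, path2: str | Path) -> None:
    """Paired FASTQ (mate 1 / mate 2 files); '.gz' suffix enables gzip."""
    qual = "I" * reads.read_length

    def _open(path):
        path = str(path)
        if path.endswith(".gz"):
            return gzip.open(path, "wt")
        return open(path, "w")

    with _open(path1) as f1, _open(path2) as f2:
        for pair in reads.pairs:
            f1.write(f"@{pair.name}/1\n{pair.mate1}\n+\n{qual}\n")
            f2.write(f"@{pair.name}/2\n{pair.mate2}\n+\n{qual}\n")


def write_ground_truth(truth: GroundTruthCircle, path: str | Path) -> None:
    """BED4 (0-based half-open): chrom, start, end, element id."""
    with open(path, "w") as fh:
        fh.write(f"{truth.chrom}\t{truth.start}\t{truth.end}\t{truth.element_id}\n")


def read_ground_truth(path: str | Path) -> GroundTruthCircle:
    with open(path) as fh:
        chrom, start, end, element_id = fh.readline().rstrip("\n").split("\t")
    return GroundTruthCircle(
        chrom=chrom, start=int(start), end=int(end),
        element_id=element_id, junction_position=int(start),
    )


def write_annotation_db(
    genome: SimulatedGenome,
    truth: GroundTruthCircle,
    path: str | Path,
    config: SimulationConfig,
    n_decoys: int = 2,
) -> None:
    """Annotation FASTA: the planted element plus unrelated decoy repeats."""
    rng = _rng(config, 3)
    with open(path, "w") as fh:
        fh.write(f">{truth.element_id}\n{element_sequence(genome, truth)}\n")
        for i in range(n_decoys):
            codes = rng.integers(0, 4, size=truth.length, dtype=np.uint8)
            fh.write(f">decoy{i + 1}\n{_codes_to_str(codes)}\n")


def simulate_to_dir(
    config: SimulationConfig,
    outdir: str | Path,
    *,
    gzip_reads: bool = False,
) -> dict[str, Path]:
    """Run the full simulation and write every artifact to ``outdir``.

    Writes reference FASTA, paired circSeq/control FASTQ, oracle SAM for
    both datasets, ground-truth BED, an annotation FASTA and a JSON echo of
    the configuration.  Returns the path of each artifact by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate_dataset(config)
    suffix = ".fastq.gz" if gzip_reads else ".fastq"
    paths = {
        "reference": outdir / "reference.fasta",
        "circ_1": outdir / f"circ_1{suffix}",
        "circ_2": outdir / f"circ_2{suffix}",
        "ctrl_1": outdir / f"ctrl_1{suffix}",
        "ctrl_2": outdir / f"ctrl_2{suffix}",
        "circ_sam": outdir / "circ.sam",
        "ctrl_sam": outdir / "ctrl.sam",
        "ground_truth": outdir / "ground_truth.bed",
        "annotation": outdir / "annotation.fasta",
        "config": outdir / "config.json",
    }
    write_fasta(result.genome, paths["reference"])
    write_fastq_pair(result.circ, paths["circ_1"], paths["circ_2"])
    write_fastq_pair(result.control, paths["ctrl_1"], paths["ctrl_2"])
    emit_oracle_alignments(result.genome, result.circ, result.truth, paths["circ_sam"])
    emit_oracle_alignments(result.genome, result.control, result.truth, paths["ctrl_sam"])
    write_ground_truth(result.truth, paths["ground_truth"])
    write_annotation_db(result.genome, result.truth, paths["annotation"], config)
    with open(paths["config"], "w") as fh:
        json.dump({**result.config.__dict__}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["result"] = result  # in-memory handle for callers that want provenance
    return paths
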