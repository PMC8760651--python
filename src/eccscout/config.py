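"""Pipeline configuration and input validation.

Three running modes cover the possible input configurations: ``map``
(circSeq alignments against a reference), ``clu`` (reference-free
comparative clustering of circSeq against a control read set) and ``all``
(both, plus the comparative linking stage).  circSeq data is mandatory in
every mode.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass, field
from pathlib import Path

MODES = ("all", "map", "clu")


@dataclass
class PipelineConfig:
    mode: str = "all"
    circ_reads: tuple[str, ...] = ()
    control_reads: tuple[str, ...] = ()
    reference: str | None = None
    circ_alignments: str | None = None
    control_alignments: str | None = None
    annotation: str | None = None
    output_dir: str = "eccscout_out"
    # mapping-module thresholds
    min_split: int = 5
    breakpoint_tolerance: int = 5
    max_insert: float | None = None  # None: estimated from proper pairs
    merge_distance: int = 0
    min_prominence: float = 1.0
    epsilon: float = 0.1
    # clustering-module thresholds
    sample_pairs: int = 6000
    cluster_k: int = 15
    min_shared: int = 40
    min_cluster: int = 25
    cluster_threshold: float = 0.8
    min_mate_links: int = 2
    min_overlap: int = 31
    assembly_max_reads: int = 400
    # comparative / annotation search
    min_identity: float = 0.8
    min_link_length: int = 50
    seed_k: int = 13
    seed: int = 0
    log_level: str = "INFO"

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


_INT_KEYS = {
    "min_split", "breakpoint_tolerance", "merge_distance", "sample_pairs",
    "cluster_k", "min_shared", "min_cluster", "min_mate_links", "min_overlap",
    "assembly_max_reads", "min_link_length", "seed_k", "seed",
}
_FLOAT_KEYS = {"max_insert", "min_prominence", "epsilon", "cluster_threshold", "min_identity"}
_LIST_KEYS = {"circ_reads", "control_reads"}


def load_config_file(path: str | Path, base: PipelineConfig | None = None) -> PipelineConfig:
    """Flat key=value configuration; '#' starts a comment; lists are comma-split."""
    config = base or PipelineConfig()
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in {f.name for f in dataclasses.fields(PipelineConfig)}:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            if key in _INT_KEYS:
                values[key] = int(value)
            elif key in _FLOAT_KEYS:
                values[key] = float(value)
            elif key in _LIST_KEYS:
                values[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            else:
                values[key] = value
    return config.replace(**values)


def _open_text(path: str) -> object:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def sniff_format(path: str) -> str:
    """'fasta', 'fastq', 'sam' or 'unknown', from the first record bytes."""
    with _open_text(path) as fh:
        line = fh.readline()
        while line and not line.strip():
            line = fh.readline()
        if not line:
            return "unknown"
        if line.startswith(">"):
            return "fasta"
        if line.startswith("@"):
            head = line[1:4]
            if len(line) >= 4 and line[3] == "\t" and head[:2].isalpha() and head[:2].isupper():
                return "sam"
            return "fastq"
        if line.count("\t") >= 10:
            return "sam"  # header-less alignment line
    return "unknown"


def _require(path: str | None, role: str, formats: set[str]) -> None:
    if path is None or (isinstance(path, tuple) and not path):
        raise ValueError(f"{role} is required but was not provided")
    paths = path if isinstance(path, tuple) else (path,)
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"{role} file not found: {p}")
        fmt = sniff_format(p)
        if fmt not in formats:
            raise ValueError(
                f"{role} file {p} looks like {fmt!r}, expected one of {sorted(formats)}"
            )


def validate_inputs(config: PipelineConfig) -> PipelineConfig:
    """Check mode-dependent mandatory inputs before any compute.

    circSeq reads are always mandatory; mode 'map' additionally needs a
    reference and circSeq alignments; mode 'clu' needs control reads;
    mode 'all' needs all of them.
    """
    if config.mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {config.mode!r}")
    reads_formats = {"fasta", "fastq"}
    _require(config.circ_reads, "circSeq reads (--circ)", reads_formats)
    if config.mode in ("map", "all"):
        _require(config.reference, "reference genome (--reference)", {"fasta"})
        _require(config.circ_alignments, "circSeq alignments (--alignments)", {"sam"})
        if config.control_alignments is not None:
            _require(config.control_alignments, "control alignments", {"sam"})
    if config.mode in ("clu", "all"):
        _require(config.control_reads, "control reads (--control)", reads_formats)
    if config.annotation is not None:
        _require(config.annotation, "annotation database", {"fasta"})
    return config
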