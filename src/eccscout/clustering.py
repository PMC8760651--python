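"""Reference-free detection of enriched circles by comparative read clustering.

Rolling-circle amplification makes every circular template look like a
high-copy repeat in the circSeq library, while it stays at genomic copy
number in a non-enriched control.  Clustering circSeq and control reads
*together* by sequence similarity therefore separates amplified circles
from ordinary genomic background: clusters dominated by circSeq reads
(proportion strictly above 80% by default) mark candidate eccDNAs.

The similarity engine is a shared-k-mer graph: two reads are connected
when they share at least ``min_shared`` canonical k-mers, and clusters
are connected components of that graph.  Clusters are joined into
superclusters through cross-cluster mate pairs, and greedy overlap-layout
assembly turns each candidate cluster into contigs for the downstream
comparative search.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pysam
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from .simulate import revcomp, _str_to_codes

logger = logging.getLogger(__name__)


@dataclass
class PreparedRead:
    name: str  # dataset-prefixed, mate-suffixed (/1 or /2)
    sequence: str
    dataset: str  # "circ" | "ctrl"
    mate_partner: str
    source_name: str = ""  # original record name before renaming


@dataclass
class PreparedReads:
    reads: list[PreparedRead]
    equalized_length: int


@dataclass
class ReadCluster:
    """Reads grouped by similarity, with per-dataset counts."""

    id: str
    member_read_names: list[str]
    count_circ: int
    count_ctrl: int
    contigs: list[str] = field(default_factory=list)

    @property
    def proportion_circ(self) -> float:
        total = self.count_circ + self.count_ctrl
        return self.count_circ / total if total else 0.0

    @property
    def size(self) -> int:
        return self.count_circ + self.count_ctrl


@dataclass
class SuperCluster:
    id: str
    cluster_ids: list[str]
    mate_link_counts: dict[tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# preparation


def _read_pairs(files) -> list[tuple[str, str, str]]:
    """(name, mate1, mate2) tuples from one interleaved file or an R1/R2 pair."""
    if isinstance(files, (str, Path)):
        files = [files]
    files = [str(f) for f in files]
    if len(files) == 1:
        entries = [(e.name, e.sequence) for e in pysam.FastxFile(files[0])]
        if len(entries) % 2:
            entries = entries[:-1]
        return [
            (entries[i][0].removesuffix("/1"), entries[i][1], entries[i + 1][1])
            for i in range(0, len(entries), 2)
        ]
    if len(files) != 2:
        raise ValueError("reads must be one interleaved file or an R1/R2 pair")
    with pysam.FastxFile(files[0]) as f1, pysam.FastxFile(files[1]) as f2:
        return [(e1.name.removesuffix("/1"), e1.sequence, e2.sequence) for e1, e2 in zip(f1, f2)]


def pairs_for_coverage(coverage: float, genome_length: int, read_length: int) -> int:
    """Read pairs needed for a target genome coverage (e.g. 4x for clustering)."""
    return int(round(coverage * genome_length / (2 * read_length)))


def prepare_reads(
    circ_files,
    ctrl_files,
    sample_pairs: int,
    seed: int = 0,
) -> PreparedReads:
    """Sub-sample, rename, length-equalize and interlace the two read sets.

    ``sample_pairs`` pairs are drawn uniformly without replacement from
    each dataset (all pairs, with a warning, if fewer exist).  Read names
    become CIRC_/CTRL_-prefixed with /1,/2 mate suffixes; all reads are
    truncated to the minimum read length in the sample and interlaced
    circSeq/control pair by pair.
    """
    rng = np.random.default_rng([seed, 17])
    sampled = {}
    for dataset, files in (("circ", circ_files), ("ctrl", ctrl_files)):
        pairs = _read_pairs(files)
        if not pairs:
            raise ValueError(f"{dataset} read input is empty")
        if len(pairs) <= sample_pairs:
            if len(pairs) < sample_pairs:
                logger.warning(
                    "%s has only %d pairs (%d requested); using all",
                    dataset, len(pairs), sample_pairs,
                )
            chosen = pairs
        else:
            idx = np.sort(rng.choice(len(pairs), size=sample_pairs, replace=False))
            chosen = [pairs[i] for i in idx]
        sampled[dataset] = chosen
    min_len = min(
        min(len(m1), len(m2))
        for chosen in sampled.values()
        for _, m1, m2 in chosen
    )
    reads: list[PreparedRead] = []

    def _emit(dataset: str, index: int, source: str, m1: str, m2: str) -> None:
        prefix = "CIRC_" if dataset == "circ" else "CTRL_"
        base = f"{prefix}{index:06d}"
        reads.append(
            PreparedRead(f"{base}/1", m1[:min_len].upper(), dataset, f"{base}/2", source)
        )
        reads.append(
            PreparedRead(f"{base}/2", m2[:min_len].upper(), dataset, f"{base}/1", source)
        )

    n_interlaced = min(len(sampled["circ"]), len(sampled["ctrl"]))
    for i in range(n_interlaced):
        _emit("circ", i, *sampled["circ"][i])
        _emit("ctrl", i, *sampled["ctrl"][i])
    for dataset in ("circ", "ctrl"):
        for i in range(n_interlaced, len(sampled[dataset])):
            _emit(dataset, i, *sampled[dataset][i])
    return PreparedReads(reads=reads, equalized_length=min_len)


# ---------------------------------------------------------------------------
# clustering


def _canonical_kmer_codes(seqs: Sequence[str], k: int) -> np.ndarray:
    """(n_reads, n_kmers) matrix of canonical (strand-collapsed) k-mer codes."""
    n = len(seqs)
    length = len(seqs[0])
    codes = np.empty((n, length), dtype=np.uint8)
    for i, seq in enumerate(seqs):
        codes[i] = _str_to_codes(seq)
    pow4 = (4 ** np.arange(k, dtype=np.int64))[::-1]
    fwd_windows = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
    fwd = fwd_windows.astype(np.int64) @ pow4
    rc_codes = (3 - codes)[:, ::-1]
    rc_windows = np.lib.stride_tricks.sliding_window_view(rc_codes, k, axis=1)
    rc = (rc_windows.astype(np.int64) @ pow4)[:, ::-1]
    return np.minimum(fwd, rc)


def _shared_kmer_edges(
    kcodes: np.ndarray, min_shared: int, chunk: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs of reads sharing >= min_shared distinct canonical k-mers."""
    n = kcodes.shape[0]
    flat_rows = np.repeat(np.arange(n), kcodes.shape[1])
    _, flat_cols = np.unique(kcodes.ravel(), return_inverse=True)
    # collapse duplicate k-mers within a read: multiplicity must not count
    key = flat_rows.astype(np.int64) * (flat_cols.max() + 1) + flat_cols
    _, keep = np.unique(key, return_index=True)
    rows, cols = flat_rows[keep], flat_cols[keep]
    m = scipy.sparse.csr_matrix(
        (np.ones(rows.size, dtype=np.int32), (rows, cols)),
        shape=(n, int(cols.max()) + 1 if cols.size else 1),
    )
    mt = m.T.tocsr()
    out_r, out_c = [], []
    for lo in range(0, n, chunk):
        block = m[lo:lo + chunk] @ mt
        block = block.tocoo()
        mask = (block.data >= min_shared) & (block.row + lo != block.col)
        out_r.append(block.row[mask].astype(np.int64) + lo)
        out_c.append(block.col[mask].astype(np.int64))
    if not out_r:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(out_r), np.concatenate(out_c)


def cluster_reads(
    prepared: PreparedReads,
    k: int = 15,
    min_shared: int = 40,
    min_cluster: int = 25,
) -> list[ReadCluster]:
    """Connected components of the shared-canonical-k-mer read graph.

    Components smaller than ``min_cluster`` are discarded as noise.
    Clusters are returned largest first, with per-dataset read counts.
    """
    if k > prepared.equalized_length:
        raise ValueError(
            f"k={k} exceeds equalized read length {prepared.equalized_length}"
        )
    n = len(prepared.reads)
    if n == 0:
        return []
    seqs = [r.sequence for r in prepared.reads]
    kcodes = _canonical_kmer_codes(seqs, k)
    rows, cols = _shared_kmer_edges(kcodes, min_shared)
    adj = scipy.sparse.csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    keep = np.flatnonzero(sizes >= min_cluster)
    order = sorted(keep, key=lambda lab: (-int(sizes[lab]), int(np.flatnonzero(labels == lab)[0])))
    clusters = []
    for rank, lab in enumerate(order, start=1):
        members = np.flatnonzero(labels == lab)
        names = [prepared.reads[i].name for i in members]
        count_circ = sum(1 for i in members if prepared.reads[i].dataset == "circ")
        clusters.append(
            ReadCluster(
                id=f"CL{rank:04d}",
                member_read_names=names,
                count_circ=count_circ,
                count_ctrl=len(members) - count_circ,
            )
        )
    return clusters


def select_candidate_clusters(
    clusters: Sequence[ReadCluster], threshold: float = 0.8
) -> list[ReadCluster]:
    """Clusters whose circSeq read proportion is strictly above ``threshold``."""
    return [c for c in clusters if c.proportion_circ > threshold]


def link_superclusters(
    clusters: Sequence[ReadCluster], min_mate_links: int = 2
) -> list[SuperCluster]:
    """Join clusters bridged by >= min_mate_links mate pairs.

    Superclusters are the connected components of the cluster-link graph;
    unlinked clusters remain singleton superclusters.
    """
    cluster_of: dict[str, str] = {}
    for cluster in clusters:
        for name in cluster.member_read_names:
            cluster_of[name] = cluster.id
    link_counts: dict[tuple[str, str], int] = {}
    for cluster in clusters:
        for name in cluster.member_read_names:
            if not name.endswith("/1"):
                continue
            partner = name[:-2] + "/2"
            other = cluster_of.get(partner)
            if other is None or other == cluster.id:
                continue
            key = tuple(sorted((cluster.id, other)))
            link_counts[key] = link_counts.get(key, 0) + 1
    graph = nx.Graph()
    graph.add_nodes_from(c.id for c in clusters)
    strong = {k: v for k, v in link_counts.items() if v >= min_mate_links}
    graph.add_edges_from(strong)
    supers = []
    components = sorted(nx.connected_components(graph), key=lambda comp: sorted(comp)[0])
    for i, comp in enumerate(components, start=1):
        ids = sorted(comp)
        supers.append(
            SuperCluster(
                id=f"SC{i:03d}",
                cluster_ids=ids,
                mate_link_counts={
                    k: v for k, v in strong.items() if k[0] in comp or k[1] in comp
                },
            )
        )
    return supers


# ---------------------------------------------------------------------------
# contig assembly


def _max_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest L >= min_overlap with a[-L:] == b[:L]; len(b) if b is inside a."""
    if len(b) < min_overlap:
        return 0
    probe = b[:min_overlap]
    start = 0
    while True:
        p = a.find(probe, start)
        if p == -1:
            return 0
        tail = len(a) - p
        if tail >= len(b):
            if a[p:p + len(b)] == b:
                return len(b)  # containment
        elif a[p:] == b[:tail]:
            return tail
        start = p + 1


def _best_pair_overlap(a: str, b: str, min_overlap: int) -> tuple[int, str]:
    """Best merge of two sequences over relative orientations.

    Modes: 'ab' (a then b), 'ba', 'arb' (a then revcomp(b)), 'rba'.
    """
    rb = revcomp(b)
    options = [
        (_max_overlap(a, b, min_overlap), "ab"),
        (_max_overlap(b, a, min_overlap), "ba"),
        (_max_overlap(a, rb, min_overlap), "arb"),
        (_max_overlap(rb, a, min_overlap), "rba"),
    ]
    return max(options)


def _merge(a: str, b: str, length: int, mode: str) -> str:
    if mode in ("arb", "rba"):
        b = revcomp(b)
        mode = "ab" if mode == "arb" else "ba"
    first, second = (a, b) if mode == "ab" else (b, a)
    if length >= len(second):  # containment
        return first
    return first + second[length:]


def build_contigs(
    sequences: Sequence[str],
    min_overlap: int = 31,
    max_reads: int = 400,
) -> list[str]:
    """Greedy overlap-layout assembly of a cluster's reads.

    Repeatedly merges the pair with the longest exact suffix-prefix
    overlap (>= min_overlap), trying both orientations; exact duplicates
    are collapsed first and clusters larger than ``max_reads`` are
    deterministically down-sampled.  Unmerged sequences are emitted as
    their own contigs; contigs are ordered longest first.
    """
    seqs = sorted(set(s.upper() for s in sequences if s))
    if len(seqs) > max_reads:
        idx = np.unique(np.linspace(0, len(seqs) - 1, max_reads).astype(int))
        seqs = [seqs[i] for i in idx]
    alive: dict[int, str] = dict(enumerate(seqs))
    heap: list[tuple[int, int, int, str]] = []

    def _push_pairs(i: int, others: Iterable[int]) -> None:
        for j in others:
            if j == i:
                continue
            length, mode = _best_pair_overlap(alive[i], alive[j], min_overlap)
            if length >= min_overlap:
                heapq.heappush(heap, (-length, i, j, mode))

    ids = list(alive)
    for pos, i in enumerate(ids):
        _push_pairs(i, ids[pos + 1:])
    next_id = len(seqs)
    while heap:
        neg_len, i, j, mode = heapq.heappop(heap)
        if i not in alive or j not in alive:
            continue
        # lazily re-validate: sequences never change while alive, so entry holds
        merged = _merge(alive[i], alive[j], -neg_len, mode)
        del alive[i], alive[j]
        alive[next_id] = merged
        _push_pairs(next_id, list(alive))
        next_id += 1
    return sorted(alive.values(), key=lambda s: (-len(s), s))


def contigs_for_cluster(
    cluster: ReadCluster,
    prepared: PreparedReads,
    min_overlap: int = 31,
    max_reads: int = 400,
) -> list[str]:
    """Assemble a cluster's member reads; stores and returns the contigs."""
    by_name = {r.name: r.sequence for r in prepared.reads}
    seqs = [by_name[name] for name in cluster.member_read_names if name in by_name]
    cluster.contigs = build_contigs(seqs, min_overlap=min_overlap, max_reads=max_reads)
    return cluster.contigs
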