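"""Ungapped seed-and-extend local similarity search.

Exact k-mer seeds are extended in both directions without gaps under
+1/-2 match/mismatch scoring with an X-drop cutoff.  Hits are reported
with identity, aligned length and score; searching the reverse-complement
query covers the minus strand.  This is the similarity primitive behind
both candidate annotation and the contig-to-region comparative search.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import revcomp


@dataclass(frozen=True)
class LocalMatch:
    """One ungapped local alignment (query/subject intervals 0-based half-open).

    Coordinates always refer to the *original* (plus-strand) query and the
    subject as given; ``strand`` is '-' when the reverse complement of the
    query matched.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    matches: int
    aligned_length: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length


def _index_kmers(subject: bytes, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = {}
    for j in range(len(subject) - k + 1):
        kmer = subject[j:j + k]
        index.setdefault(kmer, []).append(j)
    return index


def _extend(
    q: bytes,
    s: bytes,
    i: int,
    j: int,
    k: int,
    match: int,
    mismatch: int,
    xdrop: int,
) -> tuple[int, int, int, int, int]:
    """Extend seed q[i:i+k] == s[j:j+k]; return (qs, qe, ss, matches, score)."""
    # rightward
    score = best = k * match
    matches = best_matches = k
    qe, se = i + k, j + k
    best_qe = qe
    while qe < len(q) and se < len(s):
        if q[qe] == s[se]:
            score += match
            matches += 1
        else:
            score += mismatch
        qe += 1
        se += 1
        if score > best:
            best, best_qe, best_matches = score, qe, matches
        elif score < best - xdrop:
            break
    # leftward from the best right extent
    score = best
    matches = best_matches
    qs, ss = i, j
    best_qs, best_ss = qs, ss
    while qs > 0 and ss > 0:
        qs -= 1
        ss -= 1
        if q[qs] == s[ss]:
            score += match
            matches += 1
        else:
            score += mismatch
        if score > best:
            best, best_qs, best_ss, best_matches = score, qs, ss, matches
        elif score < best - xdrop:
            break
    return best_qs, best_qe, best_ss, best_matches, best


def seed_and_extend(
    query: str,
    subject: str,
    *,
    seed_k: int = 13,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 20,
    min_identity: float = 0.8,
    min_length: int | None = None,
    both_strands: bool = True,
) -> list[LocalMatch]:
    """All ungapped local matches of ``query`` against ``subject``.

    Matches must reach ``min_identity`` over at least ``min_length``
    aligned bases (default 3 * seed_k).  Seeds falling inside an already
    extended alignment on the same diagonal are skipped.  Results are
    sorted best-first: by score, then identity, then coordinates.
    """
    if min_length is None:
        min_length = 3 * seed_k
    s = subject.upper().encode("ascii")
    index = _index_kmers(s, seed_k)
    results: list[LocalMatch] = []
    strands = ("+", "-") if both_strands else ("+",)
    qlen = len(query)
    for strand in strands:
        oriented = query.upper() if strand == "+" else revcomp(query)
        q = oriented.encode("ascii")
        covered: dict[int, int] = {}  # diagonal -> query end already extended
        for i in range(len(q) - seed_k + 1):
            positions = index.get(q[i:i + seed_k])
            if not positions:
                continue
            for j in positions:
                diag = j - i
                if covered.get(diag, -1) > i:
                    continue
                qs, qe, ss, matches, score = _extend(
                    q, s, i, j, seed_k, match, mismatch, xdrop
                )
                covered[diag] = qe
                length = qe - qs
                if length < min_length or matches / length < min_identity:
                    continue
                if strand == "+":
                    oqs, oqe = qs, qe
                else:
                    oqs, oqe = qlen - qe, qlen - qs
                results.append(
                    LocalMatch(
                        query_start=oqs,
                        query_end=oqe,
                        subject_start=ss,
                        subject_end=ss + length,
                        strand=strand,
                        matches=matches,
                        aligned_length=length,
                        score=score,
                    )
                )
    # drop duplicate intervals kept from overlapping seeds
    unique = {}
    for m in results:
        key = (m.strand, m.query_start, m.query_end, m.subject_start)
        if key not in unique or m.score > unique[key].score:
            unique[key] = m
    out = list(unique.values())
    out.sort(key=lambda m: (-m.score, -m.identity, m.subject_start, m.query_start, m.strand))
    return out
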