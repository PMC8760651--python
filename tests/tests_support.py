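"""Shared helpers for the test suite: random inputs and brute-force oracles."""

import numpy as np


def random_track_array(rng: np.random.Generator, length: int) -> np.ndarray:
    """Coverage-like array: smoothed positive noise plus rectangular bumps."""
    base = rng.gamma(2.0, 1.0, size=length)
    x = np.convolve(base, np.ones(5) / 5, mode="same")
    for _ in range(int(rng.integers(0, 4))):
        center = int(rng.integers(0, length))
        width = int(rng.integers(3, max(4, length // 10)))
        height = float(rng.uniform(0.5, 8.0))
        lo, hi = max(0, center - width), min(length, center + width)
        x[lo:hi] += height
    return x


def shared_kmer_components(seqs, k, min_shared, min_cluster):
    """Brute-force oracle: all-pairs canonical k-mer counting + flood fill."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def canonical(kmer):
        rc = "".join(comp[b] for b in reversed(kmer))
        return min(kmer, rc)

    kmer_sets = [
        {canonical(s[i:i + k]) for i in range(len(s) - k + 1)} for s in seqs
    ]
    n = len(seqs)
    adjacency = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if len(kmer_sets[i] & kmer_sets[j]) >= min_shared:
                adjacency[i].append(j)
                adjacency[j].append(i)
    seen = [False] * n
    components = []
    for start in range(n):
        if seen[start]:
            continue
        stack, members = [start], []
        seen[start] = True
        while stack:
            node = stack.pop()
            members.append(node)
            for nb in adjacency[node]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        if len(members) >= min_cluster:
            components.append(frozenset(members))
    return set(components)


def prominence_oracle(x, min_prominence):
    """O(n^2) reference implementation of prominence-filtered peaks."""
    n = len(x)
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] <= x[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j + 1 < n and x[j + 1] < x[i]:
            # plateau [i, j] is a local maximum; apex = leftmost position
            left_base = x[i]
            k = i - 1
            while k >= 0 and x[k] <= x[i]:  # stop at nearest strictly higher point
                left_base = min(left_base, x[k])
                k -= 1
            right_base = x[i]
            k = j + 1
            while k < n and x[k] <= x[i]:
                right_base = min(right_base, x[k])
                k += 1
            prominence = x[i] - max(left_base, right_base)
            if prominence >= min_prominence:
                peaks.append((i, x[i], prominence))
        i = j + 1
    return peaks
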