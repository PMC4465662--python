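"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — quadratic dynamic programming,
exhaustive enumeration, explicit pair counting — and shares no code
with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from math import inf

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_global_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Affine-gap global alignment score; a gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first residue of a gap
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    Ix = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def _is_spanning_tree(nodes: frozenset, edge_subset) -> bool:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merged = 0
    for u, v, _ in edge_subset:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[ru] = rv
        merged += 1
    return merged == len(nodes) - 1


def max_forest_weight_bruteforce(nodes, weighted_edges) -> float:
    """Maximum spanning-forest weight by exhaustive per-component enumeration.

    ``weighted_edges`` is a list of (u, v, w).  Intended for graphs of at
    most ~8 nodes.
    """
    # split into connected components first
    adj: dict = {n: set() for n in nodes}
    for u, v, _ in weighted_edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set = set()
    total = 0.0
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        comp_edges = [(u, v, w) for u, v, w in weighted_edges if u in comp and v in comp]
        k = len(comp) - 1
        if k == 0:
            continue
        best = -inf
        for subset in itertools.combinations(comp_edges, k):
            if _is_spanning_tree(frozenset(comp), subset):
                best = max(best, sum(w for _, _, w in subset))
        total += best
    return total


def ari_paircount(labels_true: list, labels_pred: list) -> float:
    """Adjusted Rand index by explicit O(n^2) pair enumeration."""
    n = len(labels_true)
    a = b = c = d = 0  # same/same, same/diff, diff/same, diff/diff
    for i in range(n):
        for j in range(i + 1, n):
            st = labels_true[i] == labels_true[j]
            sp = labels_pred[i] == labels_pred[j]
            if st and sp:
                a += 1
            elif st and not sp:
                b += 1
            elif not st and sp:
                c += 1
            else:
                d += 1
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0
    return 2.0 * (a * d - b * c) / denom


def at_windows_bruteforce(seq: str, window: int, min_fraction: float) -> list[tuple[int, float]]:
    """All (start, AT fraction) windows meeting the threshold, by slicing."""
    s = seq.upper()
    out = []
    for start in range(len(s) - window + 1):
        chunk = s[start : start + window]
        frac = sum(chunk.count(c) for c in "AT") / window
        if frac >= min_fraction:
            out.append((start, frac))
    return out
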