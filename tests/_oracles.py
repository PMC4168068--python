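"""Independent brute-force oracles used only by the test suite.

These are deliberately written as plain, slow, obviously-correct Python
(dict-of-dict DP tables, recursive reachability) and share no code with
the package implementation they check.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive affine-gap Smith-Waterman score; gap of length L costs
    gap_open + L * gap_extend."""
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left moves)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up moves)
    best = 0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + blosum62(a[i - 1], b[j - 1])
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def nw_global(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Full quadratic global DP with diag > up > left tie preference.

    Returns (score, n_identical, alignment_length).
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = gap * i
        P[i][0] = 1
    for j in range(1, m + 1):
        H[0][j] = gap * j
        P[0][j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = H[i - 1][j] + gap
            left = H[i][j - 1] + gap
            best = max(diag, up, left)
            H[i][j] = best
            P[i][j] = 0 if diag == best else (1 if up == best else 2)
    i, j = n, m
    ident = 0
    length = 0
    while i > 0 or j > 0:
        length += 1
        p = P[i][j]
        if p == 0:
            if a[i - 1] == b[j - 1]:
                ident += 1
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return H[n][m], ident, length


def karlin_altschul_evalue(raw_score: int, m: int, n: int,
                           lam: float = 0.267, K: float = 0.041) -> float:
    return K * m * n * math.exp(-lam * raw_score)


def components(nodes, edges):
    """Connected components by plain recursive reachability."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    out = []
    for start in nodes:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        out.append(frozenset(comp))
    return set(out)


def word_hits(a: str, b: str, w: int):
    """Exhaustive double-loop dotplot forward hits."""
    hits = set()
    for i in range(len(a) - w + 1):
        for j in range(len(b) - w + 1):
            if a[i : i + w] == b[j : j + w]:
                hits.add((i, j))
    return hits


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq.upper()))
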