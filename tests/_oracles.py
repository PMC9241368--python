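"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately simple and slow: plain dynamic programming,
exhaustive enumeration, and closed-form formulas, sharing no code with the
package internals they check.
"""

from __future__ import annotations

import math

from scipy.stats import hypergeom


def sw_affine_score(a: str, b: str, match=1.0, mismatch=-2.0, gap_open=-5.0, gap_extend=-2.0) -> float:
    """O(nm) Smith-Waterman score with affine gaps.

    A gap of length L scores gap_open + (L-1)*gap_extend (the first gapped
    base pays the open score).
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (move along b)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            diag = H[i - 1][j - 1] + (match if ai == b[j - 1] else mismatch)
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def fisher_two_sided(a: int, b: int, c: int, d: int, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher p by exhaustive enumeration over the margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = hypergeom(n, c1, r1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + rel_tol):
            total += px
    return min(total, 1.0)


CODON_TABLE = {}


def _build_codon_table():
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


def expected_ns_s_fraction() -> float:
    """Fraction of the 9 single-base changes per codon that are
    nonsynonymous, averaged over all 64 codons (uniform codon usage)."""
    ns = s = 0
    for codon, aa in CODON_TABLE.items():
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mutated = codon[:pos] + alt + codon[pos + 1 :]
                if CODON_TABLE[mutated] == aa:
                    s += 1
                else:
                    ns += 1
    return ns / (ns + s)


def point_in_intervals(position: int, intervals: list[tuple[int, int]]) -> bool:
    """Linear scan point-in-interval check (half-open intervals)."""
    return any(a <= position < b for a, b in intervals)


def paired_t(x, y):
    """Closed-form paired two-sided t-test: returns (t, df, p)."""
    from scipy.stats import t as tdist

    diffs = [xi - yi for xi, yi in zip(x, y)]
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, n - 1, p


def random_additive_tree(rng, n_taxa: int):
    """A random unrooted binary tree with positive branch lengths and its
    exact leaf-to-leaf distance matrix.

    Returns (newick, labels, distance matrix as dict of dicts).
    """
    import itertools

    labels = [f"T{i}" for i in range(n_taxa)]
    # grow a tree: start from 3-star, attach leaves to random edges
    # represent as adjacency with branch lengths
    next_internal = [n_taxa]

    def new_internal():
        v = f"I{next_internal[0]}"
        next_internal[0] += 1
        return v

    adj: dict[str, dict[str, float]] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    def rand_len():
        return round(float(rng.uniform(0.5, 5.0)), 3)

    center = new_internal()
    for leaf in labels[:3]:
        connect(center, leaf, rand_len())
    for leaf in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        mid = new_internal()
        disconnect(u, v)
        split = w / 2
        connect(u, mid, split)
        connect(mid, v, w - split)
        connect(mid, leaf, rand_len())

    # all-pairs distances among leaves by DFS
    dist = {l: {} for l in labels}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in labels:
            dist[src][dst] = seen[dst]
    return adj, labels, dist
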