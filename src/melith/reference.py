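"""Brute-force reference implementations used to validate the fast paths.

Everything here is written for transparency, not speed: Fisher's exact
test by full enumeration of tables with fixed margins, the rank-sum test
by complete permutation, and minimum parsimony by exhaustive search over
unrooted binary trees scored with Fitch counting.  These serve as
independent oracles in the test suite and the acceptance checks; the
pipeline itself never calls them.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf

import numpy as np

__all__ = [
    "fisher_exact_enumeration",
    "rank_sum_permutation",
    "enumerate_unrooted_trees",
    "fitch_cost",
    "min_parsimony_cost",
]


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by enumerating all tables
    with the observed margins and summing probabilities <= the observed
    one (probability ordering)."""
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, c1, r1)
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def rank_sum_permutation(x, y) -> float:
    """Two-sided rank-sum p by complete enumeration of group assignments.

    Uses mid-ranks for ties; two-sidedness by the absolute deviation of
    the rank sum from its null mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    rank_vals = np.empty(n)
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        rank_vals[i:j] = (i + j + 1) / 2.0
        i = j
    ranks[order] = rank_vals
    obs = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2.0
    obs_dev = abs(obs - mean)
    hits = total = 0
    for idx in combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# exhaustive parsimony


def enumerate_unrooted_trees(taxa: list):
    """Yield every unrooted binary tree over the taxa as an edge list.

    Trees are built by stepwise addition: taxon k+1 is attached to each
    edge of each tree over the first k taxa ((2n-5)!! trees).  Internal
    nodes are negative integers; leaves are the taxa themselves.
    """
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def grow(edges: list[tuple], next_internal: int, remaining: list):
        if not remaining:
            yield edges
            return
        taxon = remaining[0]
        for i in range(len(edges)):
            u, v = edges[i]
            new = edges[:i] + edges[i + 1:] + [
                (u, next_internal), (next_internal, v), (next_internal, taxon)
            ]
            yield from grow(new, next_internal - 1, remaining[1:])

    base = [(taxa[0], -1), (taxa[1], -1), (taxa[2], -1)]
    yield from grow(base, -2, list(taxa[3:]))


def fitch_cost(edges: list[tuple], states: dict) -> int:
    """Minimum changes for one binary (0/1) character on one tree.

    ``states`` maps each leaf taxon to its state; internal nodes
    (negative ints) are inferred by the exact small-parsimony dynamic
    programme, which is valid on polytomies too.  The tree is rooted at
    the first leaf in ``states`` (its state is fixed).
    """
    adjacency: dict = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    root = next(iter(states))
    INF = float("inf")

    def post(node, parent) -> tuple[float, float]:
        kids = [w for w in adjacency[node] if w != parent]
        if not kids:
            return (INF, 0.0) if states[node] == 1 else (0.0, INF)
        c0 = c1 = 0.0
        for w in kids:
            k0, k1 = post(w, node)
            c0 += min(k0, k1 + 1)
            c1 += min(k1, k0 + 1)
        if node in states:  # rooted at a leaf: its own state is fixed
            if states[node] == 1:
                c0 = INF
            else:
                c1 = INF
        return c0, c1

    c0, c1 = post(root, None)
    return int(min(c0, c1))


def min_parsimony_cost(patterns: dict, regions: list, outgroup: str = "__normal__") -> int:
    """Minimum weighted parsimony cost over all unrooted binary trees.

    ``patterns`` maps a frozenset of regions (a presence pattern) to its
    variant count (weight).  A normal outgroup with all-absent states is
    included so rooting matters the same way it does in the pipeline.
    """
    taxa = list(regions) + [outgroup]
    best = inf
    for edges in enumerate_unrooted_trees(taxa):
        cost = 0
        for pattern, weight in patterns.items():
            states = {r: (1 if r in pattern else 0) for r in regions}
            states[outgroup] = 0
            cost += weight * fitch_cost(edges, states)
            if cost >= best:
                break
        best = min(best, cost)
    return int(best)
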