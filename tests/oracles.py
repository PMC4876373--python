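"""Independent test oracles.

Everything here is deliberately written in the most naive way possible —
plain loops, direct Monte-Carlo resampling — and shares no code with the
package implementations it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def isolation_index_naive(d: np.ndarray, side: list[int]) -> float:
    """Bandelt-Dress isolation index by direct quadruple loop over indices."""
    k = d.shape[0]
    other = [i for i in range(k) if i not in side]
    best = np.inf
    for i in side:
        for i2 in side:
            for j in other:
                for j2 in other:
                    m = max(
                        d[i, j] + d[i2, j2],
                        d[i, j2] + d[i2, j],
                        d[i, i2] + d[j, j2],
                    )
                    best = min(best, m - d[i, i2] - d[j, j2])
    return 0.5 * best


def positive_splits_naive(d: np.ndarray) -> dict[frozenset, float]:
    """All bipartitions with positive isolation index, by brute force.

    Keys are frozensets of the taxon *indices* on the side containing 0.
    """
    k = d.shape[0]
    out = {}
    rest = list(range(1, k))
    for r in range(k - 1):
        for combo in combinations(rest, r):
            side = [0, *combo]
            w = isolation_index_naive(d, side)
            if w > 1e-10:
                out[frozenset(side)] = w
    return out


def random_tree_metric(n_taxa: int, rng: np.random.Generator) -> np.ndarray:
    """Additive distance matrix from a random binary tree topology.

    Built by random sequential attachment with positive branch lengths;
    path lengths between leaves give the metric.
    """
    # adjacency as dict node -> list of (node, length); leaves are 0..n-1
    next_id = n_taxa
    adj: dict[int, list[tuple[int, float]]] = {}

    def connect(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    connect(0, 1, float(rng.uniform(0.1, 2.0)))
    edges = [(0, 1)]
    for leaf in range(2, n_taxa):
        a, b = edges[rng.integers(len(edges))]
        mid = next_id
        next_id += 1
        w_ab = next(w for nb, w in adj[a] if nb == b)
        adj[a] = [(nb, w) for nb, w in adj[a] if nb != b]
        adj[b] = [(nb, w) for nb, w in adj[b] if nb != a]
        split = float(rng.uniform(0.2, 0.8)) * w_ab
        connect(a, mid, split)
        connect(mid, b, w_ab - split)
        connect(mid, leaf, float(rng.uniform(0.1, 2.0)))
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (mid, leaf)]
    # all-pairs leaf distances by BFS/DFS from each leaf
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in range(n_taxa):
            d[src, t] = dist[t]
    np.fill_diagonal(d, 0.0)
    return d


def mc_f3_moments(pX, pA, pB, nX, nA, nB, n_reps, rng):
    """Monte-Carlo mean and variance of the corrected per-marker f3 estimator."""
    u = rng.binomial(nX, pX, n_reps) / nX
    a = rng.binomial(nA, pA, n_reps) / nA
    b = rng.binomial(nB, pB, n_reps) / nB
    t = (u - a) * (u - b) - u * (1.0 - u) / (nX - 1.0)
    return float(t.mean()), float(t.var(ddof=1))


def balding_nichols_draw(p, c, rng, size=None):
    """Direct Balding-Nichols child-frequency draws with mean p."""
    scale = (1.0 - c) / c
    return rng.beta(p * scale, (1.0 - p) * scale, size=size)
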