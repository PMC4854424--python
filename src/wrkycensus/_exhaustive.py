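"""Brute-force references for validating the distance-tree pipeline.

Small-n utilities that are deliberately naive: enumerate every unrooted
leaf-labelled topology, fit branch lengths to a distance matrix by
ordinary least squares, and pick the topology with minimal residual.
Exact but exponential — intended for n <= 6, where they provide an
independent check of neighbor joining.  Also generates random additive
matrices (path distances of random trees) whose generating topology is
known by construction.
"""

from __future__ import annotations

import itertools

import numpy as np


def _star(labels):
    # edges: list of frozenset bipartition sides will be derived later;
    # represent topology as a set of edges between node ids.
    # nodes: 0..n-1 leaves; internal nodes numbered from n upward.
    a, b, c = labels[:3]
    return {"edges": [(a, "i0"), (b, "i0"), (c, "i0")], "next": 1}


def enumerate_topologies(labels: list) -> list[list[tuple]]:
    """All unrooted binary topologies on the labels, as edge lists."""
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    topos = [_star(labels)]
    for leaf in labels[3:]:
        nxt = []
        for t in topos:
            for k, (u, v) in enumerate(t["edges"]):
                mid = f"i{t['next']}"
                edges = list(t["edges"])
                edges[k : k + 1] = [(u, mid), (mid, v), (leaf, mid)]
                nxt.append({"edges": edges, "next": t["next"] + 1})
        topos = nxt
    return [t["edges"] for t in topos]


def _edge_bipartitions(edges, labels):
    """For each edge, the leaf set on one side (canonicalised)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    ref = min(labels)
    label_set = set(labels)
    out = []
    for u, v in edges:
        # leaves reachable from u without crossing (u, v)
        stack, seen = [u], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in label_set:
                side.add(node)
            for w in adj[node]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if ref in side:
            side = label_set - side
        out.append(frozenset(side))
    return out


def ls_fit(edges, labels, dmat: np.ndarray, index: dict) -> tuple[float, np.ndarray]:
    """Least-squares branch lengths for one topology; returns (SSQ, x)."""
    bips = _edge_bipartitions(edges, labels)
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        d[r] = dmat[index[a], index[b]]
        for c, side in enumerate(bips):
            if (a in side) != (b in side):
                A[r, c] = 1.0
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = A @ x - d
    return float(resid @ resid), x


def best_ls_topology(labels: list, dmat: np.ndarray):
    """Exhaustive LS search; returns (bipartition set, path-distance dict)."""
    index = {l: i for i, l in enumerate(labels)}
    best = None
    for edges in enumerate_topologies(labels):
        ssq, x = ls_fit(edges, labels, dmat, index)
        if best is None or ssq < best[0] - 1e-12:
            best = (ssq, edges, x)
    ssq, edges, x = best
    bips = _edge_bipartitions(edges, labels)
    nontrivial = {
        b for b in bips if 1 < len(b) < len(labels) - 1
    }
    # fitted leaf-to-leaf distances
    pairs = {}
    for a, b in itertools.combinations(sorted(labels), 2):
        total = 0.0
        for c, side in enumerate(bips):
            if (a in side) != (b in side):
                total += x[c]
        pairs[(a, b)] = total
    return nontrivial, pairs


def random_additive_matrix(labels: list, rng: np.random.Generator):
    """Path-distance matrix of a random binary tree with known splits."""
    edges = None
    topos = None
    # build one random topology by random sequential insertion
    t = _star(labels)
    for leaf in labels[3:]:
        k = rng.integers(0, len(t["edges"]))
        u, v = t["edges"][k]
        mid = f"i{t['next']}"
        es = list(t["edges"])
        es[k : k + 1] = [(u, mid), (mid, v), (leaf, mid)]
        t = {"edges": es, "next": t["next"] + 1}
    edges = t["edges"]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    bips = _edge_bipartitions(edges, labels)
    n = len(labels)
    index = {l: i for i, l in enumerate(labels)}
    dmat = np.zeros((n, n))
    for a, b in itertools.combinations(labels, 2):
        total = sum(
            lengths[c] for c, side in enumerate(bips) if (a in side) != (b in side)
        )
        dmat[index[a], index[b]] = dmat[index[b], index[a]] = total
    nontrivial = {b for b in bips if 1 < len(b) < n - 1}
    return dmat, nontrivial
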