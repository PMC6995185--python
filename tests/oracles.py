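"""Independent oracles used by the test suite.

The neighbor-joining oracle enumerates every unrooted topology for small
taxon sets and fits branch lengths by ordinary least squares on the
path-indicator system, returning the best-fitting tree. It shares no code
with the package's NJ implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_topologies(n: int):
    """All unrooted binary topologies over leaves 0..n-1 as edge lists.

    Built by stepwise addition: each new leaf subdivides every existing
    edge, which generates each topology exactly once ((2n-5)!! trees).
    """
    assert n >= 3
    base = [(0, n), (1, n), (2, n)]  # internal node ids start at n
    trees = [base]
    for leaf in range(3, n):
        new_trees = []
        for tree in trees:
            for i, (u, v) in enumerate(tree):
                mid = max(max(e) for e in tree) + 1
                t = tree[:i] + tree[i + 1 :]
                t = t + [(u, mid), (v, mid), (leaf, mid)]
                new_trees.append(t)
        trees = new_trees
    return trees


def _leaf_paths(edges, n):
    adj: dict[int, list[tuple[int, int]]] = {}
    for ei, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, ei))
        adj.setdefault(v, []).append((u, ei))
    paths = {}
    for a in range(n):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _parent, path = stack.pop()
            if node < n and node != a:
                paths[(a, node)] = path
                continue
            for nxt, ei in adj[node]:
                if nxt in seen:
                    continue
                seen.add(nxt)
                stack.append((nxt, node, path + [ei]))
    return paths


def ls_fit(edges, n, D):
    """OLS branch lengths for a topology; returns (lengths, sse)."""
    paths = _leaf_paths(edges, n)
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for ei in paths[(a, b)]:
            A[r, ei] = 1.0
        d[r] = D[a, b]
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    sse = float(((A @ x - d) ** 2).sum())
    return x, sse


def best_ls_tree(D):
    """Exhaustive least-squares tree search; returns (edges, lengths)."""
    n = D.shape[0]
    best = None
    for edges in enumerate_topologies(n):
        x, sse = ls_fit(edges, n, D)
        if best is None or sse < best[2] - 1e-12:
            best = (edges, x, sse)
    return best[0], best[1]


def edge_bipartitions(edges, lengths, n, labels):
    """Map each edge to (frozenset of leaf labels on one side, length)."""
    out = {}
    for ei, (u, v) in enumerate(edges):
        rest = [e for e in edges if e != (u, v)]
        adj: dict[int, list[int]] = {}
        for a, b in rest:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        # leaves reachable from u without crossing the edge
        stack, seen = [u], {u}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nxt in adj.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        names = frozenset(labels[i] for i in side)
        comp = frozenset(labels) - names
        canon = names if sorted(names) < sorted(comp) else comp
        out[canon] = float(lengths[ei])
    return out


def random_additive_matrix(n, rng):
    """Random binary topology with U(0.5, 2) edge lengths; returns
    (distance matrix, bipartition->length map, labels)."""
    # draw a topology by random stepwise addition (uniform enough for tests)
    edges = [(0, n), (1, n), (2, n)]
    for leaf in range(3, n):
        i = rng.integers(len(edges))
        u, v = edges.pop(int(i))
        mid = max(max(e) for e in edges + [(u, v)]) + 1
        edges += [(u, mid), (v, mid), (leaf, mid)]
    lengths = rng.uniform(0.5, 2.0, size=len(edges))
    paths = _leaf_paths(edges, n)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                key = (a, b) if (a, b) in paths else (b, a)
                D[a, b] = sum(lengths[ei] for ei in paths[key])
    D = (D + D.T) / 2  # exact float symmetry regardless of summation order
    labels = [f"t{i}" for i in range(n)]
    bps = edge_bipartitions(edges, lengths, n, labels)
    return D, bps, labels


def tree_to_bipartitions(tree, labels):
    """Bipartition->length map of an ervkit NJ tree (Bio.Phylo)."""
    allset = frozenset(labels)
    out = {}
    for clade in tree.find_clades():
        if clade is tree.root or clade.branch_length is None:
            continue
        names = frozenset(t.name for t in clade.get_terminals())
        comp = allset - names
        canon = names if sorted(names) < sorted(comp) else comp
        out[canon] = float(clade.branch_length)
    return out
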