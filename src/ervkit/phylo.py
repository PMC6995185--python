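"""Distance-based phylogenetics: p-distance and Kimura 2-parameter
distances with pairwise deletion, neighbor-joining, nonparametric
bootstrap, majority-rule consensus sequences, and bootstrap-supported
subgroup extraction.

The neighbor-joining implementation follows the Saitou-Nei Q-criterion
with ties broken by the smallest index pair; on an additive distance
matrix it recovers the true topology and branch lengths exactly (the test
suite checks this against an exhaustive least-squares topology search).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .core import ParameterError, SaturationError, UndefinedDistanceError

logger = logging.getLogger("ervkit")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_PURINE = {0, 2}  # A, G


class DistanceResult(NamedTuple):
    d: float
    p_transitions: float
    p_transversions: float
    sites_compared: int


def _encode_rows(rows: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer(("".join(rows)).encode(), dtype=np.uint8)
    return _CODE[arr].reshape(len(rows), -1)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    diff = valid & (a != b)
    ts = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
                 | ((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
    return n, int(ts.sum()), int((diff & ~ts).sum())


def k2p_from_pq(P: float, Q: float) -> float:
    """Kimura 2-parameter distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined for P={P}, Q={Q} (saturated distance)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_distance(
    row_i: str, row_j: str, model: str = "p", pairwise_deletion: bool = True
) -> DistanceResult:
    """Evolutionary distance between two equal-length gapped rows.

    Sites with a gap or N in either row are excluded (pairwise deletion).
    ``model`` is ``"p"`` (proportion of differing sites) or ``"k2p"``.
    """
    if len(row_i) != len(row_j):
        raise ParameterError("rows must have equal length")
    if not pairwise_deletion:
        raise ParameterError(
            "only pairwise deletion is supported at the pair level; "
            "use distance_matrix(deletion='complete') for complete deletion"
        )
    a, b = _encode_rows([row_i, row_j])
    n, ts, tv = _pair_counts(a, b)
    if n == 0:
        raise UndefinedDistanceError("zero comparable sites")
    P, Q = ts / n, tv / n
    if model == "p":
        d = P + Q
    elif model == "k2p":
        d = k2p_from_pq(P, Q)
    else:
        raise ParameterError(f"unknown model {model!r}")
    return DistanceResult(d, P, Q, n)


def distance_matrix(
    rows: Sequence[str], model: str = "p", deletion: str = "pairwise"
) -> np.ndarray:
    """Symmetric distance matrix over aligned rows."""
    enc = _encode_rows(rows)
    if deletion == "complete":
        keep = (enc < 4).all(axis=0)
        enc = enc[:, keep]
    elif deletion != "pairwise":
        raise ParameterError("deletion must be 'pairwise' or 'complete'")
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m, ts, tv = _pair_counts(enc[i], enc[j])
            if m == 0:
                raise UndefinedDistanceError(
                    f"zero comparable sites between rows {i} and {j}"
                )
            P, Q = ts / m, tv / m
            D[i, j] = D[j, i] = (P + Q) if model == "p" else k2p_from_pq(P, Q)
    return D


# -- neighbor joining ---------------------------------------------------------


def _nj_joins(D: np.ndarray):
    """Saitou-Nei agglomeration; ties in Q broken by the smallest index
    pair. Returns (joins, final_ids, final_matrix) where each join is
    (id_a, id_b, len_a, len_b, new_id); leaf ids are 0..n-1."""
    n = D.shape[0]
    ids = list(range(n))
    next_id = n
    M = np.array(D, dtype=float)
    joins = []
    while len(ids) > 3:
        m = len(ids)
        r = M.sum(axis=1)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        i, j = min((min(a, b), max(a, b)) for a, b in cand)
        dij = M[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        joins.append((ids[i], ids[j], li, lj, next_id))
        dnew = (M[i, :] + M[j, :] - dij) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        newM = np.empty((m - 1, m - 1))
        newM[: m - 2, : m - 2] = M[np.ix_(keep, keep)]
        newM[: m - 2, m - 2] = dnew[keep]
        newM[m - 2, : m - 2] = dnew[keep]
        newM[m - 2, m - 2] = 0.0
        M = newM
        ids = [ids[k] for k in keep] + [next_id]
        next_id += 1
    return joins, ids, M


def _validate_matrix(D: np.ndarray) -> None:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ParameterError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ParameterError("need at least 3 taxa")
    if not np.isfinite(D).all():
        raise ParameterError("distance matrix contains non-finite entries")
    if not np.allclose(D, D.T):
        raise ParameterError("distance matrix is not symmetric")


def _clamp(length: float) -> float:
    if length < 0:
        logger.warning("negative NJ branch length %.6g clamped to 0", length)
        return 0.0
    return length


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> Tree:
    """Neighbor-joining tree (unrooted; represented with a basal
    trifurcation). Branch lengths are in substitutions/site; negatives are
    clamped to zero with a log warning."""
    _validate_matrix(D)
    if len(labels) != np.asarray(D).shape[0]:
        raise ParameterError("labels must match matrix dimension")
    joins, final_ids, M = _nj_joins(np.asarray(D, dtype=float))
    nodes: dict[int, Clade] = {
        i: Clade(name=str(lbl)) for i, lbl in enumerate(labels)
    }
    for ida, idb, la, lb, new in joins:
        a, b = nodes.pop(ida), nodes.pop(idb)
        a.branch_length = _clamp(la)
        b.branch_length = _clamp(lb)
        nodes[new] = Clade(clades=[a, b])
    a, b, c = (nodes[i] for i in final_ids)
    d01, d02, d12 = M[0, 1], M[0, 2], M[1, 2]
    a.branch_length = _clamp((d01 + d02 - d12) / 2)
    b.branch_length = _clamp((d01 + d12 - d02) / 2)
    c.branch_length = _clamp((d02 + d12 - d01) / 2)
    root = Clade(clades=[a, b, c])
    return Tree(root=root, rooted=False)


def _bipartitions(joins, n: int) -> dict[int, frozenset[int]]:
    """Tip-index set under each internal node id created by the joins."""
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    for ida, idb, _la, _lb, new in joins:
        sets[new] = sets[ida] | sets[idb]
    return sets


def _tree_bipartitions(D: np.ndarray) -> set[frozenset[int]]:
    joins, _ids, _M = _nj_joins(D)
    n = D.shape[0]
    sets = _bipartitions(joins, n)
    out = set()
    for node_id, tipset in sets.items():
        if node_id >= n and 2 <= len(tipset) <= n - 2:
            out.add(tipset)
    return out


@dataclass
class BootstrapResult:
    tree: Tree
    n_replicates: int
    n_skipped: int
    note: str = ""


def bootstrap(
    rows: Sequence[tuple[str, str]],
    n_reps: int = 1000,
    model: str = "k2p",
    seed: int = 0,
) -> BootstrapResult:
    """NJ tree of an alignment with nonparametric bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal edge of the original tree is the percentage of
    replicate NJ trees containing the same bipartition. Replicates in
    which any pairwise distance is undefined (no comparable sites, or K2P
    saturation) are skipped, counted and logged. Deterministic for a
    fixed seed.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    labels = [r[0] for r in rows]
    seqs = [r[1] for r in rows]
    n = len(seqs)
    enc = _encode_rows(seqs)
    L = enc.shape[1]
    D = distance_matrix(seqs, model=model)
    tree = nj_tree(D, labels)
    if not D.any():
        # identical sequences: no internal structure to support
        logger.warning("bootstrap: all pairwise distances are zero; "
                       "supports are undefined")
        return BootstrapResult(
            tree=tree, n_replicates=0, n_skipped=0,
            note="no-internal-structure",
        )

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    V = np.empty((len(pairs), L), dtype=np.float64)
    TS = np.empty_like(V)
    TV = np.empty_like(V)
    for k, (i, j) in enumerate(pairs):
        a, b = enc[i], enc[j]
        valid = (a < 4) & (b < 4)
        diff = valid & (a != b)
        ts = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
                     | ((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
        V[k] = valid
        TS[k] = ts
        TV[k] = diff & ~ts

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[int], int] = {}
    skipped = 0
    for _ in range(n_reps):
        w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(np.float64)
        v = V @ w
        if (v == 0).any():
            skipped += 1
            continue
        P = (TS @ w) / v
        Q = (TV @ w) / v
        if model == "k2p":
            w1 = 1 - 2 * P - Q
            w2 = 1 - 2 * Q
            if (w1 <= 0).any() or (w2 <= 0).any():
                skipped += 1
                continue
            d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        else:
            d = P + Q
        Drep = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            Drep[i, j] = Drep[j, i] = d[k]
        for bp in _tree_bipartitions(Drep):
            counts[bp] = counts.get(bp, 0) + 1
    used = n_reps - skipped
    if skipped:
        logger.warning("bootstrap: %d/%d replicates skipped (undefined "
                       "distances)", skipped, n_reps)

    # attach supports to the original tree's internal clades
    index = {lbl: i for i, lbl in enumerate(labels)}
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        tipset = frozenset(index[t.name] for t in clade.get_terminals())
        if used > 0:
            mirror = frozenset(range(n)) - tipset
            c = counts.get(tipset, 0) + counts.get(mirror, 0)
            clade.confidence = round(100.0 * c / used)
    return BootstrapResult(tree=tree, n_replicates=used, n_skipped=skipped)


# -- consensus ----------------------------------------------------------------


def majority_consensus(rows: Sequence) -> str:
    """Majority-rule consensus of an alignment.

    Per column, the most frequent base among A/C/G/T wins (ties broken
    alphabetically); columns where the gap character outnumbers every
    base are dropped. N is ignored in the counts.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in rows]
    if len(seqs) < 2:
        raise ParameterError("consensus needs at least 2 rows")
    if len({len(s) for s in seqs}) != 1:
        raise ParameterError("rows must have equal length")
    out = []
    for col in zip(*seqs):
        counts = {b: 0 for b in "ACGT"}
        gaps = 0
        for ch in col:
            if ch in counts:
                counts[ch] += 1
            elif ch == "-":
                gaps += 1
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if gaps > best[1]:
            continue
        if best[1] > 0:
            out.append(best[0])
    return "".join(out)


# -- subgroup extraction ------------------------------------------------------


@dataclass
class SubgroupAssignment:
    labels: dict[str, str] = field(default_factory=dict)  # tip -> label
    clade_support: dict[str, float] = field(default_factory=dict)

    def members(self, label: str) -> list[str]:
        return sorted(
            t for t, l in self.labels.items()
            if l == label or l.startswith(label)
        )


def _patristic(tree: Tree):
    """Tip names and patristic distance matrix of a Bio.Phylo tree."""
    tips = tree.get_terminals()
    names = [t.name for t in tips]
    idx = {name: i for i, name in enumerate(names)}
    unit = all(
        c.branch_length is None for c in tree.find_clades() if c is not tree.root
    )
    depths = tree.depths(unit_branch_lengths=unit)
    n = len(tips)
    lca = np.zeros((n, n))
    for clade in tree.get_nonterminals():
        d = depths[clade]
        ii = [idx[t.name] for t in clade.get_terminals()]
        block = np.ix_(ii, ii)
        lca[block] = np.maximum(lca[block], d)
    tip_depth = np.array([depths[t] for t in tips])
    D = tip_depth[:, None] + tip_depth[None, :] - 2 * lca
    np.fill_diagonal(D, 0.0)
    return names, D


def _side_spreads(tree: Tree):
    """For every internal edge (clade in the rooted representation),
    the standard deviations of tip-to-edge-endpoint distances on the
    clade side and on the complement side.

    A subgroup of loci descending from one ancestral element is
    clock-like: its tips sit at nearly equal distances from the edge
    where it attaches. The heterogeneous remainder of the tree is not.
    """
    unit = all(
        c.branch_length is None for c in tree.find_clades() if c is not tree.root
    )
    depths = tree.depths(unit_branch_lengths=unit)
    parents = {}
    anc: dict = {tree.root: []}
    for clade in tree.find_clades(order="level"):
        for child in clade.clades:
            parents[child] = clade
            anc[child] = anc[clade] + [clade]

    def ancestors_of(clade):
        return anc[clade] + [clade]

    tipsets = {
        c: frozenset(t.name for t in c.get_terminals())
        for c in tree.find_clades()
    }
    tips = tree.get_terminals()
    out = {}
    for clade in tree.get_nonterminals():
        if clade is tree.root:
            continue
        parent = parents[clade]
        side = tipsets[clade]
        inner = [depths[t] - depths[clade] for t in tips if t.name in side]
        outer = []
        panc = ancestors_of(parent)
        for t in tips:
            if t.name in side:
                continue
            lca = next(
                a for a in reversed(panc) if t.name in tipsets[a]
            )
            outer.append(depths[t] + depths[parent] - 2 * depths[lca])
        out[clade] = (
            float(np.std(inner)) if inner else float("inf"),
            float(np.std(outer)) if outer else float("inf"),
        )
    return out


def extract_subgroups(
    tree: Tree,
    support_threshold: float = 70.0,
    min_size: int = 5,
) -> SubgroupAssignment:
    """Call LTR subgroups from a bootstrap-annotated tree.

    Every supported bipartition (internal edge with support >= threshold)
    proposes a subgroup: the tree is unrooted, so the subgroup may be
    either side of the split, and the side whose tips sit at the more
    uniform distance from the edge is chosen (loci descending from one
    ancestral element are clock-like; the remainder of the tree is
    heterogeneous). Proposals of at least ``min_size`` tips are accepted
    greedily, largest first, keeping the accepted family laminar;
    maximal accepted sets become subgroups labelled A, B, ... in
    decreasing size order, and at least two supported sets nested
    directly inside a subgroup become its sub-labels (B1, B2, ...).
    Remaining tips are labelled ``other``.
    """
    names = [t.name for t in tree.get_terminals()]
    n = len(names)
    allset = frozenset(names)
    spreads = _side_spreads(tree)

    proposals: dict[frozenset, float] = {}
    for clade in tree.get_nonterminals():
        if (
            clade is tree.root
            or clade.confidence is None
            or clade.confidence < support_threshold
        ):
            continue
        side = frozenset(t.name for t in clade.get_terminals())
        comp = allset - side
        if not (2 <= len(side) <= n - 2):
            continue
        sd_in, sd_out = spreads[clade]
        chosen = side if sd_in <= sd_out else comp
        # the complement of a trivially small clade is not a subgroup
        # candidate (guards against near-whole-tree proposals seeded by
        # a stray 2-tip clade)
        if chosen is comp and len(side) < min_size:
            continue
        if len(chosen) >= min_size:
            sup = float(clade.confidence)
            proposals[chosen] = max(proposals.get(chosen, 0.0), sup)

    accepted: list[tuple[frozenset, float]] = []
    for s, sup in sorted(proposals.items(), key=lambda x: (-len(x[0]), -x[1])):
        if all(s <= s2 or s2 <= s or not (s & s2) for s2, _ in accepted):
            accepted.append((s, sup))

    # residual rescue: with exactly two subgroups in the tree one deep
    # split separates them, and only its clock-tighter side is proposed
    # above. If the unassigned remainder is itself a side of a supported
    # edge and comparably clock-like, it is a subgroup too.
    union = frozenset().union(*(s for s, _ in accepted)) if accepted else frozenset()
    residual = allset - union
    if accepted and len(residual) >= min_size:
        accepted_sds = []
        for clade in tree.get_nonterminals():
            if clade is tree.root or clade.confidence is None:
                continue
            side = frozenset(t.name for t in clade.get_terminals())
            if side in {s for s, _ in accepted}:
                accepted_sds.append(spreads[clade][0])
            elif (allset - side) in {s for s, _ in accepted}:
                accepted_sds.append(spreads[clade][1])
        for clade in tree.get_nonterminals():
            if (
                clade is tree.root
                or clade.confidence is None
                or clade.confidence < support_threshold
            ):
                continue
            side = frozenset(t.name for t in clade.get_terminals())
            comp = allset - side
            match = side if side == residual else comp if comp == residual else None
            if match is None:
                continue
            sd = spreads[clade][0] if match == side else spreads[clade][1]
            if accepted_sds and sd <= 1.25 * max(accepted_sds):
                accepted.append((match, float(clade.confidence)))
            break

    assignment = SubgroupAssignment()
    for name in names:
        assignment.labels[name] = "other"
    top = [
        (s, sup)
        for s, sup in accepted
        if not any(s < s2 for s2, _ in accepted)
    ]
    top.sort(key=lambda x: (-len(x[0]), sorted(x[0])))
    for rank, (s, sup) in enumerate(top):
        label = chr(ord("A") + rank)
        assignment.clade_support[label] = sup
        for name in s:
            assignment.labels[name] = label
        nested = [
            (s2, sup2)
            for s2, sup2 in accepted
            if s2 < s
            and not any(s2 < s3 < s for s3, _ in accepted)
        ]
        nested.sort(key=lambda x: (-len(x[0]), sorted(x[0])))
        if len(nested) >= 2:
            for si, (s2, sup2) in enumerate(nested, start=1):
                sub_label = f"{label}{si}"
                assignment.clade_support[sub_label] = sup2
                for name in s2:
                    assignment.labels[name] = sub_label
    return assignment
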