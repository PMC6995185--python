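import numpy as np
import pytest
from Bio.Phylo.BaseTree import Clade, Tree

import oracles
from ervkit import phylo, simulate
from ervkit.core import ParameterError, SaturationError, UndefinedDistanceError


class TestDistances:
    def test_identical_and_single_difference(self):
        assert phylo.pairwise_distance("ACGT", "ACGT", "p").d == 0.0
        assert phylo.pairwise_distance("ACGT", "ACGT", "k2p").d == 0.0
        assert phylo.pairwise_distance("ACGT", "ACGA", "p").d == 0.25

    def test_k2p_closed_form(self):
        # 100 sites, 10 transitions, 5 transversions
        d = phylo.k2p_from_pq(0.1, 0.05)
        assert d == pytest.approx(0.170181, abs=1e-6)
        a = "A" * 85 + "A" * 10 + "A" * 5
        b = "A" * 85 + "G" * 10 + "C" * 5
        res = phylo.pairwise_distance(a, b, "k2p")
        assert res.p_transitions == 0.10 and res.p_transversions == 0.05
        assert res.d == pytest.approx(0.170181, abs=1e-6)

    def test_pairwise_deletion_excludes_gap_and_n(self):
        res = phylo.pairwise_distance("AC-GTN", "ACAGTA", "p")
        assert res.sites_compared == 4
        assert res.d == 0.0

    def test_zero_comparable_sites_error(self):
        with pytest.raises(UndefinedDistanceError):
            phylo.pairwise_distance("----", "AAAA", "p")

    def test_saturation_error(self):
        a = "A" * 100
        b = "G" * 60 + "C" * 40
        with pytest.raises(SaturationError):
            phylo.pairwise_distance(a, b, "k2p")

    def test_k2p_at_least_p_distance(self):
        """Jensen-type inequality: the K2P correction can only expand an
        observed p-distance (equality iff d = 0)."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            anc = simulate.random_dna(400, rng)
            a = simulate.evolve(anc, rng.uniform(1, 25), seed=rng)
            b = simulate.evolve(anc, rng.uniform(1, 25), seed=rng)
            p = phylo.pairwise_distance(a, b, "p").d
            k = phylo.pairwise_distance(a, b, "k2p").d
            assert k >= p
            if p == 0:
                assert k == 0


class TestNeighborJoining:
    def test_three_taxa_three_point_formula(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = phylo.nj_tree(D, ["a", "b", "c"])
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_four_taxon_additive_recovery(self):
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = phylo.nj_tree(D, list("ABCD"))
        bps = oracles.tree_to_bipartitions(tree, list("ABCD"))

        def canon(*names):
            s = frozenset(names)
            comp = frozenset("ABCD") - s
            return s if sorted(s) < sorted(comp) else comp

        assert bps[canon("A", "B")] == pytest.approx(1.0)
        assert bps[canon("A")] == pytest.approx(1.0)
        assert bps[canon("B")] == pytest.approx(2.0)
        assert bps[canon("C")] == pytest.approx(3.0)
        assert bps[canon("D")] == pytest.approx(4.0)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(2)
        D, bps, labels = oracles.random_additive_matrix(6, rng)
        perm = rng.permutation(6)
        Dp = D[np.ix_(perm, perm)]
        lp = [labels[i] for i in perm]
        t1 = phylo.nj_tree(D, labels)
        t2 = phylo.nj_tree(Dp, lp)
        assert oracles.tree_to_bipartitions(t1, labels) == pytest.approx(
            oracles.tree_to_bipartitions(t2, labels)
        )

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_recovery_vs_exhaustive_least_squares(self, n):
        """On additive matrices NJ must match the best tree found by
        exhaustive least-squares topology search, including branch
        lengths."""
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            D, true_bps, labels = oracles.random_additive_matrix(n, rng)
            edges, lengths = oracles.best_ls_tree(D)
            oracle_bps = oracles.edge_bipartitions(edges, lengths, n, labels)
            tree = phylo.nj_tree(D, labels)
            nj_bps = oracles.tree_to_bipartitions(tree, labels)
            assert set(nj_bps) == set(oracle_bps)
            for key in oracle_bps:
                assert nj_bps[key] == pytest.approx(oracle_bps[key], abs=1e-8)
            assert nj_bps == pytest.approx(true_bps, abs=1e-8)

    def test_matches_scikit_bio(self):
        """Independent cross-check against scikit-bio's NJ on a noisy
        (non-additive) matrix: same topology."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        D, _bps, labels = oracles.random_additive_matrix(6, rng)
        noise = rng.uniform(0, 0.05, D.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        Dn = D + noise
        ours = phylo.nj_tree(Dn, labels)
        theirs = skbio_nj(DistanceMatrix(Dn, labels))
        our_splits = {
            s
            for s in oracles.tree_to_bipartitions(ours, labels)
            if 2 <= len(s) <= len(labels) - 2
        }
        their_splits = set()
        allset = frozenset(labels)
        for node in theirs.non_tips(include_self=False):
            names = frozenset(t.name for t in node.tips())
            comp = allset - names
            if 2 <= len(names) <= len(labels) - 2:
                their_splits.add(
                    names if sorted(names) < sorted(comp) else comp
                )
        assert our_splits == their_splits

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ParameterError):
            phylo.nj_tree(np.zeros((2, 2)), ["a", "b"])
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], float)
        with pytest.raises(ParameterError):
            phylo.nj_tree(bad, list("abc"))
        nan = np.full((3, 3), np.nan)
        with pytest.raises(ParameterError):
            phylo.nj_tree(nan, list("abc"))


class TestBootstrap:
    def test_identical_sequences_report_no_structure(self):
        rows = [(f"t{i}", "ACGTACGTAC") for i in range(5)]
        res = phylo.bootstrap(rows, n_reps=10, model="p", seed=0)
        assert res.note == "no-internal-structure"
        assert all(
            c.confidence is None for c in res.tree.get_nonterminals()
        )

    def test_determinism(self, sim_result):
        rows, _ = simulate.true_ltr_alignment(sim_result)
        rows = rows[:12]
        r1 = phylo.bootstrap(rows, n_reps=50, model="k2p", seed=4)
        r2 = phylo.bootstrap(rows, n_reps=50, model="k2p", seed=4)
        c1 = [c.confidence for c in r1.tree.get_nonterminals()]
        c2 = [c.confidence for c in r2.tree.get_nonterminals()]
        assert c1 == c2

    def test_two_separated_blocks_get_high_support(self):
        """Two 5-taxon families simulated from two diverged templates
        must be split with bootstrap support >= 95."""
        rng = np.random.default_rng(6)
        anc = simulate.random_dna(800, rng)
        tmpl_a = simulate.evolve(anc, 30, cpg_multiplier=1.0, seed=rng)
        tmpl_b = simulate.evolve(anc, 30, cpg_multiplier=1.0, seed=rng)
        rows = []
        for i in range(5):
            rows.append((f"a{i}", simulate.evolve(tmpl_a, 5, seed=rng)))
        for i in range(5):
            rows.append((f"b{i}", simulate.evolve(tmpl_b, 5, seed=rng)))
        res = phylo.bootstrap(rows, n_reps=200, model="k2p", seed=1)
        a_set = frozenset(f"a{i}" for i in range(5))
        support = None
        allset = frozenset(r[0] for r in rows)
        for clade in res.tree.get_nonterminals():
            names = frozenset(t.name for t in clade.get_terminals())
            if names in (a_set, allset - a_set):
                support = clade.confidence
        assert support is not None and support >= 95


class TestConsensus:
    def test_majority_and_tie_break(self):
        assert phylo.majority_consensus(["AC", "AC", "AT"]) == "AC"
        # T vs G tie at column 1: alphabetical wins (G)
        assert phylo.majority_consensus(["AG", "AT", "CG", "CT"]) == "AG"

    def test_gap_plurality_column_dropped(self):
        assert phylo.majority_consensus(["A-", "A-", "AC"]) == "A"

    def test_idempotence(self):
        rows = ["ACGTAC", "ACGTAT", "ACCTAC"]
        c = phylo.majority_consensus(rows)
        assert phylo.majority_consensus([c, c]) == c

    def test_recovers_ancestor_from_evolved_copies(self):
        rng = np.random.default_rng(8)
        anc = simulate.random_dna(2000, rng)
        rows = [simulate.evolve(anc, 10, seed=rng) for _ in range(30)]
        cons = phylo.majority_consensus(rows)
        ident = sum(a == b for a, b in zip(cons, anc)) / len(anc)
        assert ident >= 0.99


def _clade(name=None, bl=1.0, confidence=None, children=()):
    c = Clade(name=name, branch_length=bl, clades=list(children))
    c.confidence = confidence
    return c


def _tips(prefix, n, bl=0.1):
    return [_clade(f"{prefix}{i}", bl) for i in range(n)]


class TestSubgroupExtraction:
    def test_single_supported_clade_becomes_A(self):
        grp = _clade(bl=2.0, confidence=95, children=_tips("g", 6))
        others = _tips("o", 4, bl=3.0)
        tree = Tree(root=Clade(clades=[grp] + others), rooted=False)
        assign = phylo.extract_subgroups(tree, 70, min_size=5)
        assert assign.clade_support == {"A": 95.0}
        assert all(assign.labels[f"g{i}"] == "A" for i in range(6))
        assert all(assign.labels[f"o{i}"] == "other" for i in range(4))

    def test_low_support_clade_ignored(self):
        grp = _clade(bl=2.0, confidence=50, children=_tips("g", 6))
        others = _tips("o", 4, bl=3.0)
        tree = Tree(root=Clade(clades=[grp] + others), rooted=False)
        assign = phylo.extract_subgroups(tree, 70, min_size=5)
        assert assign.clade_support == {}
        assert set(assign.labels.values()) == {"other"}

    def test_nested_supported_clades_become_sublabels(self):
        """A 90%-supported subgroup holding nested 99%- and 68%-supported
        clusters yields B1/B2-style sub-labels at threshold 65."""
        b1 = _clade(bl=1.0, confidence=99, children=_tips("x", 6))
        b2 = _clade(bl=1.0, confidence=68, children=_tips("y", 5))
        b = _clade(bl=3.0, confidence=90, children=[b1, b2])
        a = _clade(bl=3.0, confidence=99, children=_tips("a", 7))
        others = _tips("o", 8, bl=6.0)
        tree = Tree(root=Clade(clades=[a, b] + others), rooted=False)
        assign = phylo.extract_subgroups(tree, 65, min_size=5)
        # larger subgroup (11 tips) is labelled A, the 7-tip one B
        assert assign.labels["x0"] == "A1"
        assert assign.labels["y0"] == "A2"
        assert assign.labels["a0"] == "B"
        assert assign.labels["o0"] == "other"
        assert assign.clade_support["A1"] == 99.0
        assert assign.clade_support["A2"] == 68.0

    def test_ltr_pairs_group_close_in_tree(self, sim_result):
        """The 5' and 3' LTRs of one provirus descend from a single
        integration event, so in the NJ tree of all LTRs each pair should
        sit much closer to each other than to typical other tips."""
        rows, _ = simulate.true_ltr_alignment(sim_result)
        D = phylo.distance_matrix([r[1] for r in rows], model="k2p")
        tree = phylo.nj_tree(D, [r[0] for r in rows])
        names, P = phylo._patristic(tree)
        idx = {n: i for i, n in enumerate(names)}
        loci = sorted({r[0].rsplit("_", 1)[0] for r in rows})
        close = 0
        for locus in loci:
            i, j = idx[f"{locus}_5ltr"], idx[f"{locus}_3ltr"]
            others = np.delete(P[i], [i, j])
            if P[i, j] < np.median(others):
                close += 1
        # a clear majority of pairs, not all: the oldest insertions have
        # LTR pairs as diverged as typical cross-locus comparisons
        assert close / len(loci) >= 0.6
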