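"""Dice matrices checked against naive accumulation; neighbor joining
checked for exact recovery of additive matrices (NJ is consistent) and
against an independent implementation on random inputs."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virocurate import (cluster_groups, dice_matrix, filter_hits, nj_tree,
                        summed_scores)
from virocurate.synthetic import BLAST_COLUMNS


def _hits(rows):
    full = [(q, s, ident, ln, 0, 0, 1, ln, 1, ln, ev, bs)
            for q, s, ident, ln, ev, bs in rows]
    return pd.DataFrame(full, columns=BLAST_COLUMNS)


class TestFilter:
    @pytest.mark.parametrize("ident,ln,ev,kept", [
        (30.0, 100, 1e-5, False),   # identity exactly 30: strict >
        (30.1, 100, 1e-5, True),
        (50.0, 30, 1e-5, True),     # length 30 retained
        (50.0, 29, 1e-5, False),
        (50.0, 100, 0.01, False),   # E exactly 0.01: strict <
        (50.0, 100, 0.009, True),
    ])
    def test_thresholds(self, ident, ln, ev, kept):
        out = filter_hits(_hits([("a", "b", ident, ln, ev, 50.0)]))
        assert (len(out) == 1) == kept

    def test_empty_in_empty_out(self):
        assert len(filter_hits(_hits([]))) == 0


class TestSummedScores:
    def test_both_directions_sum_into_one_pair(self):
        hits = _hits([("a", "b", 50, 100, 1e-5, 50.0),
                      ("b", "a", 50, 100, 1e-5, 30.0),
                      ("a", "a", 100, 500, 0.0, 100.0),
                      ("b", "b", 100, 500, 0.0, 300.0)])
        S = summed_scores(hits, ["a", "b"])
        assert S.loc["a", "b"] == 80 and S.loc["b", "a"] == 80
        assert S.loc["a", "a"] == 100 and S.loc["b", "b"] == 300

    def test_no_hits_means_zero_score(self):
        S = summed_scores(_hits([("a", "a", 100, 500, 0.0, 10.0)]),
                          ["a", "b"])
        assert S.loc["a", "b"] == 0

    def test_matches_naive_double_loop(self, rng):
        genomes = [f"g{i}" for i in range(6)]
        rows = []
        for _ in range(200):
            q, s = rng.choice(genomes, 2)
            rows.append((q, s, 50, 100, 1e-5, float(rng.uniform(20, 200))))
        rows += [(g, g, 100, 500, 0.0, 100.0) for g in genomes]
        hits = _hits(rows)
        S = summed_scores(hits, genomes)
        naive = np.zeros((6, 6))
        for r in hits.itertuples(index=False):
            i, j = genomes.index(r.qseqid), genomes.index(r.sseqid)
            if i == j:
                naive[i, i] += r.bitscore
            else:
                naive[i, j] += r.bitscore
                naive[j, i] += r.bitscore
        assert np.allclose(S.values, naive)


class TestDice:
    def _S(self, saa, sbb, sab):
        return pd.DataFrame([[saa, sab], [sab, sbb]], index=["a", "b"],
                            columns=["a", "b"], dtype=float)

    def test_direct_formula(self):
        dm = dice_matrix(self._S(100, 300, 50))
        assert dm.D.loc["a", "b"] == pytest.approx(0.25)
        assert dm.dissim.loc["a", "b"] == pytest.approx(0.75)

    def test_identical_genomes_have_dice_one(self):
        dm = dice_matrix(self._S(100, 100, 100))
        assert dm.D.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_self_score_flagged_and_zeroed(self):
        with pytest.warns(UserWarning, match="zero self-score"):
            dm = dice_matrix(self._S(0, 300, 10))
        assert dm.flagged == ["a"] and dm.D.loc["a", "b"] == 0.0

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dice_bounded_when_cross_below_self(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        self_scores = rng.uniform(10, 1000, n)
        S = np.zeros((n, n))
        np.fill_diagonal(S, self_scores)
        for i in range(n):
            for j in range(i + 1, n):
                S[i, j] = S[j, i] = rng.uniform(
                    0, min(self_scores[i], self_scores[j]))
        ids = [f"g{i}" for i in range(n)]
        dm = dice_matrix(pd.DataFrame(S, index=ids, columns=ids))
        assert ((dm.D.values >= 0) & (dm.D.values <= 1)).all()
        assert np.allclose(dm.D.values, dm.D.values.T)
        assert np.allclose(np.diag(dm.dissim.values), 0)


def _tree_distance_matrix(newick_like: dict, ids):
    """Path-length matrix from an explicit edge-length description."""
    import networkx as nx
    g = nx.Graph()
    for (u, v), w in newick_like.items():
        g.add_edge(u, v, weight=w)
    n = len(ids)
    D = np.zeros((n, n))
    for i, a in enumerate(ids):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(ids):
            D[i, j] = lengths[b]
    return pd.DataFrame(D, index=ids, columns=ids)


def _tip_distances_from_newick(newick: str, ids):
    import skbio
    tree = skbio.TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids),
                        columns=list(dm.ids)).loc[ids, ids]


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree_exactly(self):
        # oracle: path lengths on a hand-built tree; NJ must return them
        edges = {("A", "u"): 1, ("B", "u"): 2, ("u", "v"): 3,
                 ("C", "v"): 4, ("D", "v"): 5}
        ids = list("ABCD")
        D = _tree_distance_matrix(edges, ids)
        tree = nj_tree(D)
        got = _tip_distances_from_newick(tree.newick, ids)
        assert np.allclose(got.values, D.values)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_recovers_random_additive_matrices(self, n_taxa, rng):
        # random binary tree with positive branch lengths is additive;
        # NJ is consistent, so tip distances must be recovered exactly
        import networkx as nx
        ids = [f"t{i}" for i in range(n_taxa)]
        nodes = list(ids)
        edges = {}
        k = 0
        while len(nodes) > 1:
            a, b = rng.choice(len(nodes), 2, replace=False)
            a, b = sorted((a, b), reverse=True)
            u, v = nodes.pop(a), nodes.pop(b)
            new = f"i{k}"
            k += 1
            edges[(u, new)] = float(rng.uniform(0.5, 3.0))
            edges[(v, new)] = float(rng.uniform(0.5, 3.0))
            nodes.append(new)
        D = _tree_distance_matrix(edges, ids)
        tree = nj_tree(D)
        got = _tip_distances_from_newick(tree.newick, ids)
        assert np.allclose(got.values, D.values, atol=1e-8)
        del nx

    def test_three_taxa_closed_form(self):
        D = pd.DataFrame([[0, 3, 5], [3, 0, 6], [5, 6, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        tree = nj_tree(D)
        # three-point equations: la=(dab+dac-dbc)/2=1, lb=2, lc=4
        assert tree.newick == "(a:1,b:2,c:4);"

    def test_taxon_order_permutation_gives_isomorphic_tree(self, rng):
        import skbio
        ids = [f"t{i}" for i in range(6)]
        M = rng.uniform(0.1, 1.0, (6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        D = pd.DataFrame(M, index=ids, columns=ids)
        t1 = skbio.TreeNode.read(io.StringIO(nj_tree(D).newick))
        perm = list(rng.permutation(ids))
        t2 = skbio.TreeNode.read(io.StringIO(
            nj_tree(D.loc[perm, perm]).newick))
        assert t1.compare_rfd(t2) == 0

    def test_matches_skbio_topology_on_random_matrices(self, rng):
        import skbio
        from skbio import DistanceMatrix
        for _ in range(5):
            n = int(rng.integers(4, 9))
            ids = [f"t{i}" for i in range(n)]
            M = rng.uniform(0.1, 1.0, (n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            D = pd.DataFrame(M, index=ids, columns=ids)
            ours = skbio.TreeNode.read(io.StringIO(nj_tree(D).newick))
            ref = skbio.tree.nj(DistanceMatrix(M, ids))
            assert ours.compare_rfd(ref) == 0

    def test_fewer_than_three_taxa_warns(self):
        D = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.warns(UserWarning, match="trivial"):
            tree = nj_tree(D)
        assert tree.newick == "(a:0.2,b:0.2);"


class TestClusterGroups:
    def _D(self, ids, pairs):
        D = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for a, b, v in pairs:
            D.loc[a, b] = D.loc[b, a] = v
        return D

    def test_chain_is_one_group_at_zero_threshold(self):
        D = self._D(list("abc"), [("a", "b", 0.3), ("b", "c", 0.2)])
        groups, singles = cluster_groups(D, threshold=1e-9)
        assert groups == [["a", "b", "c"]] and singles == []

    def test_threshold_above_max_yields_all_singletons(self):
        D = self._D(list("abc"), [("a", "b", 0.3), ("b", "c", 0.2)])
        groups, singles = cluster_groups(D, threshold=0.5)
        assert groups == [] and singles == ["a", "b", "c"]

    def test_matches_brute_force_components(self, rng):
        # oracle: exhaustive DFS over the thresholded similarity graph
        for _ in range(20):
            n = int(rng.integers(3, 10))
            ids = [f"g{i}" for i in range(n)]
            M = rng.uniform(0, 0.2, (n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            D = pd.DataFrame(M, index=ids, columns=ids)
            thr = 0.1
            groups, singles = cluster_groups(D, threshold=thr)
            # DFS
            adj = {i: [j for j in range(n)
                       if j != i and M[i, j] >= thr] for i in range(n)}
            seen, comps = set(), []
            for i in range(n):
                if i in seen:
                    continue
                stack, comp = [i], []
                while stack:
                    x = stack.pop()
                    if x in seen:
                        continue
                    seen.add(x)
                    comp.append(ids[x])
                    stack.extend(adj[x])
                comps.append(sorted(comp))
            expect_groups = sorted([c for c in comps if len(c) > 1])
            expect_singles = sorted(c[0] for c in comps if len(c) == 1)
            assert groups == expect_groups and singles == expect_singles

    def test_planted_near_identical_pair_is_isolated(self):
        # pipeline property: a duplicated genome pair has D ~ 1 while
        # unrelated genomes share nothing
        ids = ["dup1", "dup2", "x", "y"]
        rows = [(g, g, 100, 500, 0.0, 1000.0) for g in ids]
        rows += [("dup1", "dup2", 99, 500, 0.0, 990.0)]
        hits = _hits(rows)
        dm = dice_matrix(summed_scores(filter_hits(hits), ids))
        assert dm.D.loc["dup1", "dup2"] > 0.9
        assert dm.D.loc["dup1", "x"] == 0
        groups, singles = cluster_groups(dm.D, threshold=0.05)
        assert groups == [["dup1", "dup2"]] and singles == ["x", "y"]
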