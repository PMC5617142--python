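"""Rank transform, Euclidean distances, deterministic agglomeration,
tree cutting, Newick export, and two-way ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from cecscreen.cluster import (
    agglomerate,
    cut_clusters,
    export_newick,
    leaf_order,
    pairwise_euclidean,
    rank_transform,
    two_way_order,
)
from cecscreen.model import SiteMaxMatrix
from helpers_oracle import naive_agglomerate, random_distance_frame


def smax_from(values, sites=None, chems=None):
    arr = np.asarray(values, dtype=float)
    sites = sites or [f"S{i+1}" for i in range(arr.shape[0])]
    chems = chems or [f"C{j+1}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=pd.Index(sites, name="site_id"),
                      columns=pd.Index(chems, name="chemical_id"))
    return SiteMaxMatrix(df, "water")


class TestRankTransform:
    def test_average_ranks_for_ties(self):
        smax = smax_from([[1.0], [2.0], [2.0], [3.0]])
        ranks = rank_transform(smax)["C1"].tolist()
        assert ranks == [1.0, 2.5, 2.5, 4.0]

    def test_zeros_share_lowest_average_rank(self):
        smax = smax_from([[0.0], [0.0], [5.0]])
        ranks = rank_transform(smax)["C1"].tolist()
        assert ranks == [1.5, 1.5, 3.0]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0.1, 10, size=(6, 4))
        base = rank_transform(smax_from(values))
        warped = rank_transform(smax_from(np.exp(2 * np.log(values) + 1)))
        pd.testing.assert_frame_equal(base, warped)

    def test_matches_sort_and_assign_oracle(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 1, size=(8, 3))
        ranks = rank_transform(smax_from(values))
        for j, col in enumerate(ranks.columns):
            order = np.argsort(np.argsort(values[:, j])) + 1.0
            np.testing.assert_allclose(ranks[col].to_numpy(), order)


class TestPairwiseEuclidean:
    def test_identical_rows_have_zero_distance(self):
        ranks = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["S1", "S2"],
                             columns=["C1", "C2"])
        dist = pairwise_euclidean(ranks, "sites")
        assert dist.loc["S1", "S2"] == 0.0

    def test_three_four_five_triangle(self):
        ranks = pd.DataFrame([[1.0, 1.0], [4.0, 5.0]], index=["S1", "S2"],
                             columns=["C1", "C2"])
        assert pairwise_euclidean(ranks, "sites").loc["S1", "S2"] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        ranks = pd.DataFrame(
            rng.uniform(0, 5, size=(5, 4)),
            index=[f"S{i}" for i in range(5)],
            columns=[f"C{j}" for j in range(4)],
        )
        dist = pairwise_euclidean(ranks, "chemicals")
        for a in ranks.columns:
            for b in ranks.columns:
                expected = np.sqrt(((ranks[a] - ranks[b]) ** 2).sum())
                assert dist.loc[a, b] == pytest.approx(expected)


class TestAgglomerate:
    def test_two_leaves_merge_at_their_distance(self):
        dist = pd.DataFrame([[0.0, 2.5], [2.5, 0.0]], index=list("AB"),
                            columns=list("AB"))
        tree = agglomerate(dist)
        assert tree.merges.shape == (1, 4)
        assert tree.heights[0] == 2.5

    def test_collinear_points_merge_closest_pair_first(self):
        pts = np.array([0.0, 1.0, 10.0])
        D = np.abs(pts[:, None] - pts[None])
        dist = pd.DataFrame(D, index=list("ABC"), columns=list("ABC"))
        tree = agglomerate(dist)
        assert tree.merges[0, 2] == 1.0
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 1}

    @pytest.mark.parametrize("method", ["complete", "average", "single"])
    def test_equals_naive_rescan_oracle_on_random_instances(self, method):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            dist = random_distance_frame(rng, n)
            mine = agglomerate(dist, method).merges
            oracle = naive_agglomerate(dist, method)
            np.testing.assert_allclose(mine, oracle)

    def test_heights_match_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(12)
        dist = random_distance_frame(rng, 15, dim=5)
        for method in ("complete", "average", "single"):
            mine = agglomerate(dist, method)
            sp = scipy_linkage(
                squareform(dist.to_numpy(), checks=False), method=method
            )
            np.testing.assert_allclose(
                np.sort(mine.heights), np.sort(sp[:, 2]), rtol=1e-10
            )

    def test_complete_linkage_heights_nondecreasing(self):
        rng = np.random.default_rng(13)
        dist = random_distance_frame(rng, 12)
        tree = agglomerate(dist, "complete")
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_deterministic_under_tied_distances(self):
        # four equidistant leaves: every pair ties at every step, so the
        # lexicographic rule chains from the smallest labels: (A,B) first,
        # then {A,B}+C (leaf-tuple ("A","B") sorts before ("C",)), then +D
        D = np.ones((4, 4)) - np.eye(4)
        dist = pd.DataFrame(D, index=list("ABCD"), columns=list("ABCD"))
        tree = agglomerate(dist)
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == {0, 1}
        assert {int(tree.merges[1, 0]), int(tree.merges[1, 1])} == {2, 4}
        oracle = naive_agglomerate(dist, "complete")
        np.testing.assert_allclose(tree.merges, oracle)

    def test_single_leaf_rejected(self):
        dist = pd.DataFrame([[0.0]], index=["A"], columns=["A"])
        with pytest.raises(ValueError):
            agglomerate(dist)


class TestCutAndNewick:
    def test_cut_at_n_gives_singletons(self):
        rng = np.random.default_rng(14)
        dist = random_distance_frame(rng, 6)
        tree = agglomerate(dist)
        labels = cut_clusters(tree, 6)
        assert sorted(labels.values()) == list(range(6))

    def test_cut_at_one_gives_single_cluster(self):
        rng = np.random.default_rng(15)
        tree = agglomerate(random_distance_frame(rng, 5))
        assert set(cut_clusters(tree, 1).values()) == {0}

    def test_cut_matches_union_find_over_truncated_merges(self):
        rng = np.random.default_rng(16)
        dist = random_distance_frame(rng, 8)
        tree = agglomerate(dist)
        for k in range(1, 9):
            labels = cut_clusters(tree, k)
            assert len(set(labels.values())) == k
            # union-find oracle over the first n-k merges
            parent = {lbl: lbl for lbl in tree.leaf_labels}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            members = {i: [lbl] for i, lbl in enumerate(tree.leaf_labels)}
            for i in range(8 - k):
                a, b = int(tree.merges[i, 0]), int(tree.merges[i, 1])
                members[8 + i] = members.pop(a) + members.pop(b)
            for group in members.values():
                assert len({labels[x] for x in group}) == 1

    def test_two_leaf_newick_shape(self):
        dist = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=list("AB"),
                            columns=list("AB"))
        text = export_newick(agglomerate(dist))
        assert text == "(A:3,B:3);"

    def test_newick_parses_with_standard_reader(self, tmp_path):
        Phylo = pytest.importorskip("Bio.Phylo")
        rng = np.random.default_rng(17)
        tree = agglomerate(random_distance_frame(rng, 7))
        path = tmp_path / "tree.nwk"
        export_newick(tree, path)
        parsed = Phylo.read(str(path), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(
            tree.leaf_labels
        )

    def test_bad_k_rejected(self):
        rng = np.random.default_rng(18)
        tree = agglomerate(random_distance_frame(rng, 4))
        for k in (0, 5):
            with pytest.raises(ValueError):
                cut_clusters(tree, k)


class TestTwoWayOrder:
    def test_orders_are_permutations(self):
        rng = np.random.default_rng(19)
        smax = smax_from(rng.uniform(0, 10, size=(7, 5)))
        order = two_way_order(smax)
        assert sorted(order.site_order) == sorted(smax.sites)
        assert sorted(order.chemical_order) == sorted(smax.chemicals)

    def test_planted_two_block_matrix_separates_blocks(self):
        rng = np.random.default_rng(20)
        # block structure: first 5 sites high on first 3 chemicals,
        # last 5 sites high on the other 3
        values = rng.uniform(0, 0.1, size=(10, 6))
        values[:5, :3] += 10.0
        values[5:, 3:] += 10.0
        order = two_way_order(smax_from(values))
        site_labels = cut_clusters(order.site_dendrogram, 2)
        first = {f"S{i+1}" for i in range(5)}
        groups = {frozenset(s for s, g in site_labels.items() if g == i)
                  for i in (0, 1)}
        assert frozenset(first) in groups
        chem_labels = cut_clusters(order.chemical_dendrogram, 2)
        assert frozenset({"C1", "C2", "C3"}) in {
            frozenset(c for c, g in chem_labels.items() if g == i) for i in (0, 1)
        }

    def test_leaf_order_traverses_tighter_subcluster_first(self):
        # (A,B) merge at height 1; C joins the root at height 10.  The
        # singleton C has height 0, so it is the tighter child of the root
        # and is emitted before the {A,B} subtree.
        pts = np.array([0.0, 1.0, 10.0])
        D = np.abs(pts[:, None] - pts[None])
        tree = agglomerate(
            pd.DataFrame(D, index=list("ABC"), columns=list("ABC"))
        )
        assert leaf_order(tree) == ["C", "A", "B"]
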