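import io
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from kfvmotif import (
    DistanceMatrix,
    ch_log,
    ch_log_profile,
    cut_tree,
    optimal_clusters,
    to_newick,
    transform_distance,
    transform_matrix,
    upgma,
    within_between_scatter,
)

from oracles import cophenetic, scatter_sums


def dmat(ids, values, metric="cos", k=4):
    return DistanceMatrix(ids=list(ids), values=np.asarray(values, dtype=float),
                          metric=metric, k=k)


@pytest.fixture
def three_leaf():
    # classic hand example: A,B close, C far from both
    return dmat("ABC", [[0, 2, 8], [2, 0, 8], [8, 8, 0]])


@pytest.fixture
def planted_two_groups():
    # two tight groups of 4 at distance 0.5 inside, 5.0 across
    n = 8
    values = np.full((n, n), 5.0)
    for i in range(n):
        for j in range(n):
            if i // 4 == j // 4:
                values[i, j] = 0.5
    np.fill_diagonal(values, 0.0)
    return dmat([f"m{i}" for i in range(n)], values)


class TestTransform:
    def test_fixed_point_at_zero(self):
        assert transform_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert transform_distance(0.1, alpha=10) == pytest.approx(
            1 - math.exp(-1), abs=1e-12
        )

    def test_strictly_increasing_and_bounded(self, rng):
        # domain kept below the double-precision saturation of 1 - e^(-10d)
        d = np.unique(rng.random(100))
        t = transform_distance(d)
        assert np.all(np.diff(t) > 0)
        assert np.all((t >= 0) & (t < 1))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            transform_distance(-0.1)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            transform_distance(0.5, alpha=0)

    def test_matrix_transform_keeps_zero_diagonal(self, three_leaf):
        out = transform_matrix(three_leaf, alpha=10)
        np.testing.assert_array_equal(np.diag(out.values), 0.0)
        assert out.values[0, 1] == pytest.approx(1 - math.exp(-20))


class TestUPGMA:
    def test_three_leaf_hand_example(self, three_leaf):
        tree = upgma(three_leaf)
        assert tree.merges == [("A", "B", 1.0), ("A", "C", 4.0)]
        assert to_newick(tree) == "((A:1,B:1):3,C:4);"

    def test_two_leaves(self):
        tree = upgma(dmat("AB", [[0, 1], [1, 0]]))
        assert to_newick(tree) == "(A:0.5,B:0.5);"

    def test_all_zero_matrix_has_zero_heights(self):
        tree = upgma(dmat("ABC", np.zeros((3, 3))))
        assert all(h == 0.0 for _, _, h in tree.merges)

    def test_single_motif_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            upgma(dmat("A", [[0.0]]))

    def test_heights_are_monotone(self, rng):
        for _ in range(5):
            n = 10
            sq = squareform(rng.random(n * (n - 1) // 2))
            tree = upgma(dmat([f"x{i:02d}" for i in range(n)], sq))
            heights = [h for _, _, h in tree.merges]
            assert heights == sorted(heights)

    def test_cophenetic_matches_scipy_average_linkage(self, rng):
        for _ in range(5):
            n = 9
            cond = rng.random(n * (n - 1) // 2) + 0.01
            ids = [f"x{i:02d}" for i in range(n)]
            tree = upgma(dmat(ids, squareform(cond)))
            ours = cophenetic(ids, tree.merges)
            from scipy.cluster.hierarchy import cophenet

            ref = squareform(cophenet(linkage(cond, method="average")))
            for a in range(n):
                for b in range(a + 1, n):
                    assert ours[(ids[a], ids[b])] == pytest.approx(
                        ref[a, b], rel=1e-9
                    )

    def test_deterministic_tie_break(self):
        # every pair at distance 1: merges proceed in lexicographic order
        values = np.ones((4, 4)) - np.eye(4)
        tree = upgma(dmat("DCBA"[::-1], values))
        assert [m[:2] for m in tree.merges] == [("A", "B"), ("A", "C"), ("A", "D")]

    def test_transform_flag_scales_heights(self, three_leaf):
        raw = upgma(three_leaf)
        transformed = upgma(three_leaf, transform=True, alpha=10)
        assert transformed.transformed and transformed.alpha == 10
        assert transformed.merges[0][2] == pytest.approx(
            transform_distance(2.0, 10) / 2
        )
        assert raw.merges[0][2] == 1.0


class TestNewick:
    def test_roundtrip_heights(self, rng):
        n = 7
        ids = [f"x{i:02d}" for i in range(n)]
        tree = upgma(dmat(ids, squareform(rng.random(n * (n - 1) // 2))))
        parsed = TreeNode.read(io.StringIO(to_newick(tree)))
        assert sorted(t.name for t in parsed.tips()) == ids
        # root-to-tip depth equals the root height for every tip (ultrametric)
        root_height = tree.merges[-1][2]
        for tip in parsed.tips():
            assert parsed.distance(tip) == pytest.approx(root_height, rel=1e-6)

    def test_cophenetic_preserved_through_newick(self, three_leaf):
        tree = upgma(three_leaf)
        parsed = TreeNode.read(io.StringIO(to_newick(tree)))
        a, b, c = (parsed.find(x) for x in "ABC")
        assert a.distance(b) == pytest.approx(2.0)
        assert a.distance(c) == pytest.approx(8.0)


class TestCutTree:
    def test_hand_example_cuts(self, three_leaf):
        tree = upgma(three_leaf)
        assert cut_tree(tree, 2) == {"A": 0, "B": 0, "C": 1}
        assert cut_tree(tree, 3) == {"A": 0, "B": 1, "C": 2}
        assert cut_tree(tree, 1) == {"A": 0, "B": 0, "C": 0}

    def test_cluster_count_and_contiguity(self, planted_two_groups):
        tree = upgma(planted_two_groups)
        for c in range(1, 9):
            assignment = cut_tree(tree, c)
            indices = set(assignment.values())
            assert indices == set(range(c))

    def test_out_of_range_rejected(self, three_leaf):
        tree = upgma(three_leaf)
        with pytest.raises(ValueError, match="outside"):
            cut_tree(tree, 4)


class TestChLog:
    def test_scatter_matches_double_loop_oracle(self, rng):
        n = 10
        ids = [f"x{i}" for i in range(n)]
        dm = dmat(ids, squareform(rng.random(n * (n - 1) // 2)))
        for _ in range(5):
            assignment = {i: int(c) for i, c in zip(ids, rng.integers(0, 3, n))}
            if len(set(assignment.values())) < 2:
                continue
            w, b = within_between_scatter(dm, assignment)
            w_ref, b_ref = scatter_sums(dm.values, ids, assignment)
            assert w == pytest.approx(w_ref, rel=1e-12)
            assert b == pytest.approx(b_ref, rel=1e-12)

    def test_planted_split_beats_all_other_cuts(self, planted_two_groups):
        tree = upgma(planted_two_groups)
        profile = dict(ch_log_profile(planted_two_groups, tree))
        assert max(profile, key=profile.get) == 2

    def test_planted_split_beats_shuffled_split_at_same_c(self, planted_two_groups):
        ids = planted_two_groups.ids
        planted = {i: 0 if idx < 4 else 1 for idx, i in enumerate(ids)}
        shuffled = {i: idx % 2 for idx, i in enumerate(ids)}
        assert ch_log(planted_two_groups, planted) > ch_log(
            planted_two_groups, shuffled
        )

    def test_degenerate_within_scatter_warns(self, planted_two_groups):
        values = planted_two_groups.values.copy()
        values[values == 0.5] = 0.0
        dm = dmat(planted_two_groups.ids, values)
        planted = {i: 0 if idx < 4 else 1 for idx, i in enumerate(dm.ids)}
        with pytest.warns(UserWarning, match="within-cluster"):
            assert ch_log(dm, planted) == math.inf

    def test_cluster_count_bounds(self, planted_two_groups):
        all_one = {i: 0 for i in planted_two_groups.ids}
        with pytest.raises(ValueError, match="outside"):
            ch_log(planted_two_groups, all_one)


class TestOptimalClusters:
    def test_recovers_planted_group_count(self, planted_two_groups):
        tree = upgma(planted_two_groups)
        best = optimal_clusters(planted_two_groups, tree)
        assert best.c == 2
        groups = {frozenset(i for i, c in best.assignment.items() if c == g)
                  for g in (0, 1)}
        assert groups == {
            frozenset(f"m{i}" for i in range(4)),
            frozenset(f"m{i}" for i in range(4, 8)),
        }

    def test_profile_covers_2_to_n_minus_1(self, planted_two_groups):
        tree = upgma(planted_two_groups)
        profile = ch_log_profile(planted_two_groups, tree)
        assert [c for c, _ in profile] == list(range(2, 8))

    def test_three_equidistant_motifs_profile_is_single_point(self):
        dm = dmat("ABC", np.ones((3, 3)) - np.eye(3))
        tree = upgma(dm)
        profile = ch_log_profile(dm, tree)
        assert [c for c, _ in profile] == [2]

    def test_too_few_motifs_rejected(self):
        dm = dmat("AB", [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="at least 3"):
            ch_log_profile(dm, upgma(dm))
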