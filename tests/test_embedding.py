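import math

import dendropy
import numpy as np
import pytest

from snfkit.core import NetworkScheme
from snfkit.embedding import (
    CenteredMatrix,
    ClusteringResult,
    cluster_network_agreement,
    eigendecompose,
    embed,
    export_newick,
    feature_covariance,
    gram_covariance,
    region_scores,
    row_center,
    ward_dendrogram,
)

from conftest import make_matrix, random_matrix
from oracles import contingency_ari, scipy_ward_heights


class TestRowCenter:
    def test_hand_example(self):
        x = row_center(make_matrix([[-1, -1, 0]]))
        assert x.values[0] == pytest.approx([-1 / 3, -1 / 3, 2 / 3])
        assert x.row_means[0] == pytest.approx(-2 / 3)

    def test_zero_row_stays_zero(self):
        x = row_center(make_matrix([[0, 0, 0]]))
        assert not x.values.any()

    def test_rows_sum_to_zero_and_uncenter_recovers(self):
        rng = np.random.default_rng(3)
        m, _ = random_matrix(rng, 9, 6)
        x = row_center(m)
        assert np.abs(x.values.sum(axis=1)).max() < 1e-9
        assert np.array_equal(x.uncenter(), m.entries.astype(float))

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            row_center(make_matrix([[-1], [1]]))


class TestGramCovariance:
    def test_two_by_two_hand_multiplication(self):
        x = CenteredMatrix(values=np.array([[1.0, -1.0], [-1.0, 1.0]]),
                           row_means=np.zeros(2), roi_ids=("r1", "r2"))
        assert gram_covariance(x).tolist() == [[2, -2], [-2, 2]]

    def test_zero_matrix(self):
        x = CenteredMatrix(values=np.zeros((3, 4)), row_means=np.zeros(3),
                           roi_ids=("a", "b", "c"))
        assert not gram_covariance(x).any()

    def test_symmetric_with_nonnegative_diagonal(self):
        rng = np.random.default_rng(5)
        m, _ = random_matrix(rng, 7, 5)
        sigma = gram_covariance(row_center(m))
        assert np.allclose(sigma, sigma.T)
        assert (np.diagonal(sigma) >= 0).all()


class TestEigendecompose:
    def test_two_by_two_characteristic_polynomial(self):
        values, vectors = eigendecompose(np.array([[2.0, -2.0], [-2.0, 2.0]]))
        assert values == pytest.approx([4.0, 0.0])
        # residual of the eigen equation
        sigma = np.array([[2.0, -2.0], [-2.0, 2.0]])
        assert np.abs(sigma @ vectors - vectors * values).max() < 1e-8

    def test_identity_has_unit_eigenvalues(self):
        values, vectors = eigendecompose(np.eye(3))
        assert values == pytest.approx([1, 1, 1])
        assert np.allclose(vectors.T @ vectors, np.eye(3), atol=1e-6)

    def test_trace_preserved(self):
        rng = np.random.default_rng(9)
        m, _ = random_matrix(rng, 8, 5)
        sigma = gram_covariance(row_center(m))
        values, _ = eigendecompose(sigma)
        assert values.sum() == pytest.approx(np.trace(sigma), rel=1e-6)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(12)
        m, _ = random_matrix(rng, 8, 5)
        _, vectors = eigendecompose(gram_covariance(row_center(m)))
        for i in range(vectors.shape[1]):
            assert vectors[np.argmax(np.abs(vectors[:, i])), i] >= 0

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestDualityAndScores:
    def test_gram_and_feature_covariance_share_nonzero_eigenvalues(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            m, _ = random_matrix(rng, int(rng.integers(3, 15)),
                                 int(rng.integers(3, 9)))
            x = row_center(m)
            lam_g, _ = eigendecompose(gram_covariance(x))
            lam_f, _ = eigendecompose(feature_covariance(x))
            k = min(len(lam_g), len(lam_f))
            assert np.allclose(lam_g[:k], lam_f[:k], atol=1e-8)

    def test_rank_bounded_by_studies_minus_one(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            m, _ = random_matrix(rng, 12, int(rng.integers(2, 7)))
            lam, _ = eigendecompose(gram_covariance(row_center(m)))
            assert int((lam > 1e-9).sum()) <= m.n_studies - 1

    def test_scores_of_hand_example(self):
        x = CenteredMatrix(values=np.array([[1.0, -1.0], [-1.0, 1.0]]),
                           row_means=np.zeros(2), roi_ids=("r1", "r2"))
        lam, vec = eigendecompose(gram_covariance(x))
        scores = region_scores(x, lam, vec, n_components=1)
        assert sorted(scores[:, 0]) == pytest.approx([-math.sqrt(2), math.sqrt(2)])

    def test_full_rank_scores_preserve_distances_up_to_covariance_scaling(self):
        # scores use eigenvalues of X~X~^T/(|S|-1), so pairwise score
        # distances equal centered-row distances divided by sqrt(|S|-1)
        rng = np.random.default_rng(21)
        m, _ = random_matrix(rng, 9, 6)
        x = row_center(m)
        lam, vec = eigendecompose(gram_covariance(x))
        n_pos = int((lam > 1e-9).sum())
        scores = region_scores(x, lam, vec, n_components=n_pos)
        scale = math.sqrt(m.n_studies - 1)
        for i in range(m.n_regions):
            for j in range(i + 1, m.n_regions):
                d_rows = np.linalg.norm(x.values[i] - x.values[j])
                d_scores = np.linalg.norm(scores[i] - scores[j])
                assert d_scores == pytest.approx(d_rows / scale, abs=1e-6)

    def test_duplicate_rows_get_identical_scores(self):
        m = make_matrix([[-1, 0, 1], [-1, 0, 1], [1, -1, 0]])
        emb = embed(m, n_components=2)
        assert np.allclose(emb.scores[0], emb.scores[1], atol=1e-9)

    def test_too_many_components_rejected(self):
        m = make_matrix([[-1, 0, 1], [1, 0, -1], [0, 1, -1]])
        x = row_center(m)
        lam, vec = eigendecompose(gram_covariance(x))
        with pytest.raises(ValueError, match="n_components"):
            region_scores(x, lam, vec, n_components=3)  # rank <= |S|-1 = 2

    def test_explained_variance_ratios_sum_to_one(self):
        rng = np.random.default_rng(25)
        m, scheme = random_matrix(rng, 10, 5)
        emb = embed(m, scheme)
        assert (emb.explained_variance_ratio >= 0).all()
        assert emb.explained_variance_ratio.sum() == pytest.approx(1.0)


class TestWard:
    def test_identical_rows_merge_first_at_height_zero(self):
        m = make_matrix([[-1, 0], [1, 1], [-1, 0]])
        c = ward_dendrogram(m)
        a, b, h, size = c.merge_tree[0]
        assert {a, b} == {0, 2} and h == 0.0 and size == 2

    def test_three_point_exhaustive_example(self):
        # rows (0,0), (0,0), (3,4): exhaustive Ward over all merge orders
        # gives first merge at 0, then height sqrt(2*2/3)*5 = 10/sqrt(3)
        from snfkit.embedding import _ward_merge_tree

        points = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
        merges = _ward_merge_tree(points)
        assert merges[0][2] == 0.0
        assert merges[1][2] == pytest.approx(10 / math.sqrt(3))

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            m, _ = random_matrix(rng, 8, 4)
            heights = [h for _, _, h, _ in ward_dendrogram(m).merge_tree]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_scipy_oracle_on_random_matrices(self):
        # continuous inputs: merge order is unique, so the height multiset
        # is the unique Ward solution (ties admit several valid trees)
        from snfkit.embedding import _ward_merge_tree

        rng = np.random.default_rng(31)
        for _ in range(20):
            points = rng.normal(size=(8, 4))
            mine = np.sort([h for _, _, h, _ in _ward_merge_tree(points)])
            assert np.allclose(mine, scipy_ward_heights(points), atol=1e-8)

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(33)
        m, _ = random_matrix(rng, 10, 5)
        assert ward_dendrogram(m).merge_tree == ward_dendrogram(m).merge_tree

    def test_centered_mode_uses_centered_rows(self):
        m = make_matrix([[-1, -1, -1], [0, 0, 0], [1, 1, 1]])
        # raw rows are distinct, centered rows are all zero
        raw = ward_dendrogram(m, use_centered=False)
        centered = ward_dendrogram(m, use_centered=True)
        assert max(h for _, _, h, _ in centered.merge_tree) == 0.0
        assert max(h for _, _, h, _ in raw.merge_tree) > 0.0

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            ward_dendrogram(make_matrix([[1, 0]]))

    def test_labels_at_k_gives_k_nonempty_groups(self):
        rng = np.random.default_rng(35)
        m, _ = random_matrix(rng, 9, 5)
        c = ward_dendrogram(m)
        for k in range(1, 10):
            labels = c.labels_at_k(k)
            assert len(set(labels.tolist())) == k


class TestAgreement:
    def test_identical_partition_scores_one(self):
        m = make_matrix([[-1, -1, 0], [-1, -1, 0], [0, 1, 1], [0, 1, 1]],
                        [("a",), ("a",), ("b",), ("b",)])
        scheme = NetworkScheme.from_regions(m.regions, network_ids=("a", "b"),
                                            priority=("a", "b"))
        c = ward_dendrogram(m)
        assert cluster_network_agreement(c, scheme, 2) == pytest.approx(1.0)

    def test_matches_contingency_formula(self):
        rng = np.random.default_rng(39)
        for _ in range(10):
            m, scheme = random_matrix(rng, 8, 5)
            c = ward_dendrogram(m)
            k = int(rng.integers(2, 8))
            got = cluster_network_agreement(c, scheme, k)
            reference = [scheme.dominant(r) for r in c.leaf_ids]
            expected = contingency_ari(reference, c.labels_at_k(k).tolist())
            assert got == pytest.approx(expected, abs=1e-12)

    def test_label_renaming_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        labels = [0, 0, 1, 1, 2]
        renamed = [5, 5, 9, 9, 7]
        reference = ["a", "a", "b", "b", "b"]
        assert adjusted_rand_score(reference, labels) == pytest.approx(
            adjusted_rand_score(reference, renamed))

    def test_k_out_of_range(self, toy):
        m, scheme = toy
        c = ward_dendrogram(m)
        with pytest.raises(ValueError):
            cluster_network_agreement(c, scheme, 1)
        with pytest.raises(ValueError):
            cluster_network_agreement(c, scheme, 4)


def _leaf_sets(newick: str) -> set[frozenset[str]]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    out = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(leaves) > 1:
            out.add(leaves)
    return out


class TestNewick:
    def test_two_leaf_round_trip(self):
        m = make_matrix([[-1, 0], [1, 1]])
        c = ward_dendrogram(m)
        nwk = export_newick(c)
        assert _leaf_sets(nwk) == {frozenset({"r1", "r2"})}

    def test_topology_round_trips(self, toy):
        m, _ = toy
        c = ward_dendrogram(m)
        expected = set()
        n = c.n_leaves
        members = {i: frozenset({c.leaf_ids[i]}) for i in range(n)}
        for t, (a, b, _h, _s) in enumerate(c.merge_tree):
            members[n + t] = members[a] | members[b]
            expected.add(members[n + t])
        assert _leaf_sets(export_newick(c)) == expected

    def test_leaf_count_and_ultrametric_depths(self):
        rng = np.random.default_rng(43)
        m, _ = random_matrix(rng, 7, 4)
        c = ward_dendrogram(m)
        nwk = export_newick(c)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = tree.leaf_nodes()
        assert len(leaves) == 7
        root_height = max(h for _, _, h, _ in c.merge_tree)
        depths = [lf.distance_from_root() for lf in leaves]
        assert depths == pytest.approx([root_height] * 7, abs=1e-6)

    def test_malformed_merge_tree_rejected(self):
        bad = ClusteringResult(merge_tree=((0, 1, 1.0, 2),), leaf_ids=("a", "b", "c"))
        with pytest.raises(ValueError, match="malformed"):
            export_newick(bad)
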