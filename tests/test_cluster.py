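"""Hierarchical clustering, ordering, size gate, top-branch covariates."""

import numpy as np
import pytest

from chmforge import (
    Dendrogram,
    LabeledMatrix,
    OrderSpec,
    check_size,
    cluster,
    cut_top_branches,
    distance_matrix,
    order_axis,
)
from chmforge.errors import SizeLimitError, ValidationError
from chmforge.fixtures import clustered_matrix
from tests.conftest import random_labeled_matrix
from tests.naive_linkage import (
    naive_agglomerate,
    naive_pairwise_distance,
    ward_centroid_height,
)


def lm(values):
    a = np.asarray(values, dtype=float)
    return LabeledMatrix(
        [f"r{i}" for i in range(a.shape[0])], [f"c{j}" for j in range(a.shape[1])], a
    )


class TestCheckSize:
    def test_accepts_1000_by_4000(self):
        m = LabeledMatrix(
            [f"r{i}" for i in range(1000)],
            [f"c{j}" for j in range(4000)],
            np.zeros((1000, 4000)),
        )
        check_size(m)  # no error

    def test_rejects_over_limit_naming_dimensions(self):
        m = LabeledMatrix(
            [f"r{i}" for i in range(4501)],
            [f"c{j}" for j in range(500)],
            np.zeros((4501, 500)),
        )
        with pytest.raises(SizeLimitError) as exc:
            check_size(m)
        assert "4501" in str(exc.value) and "500" in str(exc.value)

    def test_minimal_matrix_passes(self):
        check_size(LabeledMatrix(["r"], ["c"], np.zeros((1, 1))))

    def test_custom_limit(self):
        m = lm(np.zeros((3, 3)))
        with pytest.raises(SizeLimitError):
            check_size(m, limit=5)


class TestDistance:
    def test_three_four_five(self):
        d = distance_matrix(lm([[0.0, 0.0], [3.0, 4.0]]), "row", "euclidean")
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0 and d[1, 0] == d[0, 1]

    def test_identical_rows_correlation_zero(self):
        d = distance_matrix(lm([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]), "row", "correlation")
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "correlation"])
    def test_missing_pairwise_rescale_matches_oracle(self, metric):
        rng = np.random.default_rng(17)
        m = random_labeled_matrix(rng, 6, 10, missing_frac=0.1)
        d = distance_matrix(m, "row", metric)
        expected = naive_pairwise_distance(m.values, metric)
        assert np.allclose(d, expected, atol=1e-10)

    def test_no_shared_positions_errors(self):
        m = lm([[1.0, np.nan], [np.nan, 2.0]])
        with pytest.raises(ValidationError):
            distance_matrix(m, "row", "euclidean")

    def test_column_axis(self):
        m = lm([[0.0, 3.0], [0.0, 4.0]])
        d = distance_matrix(m, "col", "euclidean")
        assert d[0, 1] == pytest.approx(5.0)


class TestCluster:
    def test_single_linkage_hand_example(self):
        m = lm([[0.0], [1.0], [10.0], [11.0]])
        dend = cluster(m, "row", OrderSpec("cluster", "single", "euclidean"))
        assert dend.heights[0] == pytest.approx(1.0)
        assert dend.heights[1] == pytest.approx(1.0)
        assert dend.heights[2] == pytest.approx(9.0)
        # first merges join {0,1} and {10,11}
        first_two = {frozenset(p) for p in dend.merges[:2]}
        assert first_two == {frozenset({-1, -2}), frozenset({-3, -4})}

    @pytest.mark.parametrize("linkage", ["ward", "complete", "average", "single"])
    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "correlation"])
    def test_heights_match_naive_oracle(self, linkage, metric):
        rng = np.random.default_rng(hash((linkage, metric)) % 2**31)
        for _ in range(5):
            n = int(rng.integers(3, 15))
            m = random_labeled_matrix(rng, n, 6)
            dend = cluster(m, "row", OrderSpec("cluster", linkage, metric))
            D = distance_matrix(m, "row", metric)
            heights, _ = naive_agglomerate(D, linkage)
            assert np.allclose(sorted(dend.heights), sorted(heights), atol=1e-9)

    @pytest.mark.parametrize("linkage", ["ward", "complete", "average", "single"])
    def test_cophenetic_structure_matches_oracle(self, linkage):
        from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(99)
        m = random_labeled_matrix(rng, 12, 5)
        D = distance_matrix(m, "row", "euclidean")
        Z = scipy_linkage(squareform(D, checks=False), method=linkage)
        _, coph_naive = naive_agglomerate(D, linkage)
        assert np.allclose(cophenet(Z), squareform(coph_naive, checks=False), atol=1e-9)

    def test_ward_euclidean_matches_centroid_formula(self):
        """First ward merge height equals the closed-form centroid cost."""
        rng = np.random.default_rng(12)
        m = random_labeled_matrix(rng, 8, 4)
        dend = cluster(m, "row", OrderSpec("cluster", "ward", "euclidean"))
        a, b = dend.merges[0]
        assert a < 0 and b < 0
        h = ward_centroid_height([-a - 1], [-b - 1], m.values)
        assert dend.heights[0] == pytest.approx(h, abs=1e-9)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(7)
        for linkage in ("ward", "complete", "average", "single"):
            m = random_labeled_matrix(rng, 15, 6)
            dend = cluster(m, "row", OrderSpec("cluster", linkage, "euclidean"))
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(dend.heights, dend.heights[1:]))

    def test_single_leaf_degenerate(self):
        m = lm([[1.0, 2.0]])
        dend = cluster(m, "row", OrderSpec("cluster", "ward", "euclidean"))
        assert dend.merges == [] and dend.leaf_order == [0]

    def test_ward_within_cluster_variance_nondecreasing(self):
        """Ward merge costs (height^2 / 2 increments of total within-cluster
        sum of squares) accumulate monotonically."""
        rng = np.random.default_rng(31)
        m = random_labeled_matrix(rng, 12, 5)
        dend = cluster(m, "row", OrderSpec("cluster", "ward", "euclidean"))
        increments = [h**2 / 2.0 for h in dend.heights]
        assert all(b >= a - 1e-12 for a, b in zip(increments, increments[1:]))


class TestOrderAxis:
    def test_original_is_identity(self):
        m = lm(np.zeros((5, 2)))
        perm, dend = order_axis(m, "row", OrderSpec("original"))
        assert perm == [0, 1, 2, 3, 4] and dend is None

    def test_random_seeded_reproducible(self):
        m = lm(np.zeros((100, 2)))
        p1, _ = order_axis(m, "row", OrderSpec("random", seed=5))
        p2, _ = order_axis(m, "row", OrderSpec("random", seed=5))
        p3, _ = order_axis(m, "row", OrderSpec("random", seed=6))
        assert p1 == p2
        assert p1 != p3
        assert sorted(p1) == list(range(100))

    def test_cluster_mode_returns_leaf_order(self):
        rng = np.random.default_rng(1)
        m = random_labeled_matrix(rng, 10, 4)
        spec = OrderSpec("cluster", "average", "manhattan")
        perm, dend = order_axis(m, "row", spec)
        assert perm == dend.leaf_order
        assert sorted(perm) == list(range(10))

    def test_orderspec_validation(self):
        with pytest.raises(ValidationError):
            OrderSpec("cluster", linkage="ward")  # missing distance
        with pytest.raises(ValidationError):
            OrderSpec("random")  # missing seed


class TestCutTopBranches:
    def _dend(self, seed=3, n=12):
        rng = np.random.default_rng(seed)
        m = random_labeled_matrix(rng, n, 5)
        return cluster(m, "row", OrderSpec("cluster", "ward", "euclidean")), m

    def test_k1_single_cluster(self):
        dend, m = self._dend()
        cov = cut_top_branches(dend, 1, labels=m.row_labels, axis="row")
        assert set(cov.values.values()) == {"Cluster 1"}

    def test_k_equals_n_all_singletons(self):
        dend, m = self._dend()
        cov = cut_top_branches(dend, dend.n_leaves, labels=m.row_labels, axis="row")
        assert len(set(cov.values.values())) == dend.n_leaves

    def test_numbered_by_leaf_order_appearance(self):
        dend, m = self._dend()
        cov = cut_top_branches(dend, 3, labels=m.row_labels, axis="row")
        seen = []
        for leaf in dend.leaf_order:
            c = cov.values[m.row_labels[leaf]]
            if c not in seen:
                seen.append(c)
        assert seen == ["Cluster 1", "Cluster 2", "Cluster 3"]

    def test_planted_four_clusters_recovered(self):
        m, assign = clustered_matrix(n_rows=40, n_cols=60, k=4, seed=8)
        dend = cluster(m, "col", OrderSpec("cluster", "ward", "euclidean"))
        cov = cut_top_branches(dend, 4, labels=m.col_labels, axis="col")
        got = [cov.values[lab] for lab in m.col_labels]
        # same partition up to relabeling
        mapping = {}
        for g, a in zip(got, assign):
            mapping.setdefault(a, g)
            assert mapping[a] == g
        assert len(set(mapping.values())) == 4

    def test_cut_refinement(self):
        """Cutting at k+1 refines the k-cut partition."""
        dend, m = self._dend(seed=13, n=15)
        for k in range(1, 6):
            a = cut_top_branches(dend, k, labels=m.row_labels, axis="row").values
            b = cut_top_branches(dend, k + 1, labels=m.row_labels, axis="row").values
            fine_to_coarse = {}
            for lab in m.row_labels:
                fine_to_coarse.setdefault(b[lab], set()).add(a[lab])
            assert all(len(s) == 1 for s in fine_to_coarse.values())

    def test_k_out_of_range(self):
        dend, m = self._dend()
        with pytest.raises(ValidationError):
            cut_top_branches(dend, 0)
        with pytest.raises(ValidationError):
            cut_top_branches(dend, dend.n_leaves + 1)


class TestNewick:
    def test_parses_with_dendropy_and_preserves_leaves(self):
        import dendropy

        rng = np.random.default_rng(14)
        m = random_labeled_matrix(rng, 9, 4)
        dend = cluster(m, "row", OrderSpec("cluster", "average", "euclidean"))
        text = dend.to_newick(m.row_labels)
        tree = dendropy.Tree.get(data=text, schema="newick")
        taxa = sorted(t.label for t in tree.taxon_namespace)
        assert taxa == sorted(m.row_labels)
        # ultrametric: every root-to-leaf path length equals the root height
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        root_h = dend.heights[-1]
        assert np.allclose(depths, root_h, atol=1e-9)

    def test_single_leaf_newick(self):
        dend = Dendrogram(merges=[], heights=[], leaf_order=[0])
        assert dend.to_newick(["only"]).startswith("only")
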