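import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_complete_linkage, random_ultrametric
from omiclust.clustering import (
    CopheneticMatrix,
    Dendrogram,
    DistanceMatrix,
    complete_linkage,
    cophenetic_matrix,
    euclidean_distances,
    read_cophenetic_tsv,
    to_newick,
    write_matrix_tsv,
)
from omiclust.errors import ValidationError


def points_1d(values):
    return euclidean_distances(np.asarray(values, dtype=float)[:, None])


class TestEuclideanDistances:
    def test_identical_rows_zero(self):
        dm = euclidean_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert dm.d[0, 1] == 0.0

    def test_3_4_5_triangle(self):
        dm = euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert dm.d[0, 1] == pytest.approx(5.0)

    def test_feature_permutation_invariant(self, rng):
        x = rng.normal(size=(6, 10))
        perm = rng.permutation(10)
        d1 = euclidean_distances(x).d
        d2 = euclidean_distances(x[:, perm]).d
        assert np.allclose(d1, d2)

    def test_nonfinite_named(self):
        x = np.array([[0.0, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValidationError, match="'b'.*feature 0"):
            euclidean_distances(x, ["a", "b"])

    def test_triangle_inequality(self, rng):
        x = rng.normal(size=(8, 5))
        d = euclidean_distances(x).d
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


class TestCompleteLinkage:
    def test_hand_example_0_1_10(self):
        # {0,1} merge at 1; complete-linkage distance to {10} is max(10,9)=10
        tree = complete_linkage(points_1d([0.0, 1.0, 10.0]))
        heights = [h for _, _, h in tree.merges]
        assert heights == pytest.approx([1.0, 10.0])

    def test_all_identical_zero_heights(self):
        tree = complete_linkage(points_1d([2.0, 2.0, 2.0, 2.0]))
        assert all(h == 0.0 for _, _, h in tree.merges)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            complete_linkage(DistanceMatrix(("a",), np.zeros((1, 1))))

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_small(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        x = rng.normal(size=(n, 4))
        dm = euclidean_distances(x)
        tree = complete_linkage(dm)
        merges_oracle, _ = brute_force_complete_linkage(dm.d)
        assert [h for _, _, h in tree.merges] == pytest.approx(
            [h for _, _, h in merges_oracle]
        )
        assert [(a, b) for a, b, _ in tree.merges] == [
            (a, b) for a, b, _ in merges_oracle
        ]

    def test_heights_monotone(self, rng):
        for _ in range(10):
            x = rng.normal(size=(12, 3))
            tree = complete_linkage(euclidean_distances(x))
            heights = [h for _, _, h in tree.merges]
            assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))

    def test_tied_distances_deterministic(self):
        # four corners of a square: many exactly tied distances
        x = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        t1 = complete_linkage(euclidean_distances(x))
        t2 = complete_linkage(euclidean_distances(x))
        assert t1 == t2
        assert t1.merges[0][:2] == (0, 1)  # lowest-index pair first


class TestCopheneticMatrix:
    def test_hand_example(self):
        tree = complete_linkage(points_1d([0.0, 1.0, 10.0]))
        c = cophenetic_matrix(tree).c
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(10.0)
        assert c[1, 2] == pytest.approx(10.0)

    def test_two_leaf_tree(self):
        tree = complete_linkage(points_1d([0.0, 3.0]))
        c = cophenetic_matrix(tree).c
        assert c[0, 1] == pytest.approx(3.0)

    def test_ultrametric_inequality(self, rng):
        for _ in range(10):
            x = rng.normal(size=(10, 4))
            c = cophenetic_matrix(complete_linkage(euclidean_distances(x))).c
            for i in range(10):
                for j in range(10):
                    for k in range(10):
                        assert c[i, k] <= max(c[i, j], c[j, k]) + 1e-9

    def test_matches_oracle_lookup(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.normal(size=(7, 3))
            dm = euclidean_distances(x)
            got = cophenetic_matrix(complete_linkage(dm)).c
            _, expected = brute_force_complete_linkage(dm.d)
            assert np.array_equal(got, expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_ultrametric_fixed_point(self, seed):
        # clustering an ultrametric distance matrix must return it exactly
        rng = np.random.default_rng(seed)
        n = 9
        u = random_ultrametric(rng, n)
        dm = DistanceMatrix(tuple(str(i) for i in range(n)), u)
        c = cophenetic_matrix(complete_linkage(dm)).c
        assert np.allclose(c, u)


class TestExportFormats:
    def test_newick_parses_and_preserves_heights(self):
        pytest.importorskip("dendropy")
        import dendropy

        x = np.random.default_rng(0).normal(size=(6, 3))
        dm = euclidean_distances(x, [f"s{i}" for i in range(6)])
        tree = complete_linkage(dm)
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        c = cophenetic_matrix(tree)
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i in range(6):
            for j in range(i + 1, 6):
                path = pdm.distance(taxa[f"s{i}"], taxa[f"s{j}"])
                # leaf-to-leaf path length is twice the merge height
                assert path == pytest.approx(2 * c.c[i, j], rel=1e-6)

    def test_cophenetic_tsv_round_trip(self, tmp_path):
        x = np.random.default_rng(1).normal(size=(5, 3))
        c = cophenetic_matrix(complete_linkage(euclidean_distances(x)))
        path = tmp_path / "coph.tsv"
        write_matrix_tsv(c.sample_ids, c.c, path)
        back = read_cophenetic_tsv(path)
        assert back.sample_ids == c.sample_ids
        assert np.allclose(back.c, c.c)


class TestDendrogramValidation:
    def test_wrong_merge_count(self):
        with pytest.raises(ValidationError, match="merges"):
            Dendrogram(("a", "b", "c"), ((0, 1, 1.0),))

    def test_decreasing_heights_rejected(self):
        with pytest.raises(ValidationError, match="non-decreasing"):
            Dendrogram(("a", "b", "c"), ((0, 1, 5.0), (2, 3, 1.0)))

    def test_node_merged_twice_rejected(self):
        with pytest.raises(ValidationError, match="twice"):
            Dendrogram(("a", "b", "c", "d"),
                       ((0, 1, 1.0), (0, 2, 2.0), (3, 4, 3.0)))
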