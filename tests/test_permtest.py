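import numpy as np
import pandas as pd
import pytest

from conftest import exhaustive_null
from omiclust.clustering import (
    CopheneticMatrix,
    complete_linkage,
    cophenetic_matrix,
    euclidean_distances,
)
from omiclust.errors import ValidationError
from omiclust.io_model import SampleTable
from omiclust.permtest import (
    LabelVector,
    VariableBinning,
    derive_labels,
    mean_within_label_distance,
    permutation_z,
    results_table,
    run_all_variables,
)


def coph_from_points(values):
    x = np.asarray(values, dtype=float)[:, None]
    dm = euclidean_distances(x, [f"s{i}" for i in range(len(values))])
    return cophenetic_matrix(complete_linkage(dm))


def labels_for(c, labels, name="var"):
    return LabelVector(c.sample_ids, tuple(labels), name)


class TestMeanWithinLabelDistance:
    def test_two_samples_same_label(self):
        c = coph_from_points([0.0, 3.0])
        mean, n_pairs = mean_within_label_distance(c, labels_for(c, "AA"))
        assert (mean, n_pairs) == (3.0, 1)

    def test_single_label_full_upper_triangle(self):
        c = coph_from_points([0.0, 1.0, 10.0])
        mean, n_pairs = mean_within_label_distance(c, labels_for(c, "AAA"))
        assert n_pairs == 3
        assert mean == pytest.approx((1.0 + 10.0 + 10.0) / 3)

    def test_four_leaf_aabb_pools_two_pairs(self):
        c = coph_from_points([0.0, 1.0, 10.0, 11.5])
        l = labels_for(c, "AABB")
        mean, n_pairs = mean_within_label_distance(c, l)
        assert n_pairs == 2
        assert mean == pytest.approx((c.c[0, 1] + c.c[2, 3]) / 2)

    def test_specific_level(self):
        c = coph_from_points([0.0, 1.0, 10.0, 11.5])
        l = labels_for(c, "AABB")
        mean, n_pairs = mean_within_label_distance(c, l, "B")
        assert (mean, n_pairs) == (pytest.approx(c.c[2, 3]), 1)

    def test_singleton_level_errors(self):
        c = coph_from_points([0.0, 1.0, 10.0])
        with pytest.raises(ValidationError, match="at least 2"):
            mean_within_label_distance(c, labels_for(c, "AAB"), "B")

    def test_unknown_level_errors(self):
        c = coph_from_points([0.0, 1.0])
        with pytest.raises(ValidationError, match="'C'"):
            mean_within_label_distance(c, labels_for(c, "AA"), "C")


class TestPermutationZ:
    def test_single_level_undefined(self):
        c = coph_from_points([0.0, 1.0, 10.0])
        results = permutation_z(c, labels_for(c, "AAA"), n_perm=200, seed=1)
        assert results[0].undefined and results[0].z is None

    def test_n_perm_floor(self):
        c = coph_from_points([0.0, 1.0, 10.0])
        with pytest.raises(ValidationError, match="100"):
            permutation_z(c, labels_for(c, "AAB"), n_perm=99, seed=1)

    def test_seed_required(self):
        c = coph_from_points([0.0, 1.0, 10.0])
        with pytest.raises(ValidationError, match="seed"):
            permutation_z(c, labels_for(c, "AAB"), n_perm=200, seed=None)

    def test_planted_clusters_attain_exhaustive_minimum(self):
        # two well-separated 3-point clusters, labels matching the clusters:
        # the observed pooled mean is the minimum over all 20 balanced
        # labelings, so z is the most negative value attainable
        c = coph_from_points([0.0, 0.1, 0.2, 100.0, 100.1, 100.3])
        labels = ["A", "A", "A", "B", "B", "B"]
        l = labels_for(c, labels)
        null = exhaustive_null(c.c, labels)
        obs, _ = mean_within_label_distance(c, l)
        assert obs == pytest.approx(null.min())
        results = permutation_z(c, l, n_perm=5000, seed=3)
        overall = results[0]
        z_floor = (null.min() - null.mean()) / null.std(ddof=0)
        assert overall.z == pytest.approx(z_floor, rel=0.05)
        assert overall.z < -1.96

    def test_matches_exhaustive_null(self):
        rng = np.random.default_rng(7)
        c = coph_from_points(rng.normal(size=6))
        labels = ["A", "A", "A", "B", "B", "B"]
        l = labels_for(c, labels)
        null = exhaustive_null(c.c, labels)
        results = permutation_z(c, l, n_perm=100_000, seed=11)
        overall = results[0]
        assert overall.null_mean == pytest.approx(null.mean(), rel=0.01)
        # the enumeration is the whole null population, hence ddof=0
        assert overall.null_sd == pytest.approx(null.std(ddof=0), rel=0.01)

    def test_determinism(self):
        c = coph_from_points([0.0, 1.0, 5.0, 9.0])
        l = labels_for(c, "ABAB")
        r1 = permutation_z(c, l, n_perm=500, seed=9)
        r2 = permutation_z(c, l, n_perm=500, seed=9)
        assert r1 == r2

    def test_level_relabeling_symmetry(self):
        # renaming the level names (same assignment) keeps all numbers
        c = coph_from_points([0.0, 1.0, 5.0, 9.0, 2.0, 7.0])
        a = permutation_z(c, labels_for(c, "AABBAB"), n_perm=500, seed=4)
        b = permutation_z(c, labels_for(c, "XXYYXY"), n_perm=500, seed=4)
        for ra, rb in zip(a, b):
            assert ra.observed_mean == rb.observed_mean
            assert ra.null_mean == rb.null_mean
            assert ra.z == rb.z

    def test_returns_overall_plus_level_rows(self):
        c = coph_from_points([0.0, 1.0, 5.0, 9.0])
        results = permutation_z(c, labels_for(c, "AABB"), n_perm=200, seed=5)
        assert [r.level for r in results] == ["overall", "A", "B"]

    def test_level_mean_method_differs_when_unbalanced(self):
        c = coph_from_points([0.0, 1.0, 2.0, 50.0, 51.0])
        l = labels_for(c, "AAABB")
        pooled = permutation_z(c, l, n_perm=500, seed=2, method="pooled")[0]
        by_level = permutation_z(c, l, n_perm=500, seed=2, method="level_mean")[0]
        # pooled weights the A pairs 3:1; level_mean weights levels equally
        assert pooled.observed_mean != pytest.approx(by_level.observed_mean)


class TestBinningAndVariables:
    def test_na_binning(self):
        b = VariableBinning()
        assert b.na_level(5.0) == "base"
        assert b.na_level(100.0) == "high"
        assert b.na_level(300.0) == "high"

    def test_mg_binning(self):
        b = VariableBinning()
        assert b.mg_level(0.02) == "low"
        assert b.mg_level(0.8) == "base"
        assert b.mg_level(200.0) == "high"

    def test_collapse_phase(self, sample_table):
        b = VariableBinning(collapse_phase=True)
        l = derive_labels(sample_table, "growth_phase", b)
        assert set(l.labels) == {"exponential", "stationary"}

    def test_missing_variable_errors(self, sample_table):
        with pytest.raises(ValidationError, match="bogus"):
            derive_labels(sample_table, "bogus")


class TestRunAllVariables:
    @pytest.fixture
    def coph8(self, sample_table):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 20))
        dm = euclidean_distances(x, sample_table.sample_ids)
        return cophenetic_matrix(complete_linkage(dm))

    def test_structure_one_overall_plus_levels(self, coph8, sample_table):
        results = run_all_variables(
            coph8, sample_table, variables=("batch",), n_perm=200, seed=1
        )
        assert [r.level for r in results] == ["overall", "b1", "b2"]

    def test_row_order_invariance(self, coph8, sample_table):
        shuffled = SampleTable(
            sample_table.data.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        a = run_all_variables(coph8, sample_table, variables=("batch",),
                              n_perm=200, seed=1)
        b = run_all_variables(coph8, shuffled, variables=("batch",),
                              n_perm=200, seed=1)
        assert a == b

    def test_variable_order_invariance(self, coph8, sample_table):
        a = run_all_variables(coph8, sample_table,
                              variables=("batch", "growth_phase"),
                              n_perm=200, seed=1)
        b = run_all_variables(coph8, sample_table,
                              variables=("growth_phase", "batch"),
                              n_perm=200, seed=1)
        key = lambda r: (r.variable_name, r.level)
        assert sorted(a, key=key) == sorted(b, key=key)

    def test_results_table_shape(self, coph8, sample_table):
        results = run_all_variables(coph8, sample_table,
                                    variables=("batch", "growth_phase"),
                                    n_perm=200, seed=1)
        table = results_table(results)
        assert set(table["variable"]) == {"batch", "growth_phase"}
        assert "z" in table.columns
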