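import numpy as np
import pytest
import scipy.sparse as sp

from metacell.core_data import CountMatrix, DataError
from metacell.partition import Assignment
from metacell.refine import (
    OUTLIER_PARAMETRIC,
    OUTLIER_SMALL_COMPONENT,
    MetacellCover,
    OutlierParams,
    SplitParams,
    filter_outliers,
    outlier_fold,
    pool_frequencies,
    split_heterogeneous,
)
from metacell.synthetic import SyntheticSpec, generate, make_preset
from conftest import random_count_matrix
from oracles import pool_frequencies_bruteforce


def _matrix(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        [f"g{i}" for i in range(counts.shape[0])],
        [f"c{j}" for j in range(counts.shape[1])],
        sp.csr_matrix(counts),
    )


class TestPoolFrequencies:
    def test_worked_example(self):
        # one metacell, two cells with totals 4 and 4; gene0 counts 2 and 0
        m = _matrix([[2, 0], [2, 4]])
        p = pool_frequencies(m, Assignment(np.array([0, 0])))
        assert p[0, 0] == pytest.approx(0.25)

    def test_columns_sum_to_one(self, small_matrix):
        labels = np.arange(small_matrix.n_cells) % 4
        p = pool_frequencies(small_matrix, Assignment(labels))
        np.testing.assert_allclose(p.sum(axis=0), 1.0)

    def test_matches_bruteforce(self):
        m = random_count_matrix(12, 10, rng_seed=4)
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        p = pool_frequencies(m, Assignment(labels))
        np.testing.assert_allclose(p, pool_frequencies_bruteforce(m.dense(), labels))

    def test_empty_metacell_raises(self):
        m = _matrix([[1, 2]])
        with pytest.raises(DataError):
            pool_frequencies(m, Assignment(np.array([0, 2])))


class TestOutlierFold:
    def test_arithmetic_example(self):
        # u_gi = 15, u_i = 100, p = 0.01 -> log2(16/2) = 3
        m = _matrix([[15], [85]])
        p = np.array([[0.01], [0.99]])
        f = outlier_fold(m, p, Assignment(np.array([0])))
        assert f[0, 0] == pytest.approx(3.0)

    def test_zero_count_never_positive(self, small_matrix):
        labels = np.zeros(small_matrix.n_cells, dtype=int)
        a = Assignment(labels)
        f = outlier_fold(small_matrix, pool_frequencies(small_matrix, a), a)
        assert np.all(f[small_matrix.dense() == 0] <= 0)

    def test_regularization_bounds_low_count_genes(self):
        """With u_gi <= 3 the +1 regularization pins |f| below 2 whenever the
        expected count stays below 3 (low-total genes at any depth <= 1000)."""
        for u in range(4):
            for expected in np.linspace(0.0, 3.0, 50):
                f = np.log2((1 + u) / (1 + expected))
                assert abs(f) <= 2.0 + 1e-12


class TestFilterOutliers:
    def _cover_with_fold(self, f_value):
        m = _matrix([[10, 10], [10, 10]])
        a = Assignment(np.array([0, 0]))
        f = np.full((2, 2), -1.0)
        f[0, 0] = f_value
        return filter_outliers(f, OutlierParams(t_lfc=3.0), a)

    def test_threshold_is_inclusive(self):
        cover, report = self._cover_with_fold(3.0)
        assert cover.mc[0] == -1
        assert cover.outlier_kind[0] == OUTLIER_PARAMETRIC
        assert report.iloc[0]["f"] == pytest.approx(3.0)

    def test_below_threshold_untouched(self):
        cover, report = self._cover_with_fold(2.999)
        assert cover.mc[0] == 0 and len(report) == 0

    def test_null_multinomial_flags_at_most_two_percent(self):
        spec = SyntheticSpec(
            n_genes=300,
            type_profiles=(np.ones(300) / 300)[None, :],
            cells_per_type=[400],
            depth_model=("fixed", 1000),
            rng_seed=5,
        )
        m, _ = generate(spec)
        a = Assignment(np.zeros(m.n_cells, dtype=int))
        f = outlier_fold(m, pool_frequencies(m, a), a)
        _, report = filter_outliers(f, OutlierParams(t_lfc=3.0), a)
        assert len(report) / m.n_cells <= 0.02

    def test_doublet_recovery(self):
        """50/50 doublets between two distant types, assigned to one parent's
        metacell, are flagged with high recall and precision."""
        m, truth = generate(make_preset("doublet_spike", rng_seed=3))
        doublet = truth["is_doublet"].to_numpy()
        a = Assignment(truth["type"].to_numpy().astype(int))
        f = outlier_fold(m, pool_frequencies(m, a), a)
        _, report = filter_outliers(f, OutlierParams(t_lfc=3.0), a)
        flagged = np.zeros(m.n_cells, dtype=bool)
        flagged[report["cell"].to_numpy()] = True
        tp = (flagged & doublet).sum()
        assert tp / doublet.sum() >= 0.7
        assert tp / max(flagged.sum(), 1) >= 0.5

    def test_single_pass_is_stable_on_unchanged_frequencies(self):
        m = random_count_matrix(20, 30, rng_seed=6, mean_count=5.0)
        a = Assignment(np.arange(30) % 3)
        f = outlier_fold(m, pool_frequencies(m, a), a)
        cover1, rep1 = filter_outliers(f, OutlierParams(t_lfc=2.0), a)
        cover2, rep2 = filter_outliers(f, OutlierParams(t_lfc=2.0), cover1)
        assert set(rep2["cell"]) == set()  # flagged cells are already outliers
        assert np.array_equal(cover1.mc, cover2.mc)

    def test_cover_law(self):
        m = random_count_matrix(15, 20, rng_seed=7, mean_count=4.0)
        a = Assignment(np.arange(20) % 2)
        f = outlier_fold(m, pool_frequencies(m, a), a)
        cover, _ = filter_outliers(f, OutlierParams(t_lfc=1.5), a)
        assert np.all((cover.mc >= 0) | (cover.mc == -1))
        kinds = cover.outlier_kind[cover.mc == -1]
        assert all(k is not None for k in kinds)


class TestSplitHeterogeneous:
    def test_homogeneous_metacell_not_split(self):
        spec = SyntheticSpec(
            n_genes=200,
            type_profiles=(np.ones(200) / 200)[None, :],
            cells_per_type=[40],
            depth_model=("fixed", 600),
            rng_seed=9,
        )
        m, _ = generate(spec)
        a = Assignment(np.zeros(40, dtype=int))
        out = split_heterogeneous(m, a, SplitParams())
        assert out.n_mc == 1

    def test_planted_two_state_metacell_is_split(self):
        profiles = np.zeros((2, 100))
        profiles[0, :50] = 1 / 50
        profiles[1, 50:] = 1 / 50
        spec = SyntheticSpec(
            n_genes=100,
            type_profiles=profiles,
            cells_per_type=[30, 30],
            depth_model=("fixed", 500),
            rng_seed=10,
        )
        m, truth = generate(spec)
        out = split_heterogeneous(m, Assignment(np.zeros(60, dtype=int)), SplitParams())
        assert out.n_mc == 2
        # the split recovers the planted types (DBSCAN noise points are folded
        # into the largest cluster, so allow a few stragglers)
        from sklearn.metrics import adjusted_rand_score

        types = truth["type"].to_numpy().astype(int)
        assert adjusted_rand_score(types, out.mc) >= 0.8

    def test_tiny_metacell_untouched(self):
        m = random_count_matrix(10, 2, rng_seed=1)
        out = split_heterogeneous(m, Assignment(np.zeros(2, dtype=int)), SplitParams())
        assert out.n_mc == 1

    def test_split_preserves_cell_union(self):
        m = random_count_matrix(50, 40, rng_seed=2, mean_count=5.0)
        a = Assignment(np.arange(40) % 2)
        out = split_heterogeneous(m, a, SplitParams())
        assert np.all(out.mc >= 0)


class TestCover:
    def test_drop_metacell(self):
        cover = MetacellCover.from_assignment(Assignment(np.array([0, 0, 1, 1, 2])))
        out = cover.drop_metacell(1, reason="doublet_mc")
        assert out.n_mc == 2
        assert np.array_equal(out.mc, [0, 0, -1, -1, 1])
        assert out.outlier_kind[2] == "doublet_mc"

    def test_from_assignment_provenance(self):
        cover = MetacellCover.from_assignment(Assignment(np.array([0, -1])))
        assert cover.outlier_kind[1] == OUTLIER_SMALL_COMPONENT
        assert cover.outlier_kind[0] is None
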