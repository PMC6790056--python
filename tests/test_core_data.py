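import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from metacell.core_data import (
    CellFilterParams,
    CountMatrix,
    EmptyResultError,
    ParameterError,
    ParseError,
    downsample_cells,
    filter_cells_and_genes,
    load_umi_matrix,
    write_umi_matrix,
)
from conftest import random_count_matrix


def _write_mtx(tmp_path, header_shape, entries, genes, cells):
    (tmp_path / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        f"{header_shape[0]} {header_shape[1]} {len(entries)}\n"
        + "".join(f"{g} {c} {v}\n" for g, c, v in entries)
    )
    (tmp_path / "genes.tsv").write_text("".join(f"{g}\t{g}\n" for g in genes))
    (tmp_path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cells))


class TestLoaders:
    def test_triplet_tally(self, tmp_path):
        _write_mtx(tmp_path, (3, 2), [(1, 1, 2), (2, 2, 5)], ["g1", "g2", "g3"], ["c1", "c2"])
        m = load_umi_matrix(tmp_path, "mtx_triplet")
        assert m.cell_totals.tolist() == [2, 5]
        assert m.counts[0, 0] == 2 and m.counts[1, 1] == 5

    def test_empty_triplet_body_gives_zero_matrix(self, tmp_path):
        _write_mtx(tmp_path, (3, 2), [], ["g1", "g2", "g3"], ["c1", "c2"])
        m = load_umi_matrix(tmp_path, "mtx_triplet")
        assert m.counts.shape == (3, 2) and m.counts.nnz == 0

    def test_features_tsv_v3_dialect(self, tmp_path):
        _write_mtx(tmp_path, (2, 1), [(1, 1, 3)], ["gx", "gy"], ["c1"])
        (tmp_path / "genes.tsv").unlink()
        (tmp_path / "features.tsv").write_text("gx\tGeneX\tGene Expression\ngy\tGeneY\tGene Expression\n")
        m = load_umi_matrix(tmp_path, "mtx_triplet")
        assert list(m.gene_ids) == ["gx", "gy"]

    @pytest.mark.parametrize("fmt", ["mtx_triplet", "dense_tsv", "hdf5"])
    def test_round_trip(self, tmp_path, fmt):
        m = random_count_matrix(50, 40, rng_seed=7)
        path = tmp_path / ("out" if fmt == "mtx_triplet" else f"out.{fmt}")
        write_umi_matrix(m, path, fmt)
        back = load_umi_matrix(path, fmt)
        assert list(back.gene_ids) == list(m.gene_ids)
        assert list(back.cell_ids) == list(m.cell_ids)
        assert (back.counts != m.counts).nnz == 0

    def test_malformed_header_raises(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text("not a matrix market header\n1 1 1\n")
        (tmp_path / "genes.tsv").write_text("g1\tg1\n")
        (tmp_path / "barcodes.tsv").write_text("c1\n")
        with pytest.raises(ParseError):
            load_umi_matrix(tmp_path, "mtx_triplet")

    def test_non_integer_counts_raise(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n2 2 1\n1 1 2.5\n"
        )
        (tmp_path / "genes.tsv").write_text("g1\tg1\ng2\tg2\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        with pytest.raises(ParseError, match="2.5"):
            load_umi_matrix(tmp_path, "mtx_triplet")

    def test_duplicate_gene_id_raises(self, tmp_path):
        _write_mtx(tmp_path, (2, 1), [(1, 1, 1)], ["dup", "dup"], ["c1"])
        with pytest.raises(ParseError, match="dup"):
            load_umi_matrix(tmp_path, "mtx_triplet")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ParameterError):
            load_umi_matrix(tmp_path, "parquet")


class TestInvariants:
    def test_totals_match_sums(self, small_matrix):
        dense = small_matrix.dense()
        assert np.array_equal(small_matrix.cell_totals, dense.sum(axis=0))
        assert np.array_equal(small_matrix.gene_totals, dense.sum(axis=1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(["g"], ["c"], sp.csr_matrix(np.array([[-1]])))


class TestFiltering:
    def _toy(self):
        # cells with totals 99, 100, 101
        counts = np.array([[50, 60, 70], [49, 40, 31]])
        return CountMatrix(["a", "b"], ["c1", "c2", "c3"], sp.csr_matrix(counts))

    def test_strict_less_than_boundary(self):
        m = filter_cells_and_genes(self._toy(), CellFilterParams(min_umi=100))
        # 99-total cell removed, exactly-100 cell retained
        assert list(m.cell_ids) == ["c2", "c3"]

    def test_max_umi_retains_equality(self):
        m = filter_cells_and_genes(self._toy(), CellFilterParams(min_umi=0, max_umi=100))
        assert list(m.cell_ids) == ["c1", "c2"]

    def test_blacklist_removal_recomputes_totals(self):
        # gene "big" carries 90% of c1's UMIs; removing it drops c1 below min_umi
        counts = np.array([[90, 5], [10, 95]])
        m = CountMatrix(["big", "small"], ["c1", "c2"], sp.csr_matrix(counts))
        out = filter_cells_and_genes(
            m, CellFilterParams(min_umi=50, gene_blacklist={"big"})
        )
        assert list(out.cell_ids) == ["c2"]
        assert list(out.gene_ids) == ["small"]

    def test_idempotence(self):
        p = CellFilterParams(min_umi=40, gene_blacklist={"a"})
        once = filter_cells_and_genes(self._toy(), p)
        twice = filter_cells_and_genes(once, p)
        assert list(twice.cell_ids) == list(once.cell_ids)
        assert (twice.counts != once.counts).nnz == 0

    def test_all_cells_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_cells_and_genes(self._toy(), CellFilterParams(min_umi=10_000))

    def test_invalid_window(self):
        with pytest.raises(ParameterError):
            CellFilterParams(min_umi=100, max_umi=100)


class TestDownsampling:
    def test_exact_totals_and_conservation(self, small_matrix):
        target = int(small_matrix.cell_totals.min())
        out = downsample_cells(small_matrix, target, rng_seed=3)
        assert np.all(out.cell_totals == target)
        sub = small_matrix.subset(cell_mask=np.isin(small_matrix.cell_ids, out.cell_ids))
        assert np.all(out.dense() <= sub.dense())

    def test_cell_at_target_unchanged(self):
        counts = np.array([[3], [7]])
        m = CountMatrix(["a", "b"], ["c"], sp.csr_matrix(counts))
        out = downsample_cells(m, 10, rng_seed=0)
        assert np.array_equal(out.dense(), counts)

    def test_cells_below_target_dropped(self):
        counts = np.array([[5, 20]])
        m = CountMatrix(["a"], ["c1", "c2"], sp.csr_matrix(counts))
        out = downsample_cells(m, 10, rng_seed=0)
        assert list(out.cell_ids) == ["c2"]

    def test_invalid_target(self, small_matrix):
        with pytest.raises(ParameterError):
            downsample_cells(small_matrix, 0, rng_seed=0)

    def test_hypergeometric_expectation(self):
        # cell (10, 10) down-sampled to 10: first gene ~ Hypergeom(20, 10, 10),
        # mean 5, var 10*0.5*0.5*(10/19)
        m = CountMatrix(["a", "b"], ["c"], sp.csr_matrix(np.array([[10], [10]])))
        n_rep = 2000
        draws = np.array(
            [downsample_cells(m, 10, rng_seed=s).dense()[0, 0] for s in range(n_rep)]
        )
        se = np.sqrt(10 * 0.25 * (10 / 19) / n_rep)
        assert abs(draws.mean() - 5.0) < 3 * se

    def test_reproducible(self, small_matrix):
        a = downsample_cells(small_matrix, 20, rng_seed=11)
        b = downsample_cells(small_matrix, 20, rng_seed=11)
        assert (a.counts != b.counts).nnz == 0


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), target=st.integers(1, 30))
def test_downsample_conservation_property(seed, target):
    """Down-sampled counts are coordinate-wise <= original and hit the target."""
    m = random_count_matrix(8, 6, rng_seed=seed, mean_count=3.0)
    if (m.cell_totals >= target).sum() == 0:
        return
    out = downsample_cells(m, target, rng_seed=seed)
    keep = np.isin(m.cell_ids, out.cell_ids)
    assert np.all(out.dense() <= m.dense()[:, keep])
    assert np.all(out.cell_totals == target)
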