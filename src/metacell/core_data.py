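"""UMI count-matrix container, readers/writers, filtering and down-sampling.

The package works on a genes x cells matrix of unique-molecular-identifier
(UMI) counts.  Every reader normalizes to that orientation; every stochastic
operation takes one explicit integer seed and uses ``numpy.random.default_rng``
(PCG64) -- global numpy state is never touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "CellFilterParams",
    "ParseError",
    "DataError",
    "EmptyResultError",
    "ParameterError",
    "load_umi_matrix",
    "write_umi_matrix",
    "filter_cells_and_genes",
    "downsample_cells",
]


class ParameterError(ValueError):
    """An operation was called with an invalid parameter value."""


class DataError(ValueError):
    """The input data violates an operation's contract."""


class ParseError(DataError):
    """A file does not conform to its declared dialect."""


class EmptyResultError(DataError):
    """A filtering step removed every cell (or gene)."""


def _as_str_array(ids: Iterable) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts.

    Attributes
    ----------
    gene_ids, cell_ids:
        Ordered, unique identifiers for rows and columns.
    counts:
        ``scipy.sparse.csr_matrix`` of shape (n_genes, n_cells), int64.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        data = self.counts.data
        if data.size:
            if not np.issubdtype(data.dtype, np.integer):
                if np.any(data != np.round(data)):
                    bad = np.argwhere(data != np.round(data))[0, 0]
                    raise ParseError(f"non-integer count value {data[bad]!r}")
            if data.min() < 0:
                raise DataError("negative count encountered")
        self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            uniq, cnt = np.unique(ids.astype(str), return_counts=True)
            if np.any(cnt > 1):
                raise ParseError(f"duplicated {name} identifier {uniq[cnt > 1][0]!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_totals(self) -> np.ndarray:
        """Per-cell total molecule count u_i (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    @property
    def gene_totals(self) -> np.ndarray:
        """Per-gene total molecule count u_g (row sums)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def subset(
        self,
        gene_mask: np.ndarray | None = None,
        cell_mask: np.ndarray | None = None,
    ) -> "CountMatrix":
        """Return a new matrix restricted to masked/indexed genes and cells."""
        m = self.counts
        gids, cids = self.gene_ids, self.cell_ids
        if gene_mask is not None:
            m = m[gene_mask, :]
            gids = gids[gene_mask]
        if cell_mask is not None:
            m = m[:, cell_mask]
            cids = cids[cell_mask]
        return CountMatrix(gids, cids, m.tocsr())

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given gene identifiers (raises on misses)."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lut[g] for g in gene_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - defensive
            raise DataError(f"unknown gene identifier {exc.args[0]!r}") from None


@dataclass
class CellFilterParams:
    """Cell/gene filtering thresholds.

    ``min_umi``/``max_umi`` follow the strict "less than" convention: a cell is
    removed when its (blacklist-corrected) total is strictly below ``min_umi``
    or strictly above ``max_umi``; equality retains.  ``max_umi=None`` means
    unbounded.  Blacklisted genes are removed *before* totals are recomputed.
    """

    min_umi: int = 0
    max_umi: int | None = None
    gene_blacklist: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.min_umi < 0:
            raise ParameterError("min_umi must be >= 0")
        if self.max_umi is not None and self.max_umi <= self.min_umi:
            raise ParameterError("max_umi must exceed min_umi when bounded")
        self.gene_blacklist = frozenset(self.gene_blacklist)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("mtx_triplet", "dense_tsv", "hdf5")


def load_umi_matrix(path: str | Path, format: str = "mtx_triplet") -> CountMatrix:
    """Load a UMI matrix from one of the supported on-disk dialects.

    ``mtx_triplet`` expects a 10x-style directory with ``matrix.mtx``,
    ``barcodes.tsv`` and either ``genes.tsv`` (v2, two columns) or
    ``features.tsv`` (v3, three columns).  ``dense_tsv`` is a genes-as-rows
    tab-separated table with a header of cell ids.  ``hdf5`` stores CSR arrays
    ``data/indices/indptr/shape`` plus ``gene_ids``/``cell_ids``.
    """
    path = Path(path)
    if format == "mtx_triplet":
        return _load_mtx(path)
    if format == "dense_tsv":
        return _load_dense_tsv(path)
    if format == "hdf5":
        return _load_hdf5(path)
    raise ParameterError(f"unknown format {format!r}; expected one of {_FORMATS}")


def write_umi_matrix(m: CountMatrix, path: str | Path, format: str = "mtx_triplet") -> None:
    """Write ``m`` so that :func:`load_umi_matrix` round-trips losslessly."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), m.counts.tocoo(), field="integer")
        with open(path / "genes.tsv", "w") as fh:
            for g in m.gene_ids:
                fh.write(f"{g}\t{g}\n")
        with open(path / "barcodes.tsv", "w") as fh:
            for c in m.cell_ids:
                fh.write(f"{c}\n")
    elif format == "dense_tsv":
        df = pd.DataFrame(m.dense(), index=m.gene_ids, columns=m.cell_ids)
        df.to_csv(path, sep="\t", index_label="gene")
    elif format == "hdf5":
        csr = m.counts.tocsr()
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=csr.data)
            fh.create_dataset("indices", data=csr.indices)
            fh.create_dataset("indptr", data=csr.indptr)
            fh.create_dataset("shape", data=np.asarray(csr.shape, dtype=np.int64))
            str_dt = h5py.string_dtype(encoding="utf-8")
            fh.create_dataset("gene_ids", data=[str(g) for g in m.gene_ids], dtype=str_dt)
            fh.create_dataset("cell_ids", data=[str(c) for c in m.cell_ids], dtype=str_dt)
    else:
        raise ParameterError(f"unknown format {format!r}; expected one of {_FORMATS}")


def _load_mtx(path: Path) -> CountMatrix:
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise ParseError(f"missing matrix.mtx under {path}")
    try:
        counts = scipy.io.mmread(str(mtx))
    except Exception as exc:
        raise ParseError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    genes_file = path / "genes.tsv"
    if not genes_file.exists():
        genes_file = path / "features.tsv"
    if not genes_file.exists():
        raise ParseError(f"missing genes.tsv/features.tsv under {path}")
    gene_ids = [line.split("\t")[0].strip() for line in _read_lines(genes_file)]
    barcodes = path / "barcodes.tsv"
    if not barcodes.exists():
        raise ParseError(f"missing barcodes.tsv under {path}")
    cell_ids = [line.strip() for line in _read_lines(barcodes)]
    counts = sp.csr_matrix(counts)
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise ParseError(
            f"matrix.mtx declares shape {counts.shape} but found "
            f"{len(gene_ids)} genes and {len(cell_ids)} barcodes"
        )
    return CountMatrix(gene_ids, cell_ids, counts)


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [ln for ln in fh.read().splitlines() if ln.strip()]


def _load_dense_tsv(path: Path) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"malformed dense TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"dense TSV {path} has no cell columns")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[0]
        raise ParseError(f"non-numeric counts in dense TSV {path} (column {bad!r})")
    return CountMatrix(df.index.to_numpy(), df.columns.to_numpy(), sp.csr_matrix(values))


def _load_hdf5(path: Path) -> CountMatrix:
    with h5py.File(path, "r") as fh:
        for key in ("data", "indices", "indptr", "shape", "gene_ids", "cell_ids"):
            if key not in fh:
                raise ParseError(f"HDF5 file {path} lacks dataset {key!r}")
        shape = tuple(int(x) for x in fh["shape"][:])
        counts = sp.csr_matrix(
            (fh["data"][:], fh["indices"][:], fh["indptr"][:]), shape=shape
        )
        gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in fh["gene_ids"][:]]
        cell_ids = [c.decode() if isinstance(c, bytes) else str(c) for c in fh["cell_ids"][:]]
    return CountMatrix(gene_ids, cell_ids, counts)


# ---------------------------------------------------------------------------
# Filtering and down-sampling
# ---------------------------------------------------------------------------

def filter_cells_and_genes(m: CountMatrix, p: CellFilterParams) -> CountMatrix:
    """Remove blacklisted genes, then cells outside the total-UMI window.

    Totals are recomputed after the blacklist is applied, so removing a gene
    that dominates a cell's library can push that cell below ``min_umi``.
    """
    keep_genes = np.array([g not in p.gene_blacklist for g in m.gene_ids], dtype=bool)
    out = m.subset(gene_mask=keep_genes) if not keep_genes.all() else m
    totals = out.cell_totals
    keep_cells = totals >= p.min_umi
    if p.max_umi is not None:
        keep_cells &= totals <= p.max_umi
    if not keep_cells.any():
        raise EmptyResultError(
            f"all {m.n_cells} cells removed by UMI window "
            f"[{p.min_umi}, {p.max_umi if p.max_umi is not None else 'inf'}]"
        )
    if keep_cells.all() and keep_genes.all():
        return m
    return out.subset(cell_mask=keep_cells)


def downsample_cells(m: CountMatrix, target: int, rng_seed: int) -> CountMatrix:
    """Down-sample every cell to exactly ``target`` UMIs without replacement.

    Cells whose total is below ``target`` are dropped; cells already at
    ``target`` pass through unchanged.  Per-gene counts follow multivariate
    hypergeometric sampling of the cell's molecules.
    """
    if target <= 0:
        raise ParameterError("down-sampling target must be positive")
    totals = m.cell_totals
    keep = totals >= target
    if not keep.any():
        raise EmptyResultError(f"no cell has at least {target} UMIs")
    sub = m.subset(cell_mask=keep)
    rng = np.random.default_rng(rng_seed)
    csc = sub.counts.tocsc()
    data = csc.data.copy()
    for j in range(sub.n_cells):
        lo, hi = csc.indptr[j], csc.indptr[j + 1]
        col = data[lo:hi]
        tot = int(col.sum())
        if tot > target:
            data[lo:hi] = rng.multivariate_hypergeometric(col, target, method="marginals")
    out = sp.csc_matrix((data, csc.indices.copy(), csc.indptr.copy()), shape=csc.shape)
    out.eliminate_zeros()
    return CountMatrix(sub.gene_ids, sub.cell_ids, out.tocsr())
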