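"""Raw similarities, rank transform, and the balanced directed K-nn graph.

Counts on feature genes are log-transformed (log2(eps + u)), cells are
correlated (Pearson), and each row of the similarity matrix is converted to
descending ranks (rank 1 = most similar; ties broken toward the lower cell
index; self-similarity excluded).  The rank matrix S is then *balanced* in
three steps:

    s1_ij = max(alpha*K^2 - s_ij * s_ji, 0)          (rank-product symmetrization)
    s2_ij = max(beta*K  - rank_col_j(s1_ij), 0)      (<= beta*K incoming edges)
    a_ij  = max(K       - rank_row_i(s2_ij), 0)      (<= K outgoing edges)

where the step-2/step-3 rankings run over strictly positive entries only
(zero entries are already-deleted edges and never receive a rank).  The
resulting weighted directed graph bounds both out- and in-degree, which stops
outlier cells from attaching themselves to large homogeneous populations.
Nodes may legitimately end up with degree below K or fully isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .core_data import CountMatrix, DataError, ParameterError, downsample_cells
from .features import FeatureSet

__all__ = [
    "GraphParams",
    "BalancedGraph",
    "log_transform",
    "raw_similarity",
    "rank_rows",
    "balance",
    "build_balanced_graph",
]

log = logging.getLogger(__name__)


@dataclass
class GraphParams:
    K: int = 100
    alpha: float = 10.0
    beta: float = 3.0
    log_eps: float = 1.0
    downsample_before_corr: bool = False

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ParameterError("K must be >= 2")
        if self.alpha * self.K**2 <= 1:
            raise ParameterError("alpha * K^2 must exceed 1")
        if self.beta * self.K < 1:
            raise ParameterError("beta * K must be >= 1")
        if self.log_eps <= 0:
            raise ParameterError("log_eps must be positive")


@dataclass
class BalancedGraph:
    """Directed weighted cell graph with bounded out-degree.

    ``adjacency`` holds the integer weights a_ij (CSR, cells x cells);
    ``s1``/``s2`` retain the balancing intermediates for testing.
    """

    adjacency: sp.csr_matrix
    s1: np.ndarray | None = None
    s2: np.ndarray | None = None
    cell_ids: np.ndarray | None = None
    _csc: sp.csc_matrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        self.adjacency.eliminate_zeros()

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def csc(self) -> sp.csc_matrix:
        if self._csc is None:
            self._csc = self.adjacency.tocsc()
        return self._csc

    def out_degrees(self) -> np.ndarray:
        return np.diff(self.adjacency.indptr)

    def in_degrees(self) -> np.ndarray:
        return np.diff(self.csc.indptr)

    def write_edges(self, path: str | Path) -> None:
        """3-column edge list TSV: source, target, weight."""
        coo = self.adjacency.tocoo()
        ids = self.cell_ids
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                si = ids[i] if ids is not None else i
                sj = ids[j] if ids is not None else j
                fh.write(f"{si}\t{sj}\t{w}\n")


def log_transform(m: CountMatrix, f: FeatureSet | np.ndarray, eps: float = 1.0) -> np.ndarray:
    """log2(eps + u) on feature genes; returns features x cells floats."""
    if eps <= 0:
        raise ParameterError("eps must be positive")
    gene_ids = f.gene_ids if isinstance(f, FeatureSet) else np.asarray(f, dtype=object)
    idx = m.gene_index(gene_ids)
    sub = m.counts[idx, :].toarray().astype(float)
    return np.log2(eps + sub)


def raw_similarity(
    m: CountMatrix,
    f: FeatureSet | np.ndarray,
    p: GraphParams | None = None,
    rng_seed: int = 0,
) -> np.ndarray:
    """Pearson correlations between cells on log-transformed feature counts.

    With ``downsample_before_corr`` set, cells are first down-sampled to the
    minimum cell depth to remove the depth-accuracy bias; otherwise raw counts
    are used (preferred when depths are highly variable).  Cells with zero
    variance across features get similarity 0 to every other cell.
    """
    p = p or GraphParams()
    if p.downsample_before_corr:
        target = int(m.cell_totals.min())
        m = downsample_cells(m, max(target, 1), rng_seed=rng_seed)
    t = log_transform(m, f, p.log_eps)
    if t.shape[0] < 2:
        raise DataError("need at least 2 feature genes for correlations")
    sd = t.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(t, rowvar=False)
    if degenerate.any():
        log.warning("%d cells have zero variance across features", int(degenerate.sum()))
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)


def rank_rows(r: np.ndarray) -> np.ndarray:
    """Per-row descending ranks of off-diagonal similarities.

    Rank 1 is the most similar neighbor; ties resolve toward the lower cell
    index (stable sort); the diagonal is excluded and reported as 0.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    if r.shape[0] != r.shape[1]:
        raise DataError("similarity matrix must be square")
    work = r.copy()
    np.fill_diagonal(work, -np.inf)  # sorts last, never ranked
    order = np.argsort(-work, axis=1, kind="stable")
    s = np.zeros((n, n), dtype=np.int64)
    ranks = np.arange(1, n + 1, dtype=np.int64)
    np.put_along_axis(s, order, ranks[None, :], axis=1)
    np.fill_diagonal(s, 0)
    return s


def _positive_ranks(x: np.ndarray, axis: int) -> np.ndarray:
    """Descending 1-based ranks along ``axis`` restricted to positive entries.

    Non-positive entries receive rank n+1 (so any cap subtracts to <= 0)."""
    n = x.shape[axis]
    order = np.argsort(-x, axis=axis, kind="stable")
    ranks = np.empty_like(x, dtype=np.int64)
    seq = np.arange(1, n + 1, dtype=np.int64)
    shape = [1, 1]
    shape[axis] = n
    np.put_along_axis(ranks, order, seq.reshape(shape), axis=axis)
    return np.where(x > 0, ranks, n + 1)


def balance(s: np.ndarray, p: GraphParams) -> BalancedGraph:
    """Three-step degree balancing of a rank matrix (see module docstring)."""
    s = np.asarray(s, dtype=np.int64)
    n = s.shape[0]
    prod = s * s.T
    s1 = np.maximum(p.alpha * p.K**2 - prod, 0.0)
    np.fill_diagonal(s1, 0.0)

    col_rank = _positive_ranks(s1, axis=0)  # rank within incoming edges of each node
    s2 = np.where(s1 > 0, np.maximum(p.beta * p.K - col_rank, 0.0), 0.0)

    row_rank = _positive_ranks(s2, axis=1)  # rank within outgoing edges of each node
    a = np.where(s2 > 0, np.maximum(p.K - row_rank, 0), 0).astype(np.int64)

    return BalancedGraph(sp.csr_matrix(a), s1=s1, s2=s2)


def build_balanced_graph(
    m: CountMatrix,
    f: FeatureSet | np.ndarray,
    p: GraphParams | None = None,
    rng_seed: int = 0,
) -> BalancedGraph:
    """Convenience: similarity -> ranks -> balance, carrying cell ids along."""
    p = p or GraphParams()
    r = raw_similarity(m, f, p, rng_seed=rng_seed)
    g = balance(rank_rows(r), p)
    g.cell_ids = m.cell_ids
    return g
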