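"""Parametric outlier filtering and homogeneity-based metacell splitting.

A metacell is meant to behave like repeated multinomial sampling from one RNA
pool.  Two refinement passes enforce that heuristically:

* cells whose observed count of some gene exceeds the metacell's pooled
  expectation by a regularized fold factor

      f_gi = log2((1 + u_gi) / (1 + u_i * p_g,mc(i)))  >=  t_lfc

  are moved to the outlier set (the +1 regularization keeps very low-count
  genes from triggering; e.g. f cannot exceed 2 when u_gi <= 3);
* metacells hiding two separated states are detected by clustering their
  cells de novo (DBSCAN on correlation distances over genes with intra-MC
  variance/mean > 1.2 on depth-equalized counts) and split when more than one
  cluster emerges.

The result is a :class:`MetacellCover`: disjoint metacells plus an outlier
set whose union is exactly the input cell set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .core_data import CountMatrix, DataError, ParameterError, downsample_cells
from .partition import Assignment

__all__ = [
    "OutlierParams",
    "SplitParams",
    "MetacellCover",
    "pool_frequencies",
    "outlier_fold",
    "filter_outliers",
    "split_heterogeneous",
]

log = logging.getLogger(__name__)

OUTLIER_SMALL_COMPONENT = "small_component"
OUTLIER_PARAMETRIC = "parametric"


@dataclass
class OutlierParams:
    """t_lfc: log2 fold threshold on f_gi (3 = "8-fold or more")."""

    t_lfc: float = 3.0

    def __post_init__(self) -> None:
        if self.t_lfc <= 0:
            raise ParameterError("t_lfc must be positive")


@dataclass
class SplitParams:
    var_mean_min: float = 1.2
    dbscan_eps: float | None = None  # default: 1 - q90 of intra-MC correlations
    dbscan_min_pts: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.var_mean_min <= 0:
            raise ParameterError("var_mean_min must be positive")
        if self.dbscan_min_pts < 2:
            raise ParameterError("dbscan_min_pts must be >= 2")


@dataclass
class MetacellCover:
    """Disjoint metacells M_k plus outliers; the union covers all cells.

    ``mc`` holds the per-cell label (-1 = outlier); ``outlier_kind`` records
    each outlier's provenance (small graph component vs parametric filter).
    """

    mc: np.ndarray
    outlier_kind: np.ndarray  # dtype=object; None for assigned cells

    def __post_init__(self) -> None:
        self.mc = np.asarray(self.mc, dtype=np.int64)
        self.outlier_kind = np.asarray(self.outlier_kind, dtype=object)
        if self.mc.shape != self.outlier_kind.shape:
            raise DataError("mc and outlier_kind must be parallel arrays")
        if np.any((self.mc < 0) != np.array([k is not None for k in self.outlier_kind])):
            raise DataError("outlier provenance inconsistent with labels")

    @classmethod
    def from_assignment(cls, a: Assignment) -> "MetacellCover":
        kind = np.array(
            [OUTLIER_SMALL_COMPONENT if k < 0 else None for k in a.mc], dtype=object
        )
        return cls(a.mc.copy(), kind)

    @property
    def n_mc(self) -> int:
        return int(self.mc.max()) + 1 if (self.mc >= 0).any() else 0

    @property
    def outlier_mask(self) -> np.ndarray:
        return self.mc < 0

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.mc == k)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.mc[self.mc >= 0], minlength=self.n_mc)

    def drop_metacell(self, k: int, reason: str = "manual") -> "MetacellCover":
        """Manual curation hook: move a whole metacell to the outlier set."""
        if k < 0 or k >= self.n_mc:
            raise ParameterError(f"no metacell {k}")
        mc = self.mc.copy()
        kind = self.outlier_kind.copy()
        sel = mc == k
        mc[sel] = -1
        kind[sel] = reason
        mc[mc > k] -= 1  # compact labels
        return MetacellCover(mc, kind)

    def export(self, path, cell_ids=None) -> None:
        with open(path, "w") as fh:
            fh.write("cell\tmetacell\toutlier_kind\n")
            for i, k in enumerate(self.mc):
                cid = cell_ids[i] if cell_ids is not None else i
                fh.write(f"{cid}\t{k}\t{self.outlier_kind[i] or ''}\n")


def pool_frequencies(m: CountMatrix, a: Assignment | MetacellCover) -> np.ndarray:
    """Pooled gene frequencies p_gk = sum_i u_gi / sum_i u_i per metacell.

    Returns a dense genes x n_mc array; every column sums to 1.
    """
    n_mc = a.n_mc
    if n_mc == 0:
        raise DataError("assignment has no metacells")
    sizes = np.bincount(a.mc[a.mc >= 0], minlength=n_mc)
    if np.any(sizes == 0):
        raise DataError(f"empty metacell {int(np.flatnonzero(sizes == 0)[0])}")
    X = m.dense()
    p = np.empty((m.n_genes, n_mc), dtype=float)
    for k in range(n_mc):
        mem = np.flatnonzero(a.mc == k)
        pooled = X[:, mem].sum(axis=1)
        p[:, k] = pooled / pooled.sum()
    return p


def outlier_fold(m: CountMatrix, p: np.ndarray, a: Assignment | MetacellCover) -> np.ndarray:
    """Regularized observed/expected fold f_gi for every assigned cell.

    Unassigned cells get NaN columns.
    """
    X = m.dense().astype(float)
    depths = m.cell_totals.astype(float)
    f = np.full(X.shape, np.nan)
    assigned = np.flatnonzero(a.mc >= 0)
    expected = 1.0 + depths[assigned] * p[:, a.mc[assigned]]
    f[:, assigned] = np.log2((1.0 + X[:, assigned]) / expected)
    return f


def filter_outliers(
    f: np.ndarray,
    p: OutlierParams,
    a: Assignment | MetacellCover,
) -> tuple[MetacellCover, pd.DataFrame]:
    """Move cells with any f_gi >= t_lfc (inclusive) into the outlier set.

    Pool frequencies are *not* recomputed iteratively -- this is a single
    heuristic pass against the cover it was handed.  Returns the refined
    cover plus a report of flagged cells (cell index, metacell, top offending
    gene index, its f value).  Metacells emptied by the filter are dropped
    with a warning.
    """
    if isinstance(a, Assignment):
        cover = MetacellCover.from_assignment(a)
    else:
        cover = MetacellCover(a.mc.copy(), a.outlier_kind.copy())
    with np.errstate(invalid="ignore"):
        hits = np.nan_to_num(f, nan=-np.inf) >= p.t_lfc
    flagged = np.flatnonzero(hits.any(axis=0) & (cover.mc >= 0))
    rows = []
    mc = cover.mc.copy()
    kind = cover.outlier_kind.copy()
    for i in flagged:
        g = int(np.nanargmax(f[:, i]))
        rows.append({"cell": int(i), "metacell": int(mc[i]), "gene": g, "f": float(f[g, i])})
        mc[i] = -1
        kind[i] = OUTLIER_PARAMETRIC
    report = pd.DataFrame(rows, columns=["cell", "metacell", "gene", "f"])
    # drop emptied metacells, preserving label order
    n_mc = cover.n_mc
    sizes = np.bincount(mc[mc >= 0], minlength=n_mc)
    if np.any(sizes == 0):
        for k in np.flatnonzero(sizes == 0):
            log.warning("metacell %d emptied by outlier filtering; dropped", int(k))
        lut = -np.ones(n_mc, dtype=np.int64)
        lut[sizes > 0] = np.arange(int((sizes > 0).sum()))
        mc = np.where(mc >= 0, lut[np.maximum(mc, 0)], -1)
    return MetacellCover(mc, kind), report


def split_heterogeneous(
    m: CountMatrix,
    a: Assignment | MetacellCover,
    sp_: SplitParams,
) -> MetacellCover:
    """Split metacells that hide more than one density cluster.

    Per metacell with at least ``dbscan_min_pts`` cells: down-sample members
    to their minimum depth, keep genes with variance/mean > ``var_mean_min``,
    compute correlation distances on log2(1+u), and run DBSCAN (eps defaults
    to 1 - q90 of the intra-metacell correlations).  With more than one
    cluster the metacell is split; DBSCAN noise points stay with the largest
    cluster so the union of cells never changes.
    """
    if isinstance(a, Assignment):
        cover = MetacellCover.from_assignment(a)
    else:
        cover = MetacellCover(a.mc.copy(), a.outlier_kind.copy())
    mc = cover.mc.copy()
    next_label = cover.n_mc
    for k in range(cover.n_mc):
        mem = np.flatnonzero(mc == k)
        if mem.size < sp_.dbscan_min_pts:
            continue
        sub = m.subset(cell_mask=mem)
        target = int(sub.cell_totals.min())
        ds = downsample_cells(sub, max(target, 1), rng_seed=sp_.rng_seed).dense().astype(float)
        mu = ds.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vm = np.where(mu > 0, ds.var(axis=1, ddof=1) / np.maximum(mu, 1e-300), 0.0)
        genes = vm > sp_.var_mean_min
        if genes.sum() < 2:
            continue
        t = np.log2(1.0 + ds[genes, :])
        sd = t.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(t, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        if sp_.dbscan_eps is not None:
            eps = sp_.dbscan_eps
        else:
            off = corr[~np.eye(len(mem), dtype=bool)]
            eps = float(np.clip(1.0 - np.quantile(off, 0.9), 1e-6, 2.0))
        labels = DBSCAN(eps=eps, min_samples=sp_.dbscan_min_pts, metric="precomputed").fit(
            dist
        ).labels_
        clusters = np.unique(labels[labels >= 0])
        if clusters.size <= 1:
            continue
        counts = np.array([(labels == c).sum() for c in clusters])
        largest = clusters[int(np.argmax(counts))]
        labels[labels < 0] = largest  # noise joins the largest cluster
        # first cluster keeps label k, the rest get fresh labels
        for ci, c in enumerate(clusters):
            sel = mem[labels == c]
            if ci == 0:
                mc[sel] = k
            else:
                mc[sel] = next_label
                next_label += 1
        log.info("metacell %d split into %d clusters", k, clusters.size)
    out = MetacellCover(mc, cover.outlier_kind.copy())
    # compact in case splitting reordered labels sparsely (it does not drop any)
    return out
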