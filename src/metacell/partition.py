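"""Seeded dense-subgraph partitioning of a weighted directed cell graph.

The partitioner is a graph adaptation of k-means.  Seeding repeatedly samples
a seed cell among uncovered cells with probability proportional to the cube
of its cover-free score f(i) = |N_out(i) - C| (out-neighbors not yet covered)
and claims the seed plus its uncovered out-neighbors, until no uncovered cell
has more than ``size_min`` uncovered neighbors.  Optimization then sweeps
cells in a reshuffled order each pass and reassigns each cell to the subgraph
maximizing

    w_ik = wi_ik * wo_ik / |M_k|^2

with wo/wi the summed outgoing/incoming edge weights into M_k.  To force
convergence the score of a cell's current subgraph is multiplied by a factor
that grows geometrically with the pass number.  Cells left unassigned at the
end (typically cells in connected components smaller than ``size_min`` that
never received a seed or an assigned neighbor) are outliers.

Both stages touch each edge O(1) times per pass, so a pass is linear in the
number of edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .core_data import DataError, ParameterError
from .balanced_graph import BalancedGraph

__all__ = ["PartitionParams", "Assignment", "seed", "optimize", "partition_graph"]


@dataclass
class PartitionParams:
    size_min: int = 25
    max_passes: int = 50
    stickiness_increment: float = 1.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.size_min < 1:
            raise ParameterError("size_min must be >= 1")
        if self.stickiness_increment < 1.0:
            raise ParameterError("stickiness_increment must be >= 1")
        if self.max_passes < 1:
            raise ParameterError("max_passes must be >= 1")

    @classmethod
    def for_K(cls, K: int, **kw) -> "PartitionParams":
        """Default size_min = K/4 (at least 1)."""
        return cls(size_min=max(1, K // 4), **kw)


@dataclass
class Assignment:
    """Per-cell subgraph labels; -1 marks unassigned/outlier cells."""

    mc: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.mc = np.asarray(self.mc, dtype=np.int64)

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

    def compact(self) -> "Assignment":
        """Drop empty subgraphs and relabel densely, preserving label order."""
        used = np.unique(self.mc[self.mc >= 0])
        lut = -np.ones(self.n_mc + 1, dtype=np.int64)
        lut[used] = np.arange(len(used))
        mc = np.where(self.mc >= 0, lut[np.maximum(self.mc, 0)], -1)
        return Assignment(mc, self.converged)

    def export(self, path, cell_ids=None) -> None:
        with open(path, "w") as fh:
            fh.write("cell\tmetacell\n")
            for i, k in enumerate(self.mc):
                cid = cell_ids[i] if cell_ids is not None else i
                fh.write(f"{cid}\t{k}\n")


def _adjacency(g) -> sp.csr_matrix:
    return g.adjacency if isinstance(g, BalancedGraph) else sp.csr_matrix(g)


def seed(g: BalancedGraph | sp.spmatrix, p: PartitionParams) -> Assignment:
    """Cover-free weighted seeding; returns a partial assignment (-1 = uncovered).

    The stop rule evaluates max f(i) over *uncovered* cells: seeds are sampled
    from I - C, so scores of already-covered cells cannot produce new seeds.
    """
    adj = _adjacency(g)
    n = adj.shape[0]
    if n < p.size_min:
        return Assignment(-np.ones(n, dtype=np.int64))
    csc = adj.tocsc()
    rng = np.random.default_rng(p.rng_seed)
    mc = -np.ones(n, dtype=np.int64)
    covered = np.zeros(n, dtype=bool)
    f = np.diff(adj.indptr).astype(np.int64)  # |N_out(i)|, C empty
    k = 0
    while True:
        unc = np.flatnonzero(~covered)
        if unc.size == 0:
            break
        fu = f[unc].astype(float)
        if fu.max() <= p.size_min:
            break
        w = fu**3
        j = int(rng.choice(unc, p=w / w.sum()))
        out_j = adj.indices[adj.indptr[j] : adj.indptr[j + 1]]
        members = np.concatenate(([j], out_j[~covered[out_j]]))
        members = np.unique(members)
        mc[members] = k
        covered[members] = True
        # every in-neighbor of a newly covered node loses one uncovered out-neighbor
        for v in members:
            in_v = csc.indices[csc.indptr[v] : csc.indptr[v + 1]]
            f[in_v] -= 1
        k += 1
    return Assignment(mc)


def optimize(
    g: BalancedGraph | sp.spmatrix,
    a: Assignment,
    p: PartitionParams,
) -> Assignment:
    """Sweep-based association optimization of a seeded assignment.

    Cells are visited in a seeded random permutation, reshuffled each pass;
    weights update after every reassignment (asynchronous sweeps).  Ties break
    toward the current subgraph, then the lowest subgraph index.  When every
    product score w_ik is zero the cell falls back to the additive score
    wi + wo, which lets cells with single-direction connectivity join their
    neighbors' subgraph instead of being stranded.
    """
    adj = _adjacency(g)
    n = adj.shape[0]
    mc = a.mc.copy()
    n_mc = a.n_mc
    if n_mc == 0:
        raise DataError("optimize requires at least one seeded subgraph")
    csc = adj.tocsc()
    out_ind, out_ptr, out_w = adj.indices, adj.indptr, adj.data.astype(float)
    in_ind, in_ptr, in_w = csc.indices, csc.indptr, csc.data.astype(float)
    sizes = np.bincount(mc[mc >= 0], minlength=n_mc).astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([p.rng_seed, 0x5EED]))
    converged = False
    for pass_i in range(p.max_passes):
        factor = p.stickiness_increment ** (pass_i + 1)
        order = rng.permutation(n)
        changed = 0
        for i in order:
            cur = mc[i]
            o_nb = out_ind[out_ptr[i] : out_ptr[i + 1]]
            o_wt = out_w[out_ptr[i] : out_ptr[i + 1]]
            i_nb = in_ind[in_ptr[i] : in_ptr[i + 1]]
            i_wt = in_w[in_ptr[i] : in_ptr[i + 1]]
            lo = mc[o_nb]
            li = mc[i_nb]
            mo = lo >= 0
            mi = li >= 0
            wo = np.bincount(lo[mo], weights=o_wt[mo], minlength=n_mc)
            wi = np.bincount(li[mi], weights=i_wt[mi], minlength=n_mc)
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(sizes > 0, wi * wo / np.square(np.maximum(sizes, 1.0)), 0.0)
            if cur >= 0:
                w[cur] *= factor
            best = int(np.argmax(w))
            if w[best] <= 0.0:
                w = np.where(sizes > 0, wi + wo, 0.0)
                if cur >= 0:
                    w[cur] *= factor
                best = int(np.argmax(w))
                if w[best] <= 0.0:
                    continue  # no assigned neighbors anywhere yet
            if cur >= 0 and w[cur] >= w[best]:
                best = cur
            if best != cur:
                if cur >= 0:
                    sizes[cur] -= 1
                sizes[best] += 1
                mc[i] = best
                changed += 1
        if changed == 0:
            converged = True
            break
    return Assignment(mc, converged).compact()


def partition_graph(g: BalancedGraph | sp.spmatrix, p: PartitionParams) -> Assignment:
    """Seed then optimize; seeding and sweep order use streams derived from
    ``p.rng_seed`` so the full partition is reproducible from one integer."""
    seeded = seed(g, p)
    if seeded.n_mc == 0:
        return seeded
    return optimize(g, seeded, p)
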