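"""Bootstrap resampling of graph partitions and the co-occurrence consensus.

Single runs of the randomized partitioner are noisy; the consensus stage
resamples the balanced graph ``n_boot`` times (each cell kept independently
with probability ``rho``), partitions every induced subgraph, and tallies for
each cell pair how often it was co-sampled (o_ij) and co-assigned (c_ij).
The co-occurrence frequency s_boot = c/o replaces the original correlation
structure: a new undirected graph G_boot keeps pair (i, j) when s_boot
exceeds half the larger of the two cells' K_core-th best frequencies, and the
final metacell partition re-runs the same partitioner on G_boot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .core_data import DataError, ParameterError
from .balanced_graph import BalancedGraph
from .partition import Assignment, PartitionParams, partition_graph

__all__ = [
    "ResampleParams",
    "CoocStats",
    "CoocGraphParams",
    "resample_partitions",
    "cooc_graph",
    "final_partition",
    "consensus_partition",
]

log = logging.getLogger(__name__)


@dataclass
class ResampleParams:
    n_boot: int = 500
    rho: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 0:
            raise ParameterError("n_boot must be >= 0 (0 disables the consensus stage)")
        if not 0.0 < self.rho <= 1.0:
            raise ParameterError("rho must lie in (0, 1]")


@dataclass
class CoocGraphParams:
    k_core: int = 30
    threshold_factor: float = 0.5
    partition: PartitionParams | None = None  # params for the final partition

    def __post_init__(self) -> None:
        if self.k_core < 1:
            raise ParameterError("k_core must be >= 1")
        if not 0.0 < self.threshold_factor <= 1.0:
            raise ParameterError("threshold_factor must lie in (0, 1]")


@dataclass
class CoocStats:
    """Symmetric resample tallies: o (co-sampled), c (co-assigned)."""

    o: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o)
        self.c = np.asarray(self.c)
        if np.any(self.c > self.o):
            raise DataError("co-assignment count exceeds co-sampling count")

    @property
    def s_boot(self) -> np.ndarray:
        """c/o where o > 0, else 0 (never-co-sampled pairs carry no evidence).
        The diagonal is forced to 0 -- self-pairs are excluded downstream."""
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(self.o > 0, self.c / np.maximum(self.o, 1), 0.0)
        np.fill_diagonal(s, 0.0)
        return s

    def export(self, path) -> None:
        """Sparse triplet TSV of pairs with o > 0: i, j, o, c (upper triangle)."""
        iu, ju = np.triu_indices_from(self.o, k=1)
        mask = self.o[iu, ju] > 0
        with open(path, "w") as fh:
            fh.write("i\tj\to\tc\n")
            for i, j in zip(iu[mask], ju[mask]):
                fh.write(f"{i}\t{j}\t{self.o[i, j]}\t{self.c[i, j]}\n")


def resample_partitions(
    g: BalancedGraph,
    bp: PartitionParams,
    rp: ResampleParams,
) -> CoocStats:
    """Tally co-sampling and co-assignment over ``rp.n_boot`` resamples.

    Per-resample RNG streams are spawned deterministically from
    ``rp.rng_seed``, so two runs with the same seed agree exactly and the
    tallies are independent of execution order (they are plain sums).
    Resamples drawing fewer than ``bp.size_min`` cells are skipped.
    """
    if rp.n_boot < 1:
        raise ParameterError("resampling requires n_boot >= 1")
    adj = g.adjacency
    n = adj.shape[0]
    o = np.zeros((n, n), dtype=np.int32)
    c = np.zeros((n, n), dtype=np.int32)
    children = np.random.SeedSequence(rp.rng_seed).spawn(rp.n_boot)
    for b in range(rp.n_boot):
        rng = np.random.default_rng(children[b])
        include = rng.random(n) < rp.rho
        idx = np.flatnonzero(include)
        if idx.size < bp.size_min:
            log.warning("resample %d drew %d < size_min cells; skipped", b, idx.size)
            continue
        sub = adj[np.ix_(idx, idx)].tocsr()
        bp_b = replace(bp, rng_seed=int(rng.integers(0, 2**31)))
        labels = partition_graph(sub, bp_b).mc
        o[np.ix_(idx, idx)] += 1
        for k in range(labels.max() + 1 if labels.size else 0):
            mem = idx[labels == k]
            if mem.size:
                c[np.ix_(mem, mem)] += 1
    return CoocStats(o, c)


def cooc_graph(s: CoocStats, p: CoocGraphParams) -> sp.csr_matrix:
    """Threshold co-occurrence frequencies into the undirected graph G_boot.

    T_i is the ``k_core``-th largest off-diagonal s_boot value in row i (its
    smallest positive value when fewer than ``k_core`` positives exist); the
    pair (i, j) becomes an edge iff s_boot_ij > max(T_i, T_j) * factor.
    Returned as a symmetric 0/1 CSR matrix (each undirected edge as two unit
    arcs) ready for the partitioner.  Degrees are intentionally uncapped.
    """
    sb = s.s_boot
    n = sb.shape[0]
    t = np.zeros(n)
    for i in range(n):
        row = sb[i]
        pos = row[row > 0]
        if pos.size == 0:
            t[i] = 0.0
        elif pos.size < p.k_core:
            t[i] = pos.min()
        else:
            t[i] = np.sort(pos)[::-1][p.k_core - 1]
    thresh = np.maximum.outer(t, t) * p.threshold_factor
    edges = sb > thresh
    np.fill_diagonal(edges, False)
    edges &= edges.T  # sb symmetric => already symmetric; defensive
    return sp.csr_matrix(edges.astype(np.int64))


def final_partition(g_boot: sp.spmatrix, p: PartitionParams) -> Assignment:
    """Re-apply the seeded partitioner to G_boot; -1 labels are outliers."""
    g_boot = sp.csr_matrix(g_boot)
    if g_boot.shape[0] == 0:
        raise DataError("G_boot is empty")
    return partition_graph(g_boot, p)


def consensus_partition(
    g: BalancedGraph,
    bp: PartitionParams,
    rp: ResampleParams,
    cp: CoocGraphParams,
) -> tuple[Assignment, CoocStats]:
    """Resample -> co-occurrence graph -> final partition."""
    stats = resample_partitions(g, bp, rp)
    gb = cooc_graph(stats, cp)
    fp = cp.partition or bp
    return final_partition(gb, fp), stats
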