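"""Metacell-regularized force-directed 2D projection.

Instead of embedding the full cell graph, the balanced graph's edges are
projected onto metacell pairs:

    b_ml = K^2 / (|M_m| * |M_l|) * sum_{i in M_m, j in M_l} ceil(a_ij / C)

with C the median metacell size.  B is symmetrized into B' (sum of its
row- and column-normalized forms), pairs with b' above a threshold become
candidate edges, and each metacell keeps its D best candidates.  The small
metacell graph G_M is embedded with a standard force-directed (spring)
layout; cells are then placed at the average position of their balanced-graph
neighbors' metacells, using only neighbors whose metacell pair is an edge (or
the identity) in G_M -- which regularizes the cloud without collapsing cells
onto their metacell centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import DataError, ParameterError
from .balanced_graph import BalancedGraph
from .partition import Assignment
from .refine import MetacellCover

__all__ = [
    "LayoutParams",
    "Layout",
    "mc_edge_matrix",
    "build_mc_graph",
    "layout_mcs",
    "position_cells",
    "compute_layout",
]


@dataclass
class LayoutParams:
    t_edge: float = 0.08
    d_max: int = 4
    rng_seed: int = 0
    iterations: int = 500

    def __post_init__(self) -> None:
        if self.d_max < 1:
            raise ParameterError("d_max must be >= 1")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")


@dataclass
class Layout:
    """Per-metacell and per-cell 2D coordinates.

    ``cell_coords`` rows are NaN-free; outlier cells without a surviving
    anchor are omitted and listed in ``unplaced``.
    """

    mc_coords: np.ndarray  # (n_mc, 2)
    cell_coords: pd.DataFrame  # index: cell position index; columns x, y, metacell
    unplaced: np.ndarray

    def export(self, path, cell_ids=None) -> None:
        with open(path, "w") as fh:
            fh.write("id\tx\ty\tkind\n")
            for k, (x, y) in enumerate(self.mc_coords):
                fh.write(f"mc{k}\t{x:.6g}\t{y:.6g}\tmc\n")
            for i, row in self.cell_coords.iterrows():
                cid = cell_ids[i] if cell_ids is not None else i
                fh.write(f"{cid}\t{row.x:.6g}\t{row.y:.6g}\tcell\n")


def mc_edge_matrix(
    g: BalancedGraph, cover: MetacellCover | Assignment, K: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project balanced-graph edges onto metacell pairs; returns (B, B').

    ``K`` defaults to (max edge weight + 1), which recovers the graph's
    out-degree cap since the best-ranked edge carries weight K-1.  B' is the
    sum of the row-normalized and column-normalized forms of B (zero
    rows/columns stay zero).
    """
    n_mc = cover.n_mc
    if n_mc == 0:
        raise DataError("cover has no metacells")
    sizes = cover.sizes().astype(float)
    c_scale = float(np.median(sizes))
    if K is None:
        K = int(g.adjacency.data.max()) + 1 if g.adjacency.nnz else 1
    coo = g.adjacency.tocoo()
    b = np.zeros((n_mc, n_mc))
    mm = cover.mc[coo.row]
    ll = cover.mc[coo.col]
    ok = (mm >= 0) & (ll >= 0)
    contrib = np.ceil(coo.data[ok] / c_scale)
    np.add.at(b, (mm[ok], ll[ok]), contrib)
    b *= K**2 / np.outer(sizes, sizes)

    row_sum = b.sum(axis=1, keepdims=True)
    col_sum = b.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        bprime = np.where(row_sum > 0, b / row_sum, 0.0) + np.where(
            col_sum > 0, b / col_sum, 0.0
        )
    return b, bprime


def build_mc_graph(bprime: np.ndarray, p: LayoutParams) -> nx.Graph:
    """Keep each metacell's top-D candidate edges (b' > t_edge, off-diagonal).

    A node's degree can exceed D only through edges added by its partners.
    """
    bprime = np.asarray(bprime, dtype=float)
    if bprime.ndim != 2 or bprime.shape[0] != bprime.shape[1]:
        raise DataError("B' must be square")
    n = bprime.shape[0]
    score = np.maximum(bprime, bprime.T)  # undirected candidate score
    gm = nx.Graph()
    gm.add_nodes_from(range(n))
    for m_ in range(n):
        cand = [j for j in range(n) if j != m_ and score[m_, j] > p.t_edge]
        cand.sort(key=lambda j: (-score[m_, j], j))
        for j in cand[: p.d_max]:
            gm.add_edge(m_, j, weight=float(score[m_, j]))
    return gm


def layout_mcs(g_m: nx.Graph, p: LayoutParams) -> np.ndarray:
    """Seeded Fruchterman-Reingold embedding, components packed on a grid.

    A single metacell is placed at the origin.  Identical seeds give
    identical coordinates.
    """
    n = g_m.number_of_nodes()
    coords = np.zeros((n, 2))
    if n == 0:
        return coords
    comps = sorted(nx.connected_components(g_m), key=lambda c: (-len(c), min(c)))
    n_comp = len(comps)
    grid = int(np.ceil(np.sqrt(n_comp)))
    for ci, comp in enumerate(comps):
        nodes = sorted(comp)
        sub = g_m.subgraph(nodes)
        if len(nodes) == 1:
            pos = {nodes[0]: np.zeros(2)}
        else:
            pos = nx.spring_layout(
                sub, seed=p.rng_seed + ci, iterations=p.iterations, dim=2
            )
        xy = np.array([pos[v] for v in nodes], dtype=float)
        if len(nodes) > 1:
            span = max(np.ptp(xy, axis=0).max(), 1e-9)
            xy = (xy - xy.min(axis=0)) / span  # normalize into the unit box
        offset = np.array([ci % grid, ci // grid], dtype=float) * 1.5
        for v, c in zip(nodes, xy + offset):
            coords[v] = c
    if n_comp == 1 and len(comps[0]) == 1:
        coords[:] = 0.0
    return coords


def position_cells(
    g: BalancedGraph,
    cover: MetacellCover | Assignment,
    g_m: nx.Graph,
    coords: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Average metacell coordinates of each cell's filtered neighbors.

    A cell's out-neighbors vote with their metacell's coordinates; neighbors
    whose (cell-MC, neighbor-MC) pair is neither an edge of G_M nor the
    identity are dropped.  Assigned cells with no surviving neighbor sit at
    their own metacell's coordinates.  Outlier cells are anchored at their
    strongest neighbor's metacell when one exists, otherwise omitted (listed
    in the returned index array).
    """
    adj = g.adjacency
    n = adj.shape[0]
    mc = cover.mc
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    for i in range(n):
        nb = adj.indices[adj.indptr[i] : adj.indptr[i + 1]]
        wt = adj.data[adj.indptr[i] : adj.indptr[i + 1]]
        my = mc[i]
        if my >= 0:
            keep = []
            for j in nb:
                kj = mc[j]
                if kj < 0:
                    continue
                if kj == my or g_m.has_edge(int(my), int(kj)):
                    keep.append(kj)
            if keep:
                pts = coords[np.asarray(keep)]
                xs[i], ys[i] = pts.mean(axis=0)
            else:
                xs[i], ys[i] = coords[my]
        else:
            assigned = [(w, mc[j]) for j, w in zip(nb, wt) if mc[j] >= 0]
            if assigned:
                assigned.sort(key=lambda t: (-t[0], t[1]))
                xs[i], ys[i] = coords[assigned[0][1]]
    placed = ~np.isnan(xs)
    df = pd.DataFrame(
        {"x": xs[placed], "y": ys[placed], "metacell": mc[placed]},
        index=np.flatnonzero(placed),
    )
    return df, np.flatnonzero(~placed)


def compute_layout(
    g: BalancedGraph, cover: MetacellCover | Assignment, p: LayoutParams | None = None
) -> Layout:
    p = p or LayoutParams()
    _, bprime = mc_edge_matrix(g, cover)
    gm = build_mc_graph(bprime, p)
    coords = layout_mcs(gm, p)
    cells, unplaced = position_cells(g, cover, gm, coords)
    return Layout(coords, cells, unplaced)


def plot_layout(layout: Layout, path, colors=None) -> None:
    """Static scatter of cells (colored) with metacell anchors overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    c = colors if colors is not None else layout.cell_coords["metacell"]
    ax.scatter(layout.cell_coords["x"], layout.cell_coords["y"], s=6, c=c, cmap="tab20")
    ax.scatter(layout.mc_coords[:, 0], layout.mc_coords[:, 1], s=40, c="black", marker="x")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
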