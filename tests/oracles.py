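"""Independent brute-force transcriptions of the core formulas.

Every function here is a deliberately naive (loop-based) evaluation used to
cross-check the vectorized implementations; none of them share code with the
package beyond basic numpy.
"""

from __future__ import annotations

import math

import numpy as np


def balance_bruteforce(s: np.ndarray, K: int, alpha: float, beta: float):
    """Triple-loop evaluation of the three balancing formulas.

    Rank 1 = highest value; ties broken by ascending index; zero entries are
    never ranked.  Returns (s1, s2, a).
    """
    n = s.shape[0]
    s1 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                s1[i, j] = max(alpha * K**2 - s[i, j] * s[j, i], 0.0)

    def rank_in(values, idx_order):
        """1-based descending ranks of positive entries (ties by index)."""
        order = sorted(idx_order, key=lambda t: (-values[t], t))
        ranks = {}
        r = 1
        for t in order:
            if values[t] > 0:
                ranks[t] = r
                r += 1
        return ranks

    s2 = np.zeros((n, n))
    for j in range(n):  # incoming edges of j live in column j
        col = {i: s1[i, j] for i in range(n)}
        ranks = rank_in(col, range(n))
        for i, r in ranks.items():
            s2[i, j] = max(beta * K - r, 0.0)

    a = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        row = {j: s2[i, j] for j in range(n)}
        ranks = rank_in(row, range(n))
        for j, r in ranks.items():
            a[i, j] = max(K - r, 0)
    return s1, s2, a


def pearson_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den if den > 0 else 0.0


def cooc_graph_bruteforce(s_boot: np.ndarray, k_core: int, factor: float) -> np.ndarray:
    """Edge rule: s_ij > max(T_i, T_j) * factor, T from k_core-th largest."""
    n = s_boot.shape[0]
    t = np.zeros(n)
    for i in range(n):
        pos = sorted((s_boot[i, j] for j in range(n) if j != i and s_boot[i, j] > 0),
                     reverse=True)
        if not pos:
            t[i] = 0.0
        elif len(pos) < k_core:
            t[i] = pos[-1]
        else:
            t[i] = pos[k_core - 1]
    edges = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and s_boot[i, j] > max(t[i], t[j]) * factor:
                edges[i, j] = True
    return edges


def closure_bruteforce(adj: np.ndarray, mc: np.ndarray) -> np.ndarray:
    n_mc = int(mc.max()) + 1 if (mc >= 0).any() else 0
    out = np.full(n_mc, np.nan)
    n = adj.shape[0]
    for k in range(n_mc):
        inside = incident = 0
        for i in range(n):
            for j in range(n):
                if adj[i, j] > 0 and (mc[i] == k or mc[j] == k):
                    incident += 1
                    if mc[i] == k and mc[j] == k:
                        inside += 1
        if incident:
            out[k] = inside / incident
    return out


def mc_edge_matrix_bruteforce(adj: np.ndarray, mc: np.ndarray, K: int):
    """Double-loop evaluation of b_ml and B' (row+column normalized)."""
    n_mc = int(mc.max()) + 1
    sizes = np.array([(mc == k).sum() for k in range(n_mc)], dtype=float)
    c_scale = float(np.median(sizes))
    b = np.zeros((n_mc, n_mc))
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if adj[i, j] > 0 and mc[i] >= 0 and mc[j] >= 0:
                b[mc[i], mc[j]] += math.ceil(adj[i, j] / c_scale)
    for m_ in range(n_mc):
        for l in range(n_mc):
            b[m_, l] *= K**2 / (sizes[m_] * sizes[l])
    bprime = np.zeros_like(b)
    for m_ in range(n_mc):
        for l in range(n_mc):
            rs = b[m_, :].sum()
            cs = b[:, l].sum()
            bprime[m_, l] = (b[m_, l] / rs if rs > 0 else 0.0) + (
                b[m_, l] / cs if cs > 0 else 0.0
            )
    return b, bprime


def pool_frequencies_bruteforce(X: np.ndarray, mc: np.ndarray) -> np.ndarray:
    n_mc = int(mc.max()) + 1
    G = X.shape[0]
    p = np.zeros((G, n_mc))
    for k in range(n_mc):
        mem = [i for i in range(len(mc)) if mc[i] == k]
        u_k = sum(X[:, i].sum() for i in mem)
        for g in range(G):
            p[g, k] = sum(X[g, i] for i in mem) / u_k
    return p


def geometric_profile_bruteforce(X: np.ndarray, mc: np.ndarray) -> np.ndarray:
    n_mc = int(mc.max()) + 1
    G, n = X.shape
    out = np.zeros((G, n_mc))
    for k in range(n_mc):
        mem = [i for i in range(n) if mc[i] == k]
        mean_depth = sum(X[:, i].sum() for i in mem) / len(mem)
        for g in range(G):
            mean_log = sum(math.log(1.0 + X[g, i]) for i in mem) / len(mem)
            out[g, k] = (math.exp(mean_log) - 1.0) / mean_depth
    return out


def position_cells_bruteforce(adj, mc, gm_edges: set, coords):
    """Straight transcription of the neighbor-filtering/averaging rule."""
    n = adj.shape[0]
    out = {}
    for i in range(n):
        my = mc[i]
        if my < 0:
            continue
        pts = []
        for j in range(n):
            if adj[i, j] > 0 and mc[j] >= 0:
                pair = (min(my, mc[j]), max(my, mc[j]))
                if mc[j] == my or pair in gm_edges:
                    pts.append(coords[mc[j]])
        if pts:
            out[i] = np.mean(np.array(pts), axis=0)
        else:
            out[i] = np.asarray(coords[my], dtype=float)
    return out


def optimize_scores_bruteforce(adj: np.ndarray, mc: np.ndarray) -> np.ndarray:
    """w_ik = wi * wo / |M_k|^2 for every cell and subgraph, by loops."""
    n = adj.shape[0]
    n_mc = int(mc.max()) + 1
    w = np.zeros((n, n_mc))
    sizes = np.array([(mc == k).sum() for k in range(n_mc)], dtype=float)
    for i in range(n):
        for k in range(n_mc):
            if sizes[k] == 0:
                continue
            wo = sum(adj[i, j] for j in range(n) if mc[j] == k)
            wi = sum(adj[j, i] for j in range(n) if mc[j] == k)
            w[i, k] = wi * wo / sizes[k] ** 2
    return w
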