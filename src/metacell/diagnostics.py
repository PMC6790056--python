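"""Homogeneity diagnostics and the cross-validated prediction harness.

The metacell model treats member cells as repeated multinomial samples from
one RNA pool.  This module quantifies how well a cover lives up to that:

* :func:`closure` -- the fraction of each metacell's incident graph edges
  that stay inside it (a graph-level compactness score);
* :func:`binomial_adherence` -- per gene and metacell, an empirical p-value
  of the observed binomial likelihood against 999 matrices drawn from the
  per-metacell multinomial, plus over-dispersion (observed/expected variance)
  and Poisson CV/zero-fraction curves;
* :func:`intra_mc_correlations` -- residual gene-gene correlations within
  metacells versus a label-permuted baseline;
* :func:`cv_predict` -- a gene-holdout cross-validation harness comparing
  metacell pooling against raw top-k-neighbor pooling for predicting held-out
  gene frequencies, with a no-cross-validation mode to expose over-fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_data import CountMatrix, DataError, ParameterError
from .balanced_graph import BalancedGraph, GraphParams, balance, rank_rows
from .partition import Assignment, PartitionParams, partition_graph
from .refine import MetacellCover

__all__ = [
    "AdherenceReport",
    "CVConfig",
    "closure",
    "binomial_adherence",
    "intra_mc_correlations",
    "cv_predict",
]


# ---------------------------------------------------------------------------
# Graph closure
# ---------------------------------------------------------------------------

def closure(g: BalancedGraph, cover: MetacellCover | Assignment) -> np.ndarray:
    """Per-metacell fraction of incident positive edges that are internal.

    An edge counts as incident when at least one endpoint is a member.
    Metacells with no incident edges get NaN (closure undefined).
    """
    coo = g.adjacency.tocoo()
    src_mc = cover.mc[coo.row]
    dst_mc = cover.mc[coo.col]
    n_mc = cover.n_mc
    out = np.full(n_mc, np.nan)
    for k in range(n_mc):
        touch = (src_mc == k) | (dst_mc == k)
        if not touch.any():
            continue
        inside = (src_mc == k) & (dst_mc == k)
        out[k] = inside.sum() / touch.sum()
    return out


# ---------------------------------------------------------------------------
# Binomial adherence
# ---------------------------------------------------------------------------

@dataclass
class AdherenceReport:
    """Per (gene, metacell) adherence statistics.

    ``table`` columns: metacell, gene, mean_count (down-sampled per-cell
    mean), p_value (empirical, in [1/(n_null+1), 1]), overdispersion, cv_obs,
    cv_poisson, zero_frac_obs, zero_frac_poisson.  Genes absent from a
    metacell's pool are not testable and are omitted.
    """

    table: pd.DataFrame
    n_null: int

    def export(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def overdispersion_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="gene", columns="metacell", values="overdispersion")


def _downsample_columns(x: np.ndarray, d: int, rng: np.random.Generator) -> np.ndarray:
    """Down-sample each column of a dense non-negative int matrix to total d."""
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        tot = int(col.sum())
        if tot == d:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, d, method="marginals")
    return out


def _binom_kernel(counts: np.ndarray, logc: np.ndarray) -> np.ndarray:
    """Data-dependent part of the binomial log-likelihood at the plug-in rate.

    Given uniform cell depth d and a fixed per-gene pooled count S, the
    summed log-likelihood sum_i log Binom(u_i; d, S/(n d)) differs from
    sum_i log C(d, u_i) only by a function of S, so the latter is the
    statistic compared between observed and null draws.  ``counts`` has
    shape (..., n_cells); returns the trailing-axis sum over cells.
    """
    return logc[counts].sum(axis=-1)


def binomial_adherence(
    m: CountMatrix,
    cover: MetacellCover | Assignment,
    genes: np.ndarray | None = None,
    n_null: int = 999,
    n_downsamples: int = 10,
    rng_seed: int = 0,
    min_cells: int = 3,
) -> AdherenceReport:
    """Test each metacell's counts against binomial/multinomial sampling.

    Within each metacell, cells are down-sampled to their minimum total d
    (over the tested gene set); per gene the binomial log-likelihood of the
    observed counts at the plug-in pool rate is compared against ``n_null``
    null draws.  The null conditions on the gene's pooled count S: given
    uniform depths and multinomial sampling, the cell counts given S are
    multivariate hypergeometric (S molecules over n cells of capacity d),
    a law free of the unknown rate -- this makes the test exact and its
    p-values uniform under the null, unlike an unconditional parametric
    bootstrap whose plug-in rates track the observed counts.  Ties in the
    discrete statistic are broken by seeded randomization, and p-values are
    floored at 1/(n_null+1).

    Over-dispersion (observed/expected variance, ddof=1) and the Poisson
    CV / zero-fraction curves are averaged over ``n_downsamples``
    independent down-samples; the p-value path uses the first down-sample
    only, whose marginal law matches the conditional null exactly.

    ``genes`` restricts testing (and the pool frequencies) to a gene subset,
    typically feature plus top-enriched genes; default is all genes.
    """
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    gene_idx = np.arange(m.n_genes) if genes is None else np.asarray(genes, dtype=np.int64)
    gene_names = m.gene_ids[gene_idx]
    X = m.counts[gene_idx, :].toarray()
    rng = np.random.default_rng(rng_seed)
    rows: list[pd.DataFrame] = []
    for k in range(cover.n_mc):
        mem = np.flatnonzero(cover.mc == k)
        if mem.size < min_cells:
            continue
        sub = X[:, mem]
        d = int(sub.sum(axis=0).min())
        if d < 1:
            continue
        pooled = sub.sum(axis=1).astype(float)
        p0 = pooled / pooled.sum()
        testable = p0 > 0
        n_cells = mem.size
        logc = gammaln(d + 1) - gammaln(np.arange(d + 1) + 1.0) - gammaln(d - np.arange(d + 1) + 1.0)

        # observed statistics
        obs_stat = None
        obs_s = None
        od = np.zeros(X.shape[0])
        cv_obs = np.zeros(X.shape[0])
        zf_obs = np.zeros(X.shape[0])
        mean_ds = np.zeros(X.shape[0])
        for t in range(n_downsamples):
            ds = _downsample_columns(sub, d, rng)
            mu = ds.mean(axis=1)
            var = ds.var(axis=1, ddof=1)
            phat = mu / d
            exp_var = d * phat * (1.0 - phat)
            with np.errstate(invalid="ignore", divide="ignore"):
                od += np.where(exp_var > 0, var / np.maximum(exp_var, 1e-300), 0.0)
                cv_obs += np.where(mu > 0, np.sqrt(var) / np.maximum(mu, 1e-300), 0.0)
            zf_obs += (ds == 0).mean(axis=1)
            mean_ds += mu
            if t == 0:
                obs_stat = _binom_kernel(ds, logc)
                obs_s = ds.sum(axis=1)
        od /= n_downsamples
        cv_obs /= n_downsamples
        zf_obs /= n_downsamples
        mean_ds /= n_downsamples

        # per-gene conditional null (independent draws per gene)
        capacities = np.full(n_cells, d, dtype=np.int64)
        pval = np.ones(X.shape[0])
        for g in np.flatnonzero(testable):
            s_val = int(obs_s[g])
            if s_val == 0:
                null_stat = np.zeros(n_null)
            else:
                draws = rng.multivariate_hypergeometric(
                    capacities, s_val, size=n_null, method="marginals"
                )
                null_stat = _binom_kernel(draws, logc)
            lower = int((null_stat < obs_stat[g] - 1e-9).sum())
            equal = int((np.abs(null_stat - obs_stat[g]) <= 1e-9).sum())
            u = rng.random()
            pval[g] = (lower + u * (1 + equal)) / (n_null + 1.0)
        pval = np.maximum(pval, 1.0 / (n_null + 1.0))

        with np.errstate(divide="ignore"):
            cv_pois = np.where(mean_ds > 0, 1.0 / np.sqrt(np.maximum(mean_ds, 1e-300)), 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "metacell": k,
                    "gene": gene_names[testable],
                    "mean_count": mean_ds[testable],
                    "p_value": pval[testable],
                    "overdispersion": od[testable],
                    "cv_obs": cv_obs[testable],
                    "cv_poisson": cv_pois[testable],
                    "zero_frac_obs": zf_obs[testable],
                    "zero_frac_poisson": np.exp(-mean_ds[testable]),
                }
            )
        )
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "metacell", "gene", "mean_count", "p_value", "overdispersion",
                "cv_obs", "cv_poisson", "zero_frac_obs", "zero_frac_poisson",
            ]
        )
    )
    return AdherenceReport(table, n_null)


# ---------------------------------------------------------------------------
# Residual intra-metacell correlations
# ---------------------------------------------------------------------------

def _corr_zero_safe(t: np.ndarray) -> np.ndarray:
    """Gene-gene Pearson correlations; zero-variance genes contribute 0."""
    sd = t.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(t)
    c = np.nan_to_num(c, nan=0.0)
    c[sd == 0, :] = 0.0
    c[:, sd == 0] = 0.0
    return c


def intra_mc_correlations(
    m: CountMatrix,
    cover: MetacellCover | Assignment,
    genes: np.ndarray | None = None,
    rng_seed: int = 0,
    min_cells: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Average within-metacell gene-gene correlations and a permuted baseline.

    Per metacell: members are down-sampled to a common depth, counts are
    log2(1+u)-transformed, and gene-gene Pearson correlations are averaged
    across metacells (equal weight).  The baseline repeats the computation
    after a seeded permutation of the metacell labels over assigned cells.
    Returns ``(within, permuted)``.
    """
    gene_idx = np.arange(m.n_genes) if genes is None else np.asarray(genes, dtype=np.int64)
    rng = np.random.default_rng(rng_seed)

    def _average(labels: np.ndarray, rng_local: np.random.Generator) -> np.ndarray:
        acc = np.zeros((gene_idx.size, gene_idx.size))
        used = 0
        for k in range(cover.n_mc):
            mem = np.flatnonzero(labels == k)
            if mem.size < min_cells:
                continue
            sub = m.counts[gene_idx, :][:, mem].toarray()
            d = int(sub.sum(axis=0).min())
            if d < 1:
                continue
            ds = _downsample_columns(sub, d, rng_local)
            acc += _corr_zero_safe(np.log2(1.0 + ds))
            used += 1
        if used == 0:
            raise DataError("no metacell large enough for correlation analysis")
        return acc / used

    within = _average(cover.mc, rng)
    assigned = np.flatnonzero(cover.mc >= 0)
    perm_labels = cover.mc.copy()
    perm_labels[assigned] = cover.mc[assigned][rng.permutation(assigned.size)]
    permuted = _average(perm_labels, rng)
    return within, permuted


# ---------------------------------------------------------------------------
# Cross-validated expression prediction
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Configuration for the gene-holdout prediction harness.

    ``pool_multiplier`` is the literal constant inside log2(1 + c*u) of the
    pool-frequency formula; the printed value 7 is kept as the default and is
    configurable (see docs).  Strategies: ``mc_pool`` predicts from the
    cell's metacell (cell excluded), ``raw_knn_pool`` from its top
    ``n_neighbors`` raw-similarity neighbors.
    """

    n_folds: int = 100
    n_neighbors: int = 50
    pool_multiplier: float = 7.0
    strategies: tuple = ("mc_pool", "raw_knn_pool")
    graph: GraphParams = field(default_factory=GraphParams)
    partition: PartitionParams | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ParameterError("n_folds must be >= 2")
        bad = set(self.strategies) - {"mc_pool", "raw_knn_pool"}
        if bad:
            raise ParameterError(f"unknown strategies {sorted(bad)}")


def _pool_weights_mc(labels: np.ndarray) -> np.ndarray:
    """cells x cells weight matrix: column j averages j's metacell minus j."""
    n = labels.size
    w = np.zeros((n, n))
    for k in range(int(labels.max()) + 1 if (labels >= 0).any() else 0):
        mem = np.flatnonzero(labels == k)
        if mem.size < 2:
            continue
        w[np.ix_(mem, mem)] = 1.0 / (mem.size - 1)
        w[mem, mem] = 0.0
    return w


def _pool_weights_knn(r: np.ndarray, k: int) -> np.ndarray:
    n = r.shape[0]
    work = r.copy()
    np.fill_diagonal(work, -np.inf)
    k = min(k, n - 1)
    top = np.argpartition(-work, k - 1, axis=0)[:k, :]
    w = np.zeros((n, n))
    np.put_along_axis(w, top, 1.0 / k, axis=0)
    return w


def _predict(
    X: np.ndarray, depths: np.ndarray, w: np.ndarray, mult: float
) -> np.ndarray:
    """Pool-frequency prediction for the rows of X given column-pool weights."""
    a = np.log2(1.0 + mult * X)
    colsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_log = (a @ w) / np.maximum(colsum, 1e-300)
        mean_depth = (depths @ w) / np.maximum(colsum, 1e-300)
        pred = np.expm1(mean_log) / np.maximum(mean_depth, 1e-300)
    pred[:, colsum == 0] = np.nan  # empty pools (outlier cells)
    return pred


def _rowwise_corr(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    out = np.full(pred.shape[0], np.nan)
    for g in range(pred.shape[0]):
        ok = ~np.isnan(pred[g])
        if ok.sum() < 3:
            continue
        x, y = pred[g, ok], obs[g, ok]
        if x.std() == 0 or y.std() == 0:
            out[g] = 0.0
        else:
            out[g] = float(np.corrcoef(x, y)[0, 1])
    return out


def cv_predict(m: CountMatrix, cfg: CVConfig, rng_seed: int = 0) -> pd.DataFrame:
    """Gene-holdout cross-validation of expression prediction accuracy.

    Genes are split into ``cfg.n_folds`` folds (seeded).  For each fold, raw
    cell-cell similarities -- and, for the ``mc_pool`` strategy, a direct
    (single-pass) metacell cover -- are rebuilt on the remaining genes only,
    and each held-out gene's per-cell frequency u_gi/u_i is predicted from
    pooled counts.  A no-cross-validation pass rebuilds similarities and the
    cover once on *all* genes; the CV-vs-no-CV gap measures over-fitting.
    Cells are never part of their own pool in either mode.

    Returns a per-gene table with ``mean_expr`` and columns
    ``corr_<strategy>_cv`` / ``corr_<strategy>_nocv`` in [-1, 1].
    """
    if m.n_genes < cfg.n_folds:
        raise DataError("need at least n_folds genes")
    rng = np.random.default_rng(rng_seed)
    X = m.dense().astype(float)
    depths = m.cell_totals.astype(float)
    obs = X / np.maximum(depths, 1.0)[None, :]
    folds = np.array_split(rng.permutation(m.n_genes), cfg.n_folds)
    pp = cfg.partition or PartitionParams.for_K(cfg.graph.K, rng_seed=rng_seed)

    def _weights(train_idx: np.ndarray):
        if train_idx.size < 2:
            raise DataError("a fold left fewer than 2 training genes")
        t = np.log2(cfg.graph.log_eps + X[train_idx, :])
        sd = t.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(t, rowvar=False)
        r = np.nan_to_num(r, nan=0.0)
        r[sd == 0, :] = 0.0
        r[:, sd == 0] = 0.0
        np.fill_diagonal(r, 1.0)
        out = {}
        if "raw_knn_pool" in cfg.strategies:
            out["raw_knn_pool"] = _pool_weights_knn(r, cfg.n_neighbors)
        if "mc_pool" in cfg.strategies:
            g = balance(rank_rows(r), cfg.graph)
            labels = partition_graph(g.adjacency, pp).mc
            out["mc_pool"] = _pool_weights_mc(labels)
        return out

    result = pd.DataFrame(
        {"mean_expr": m.gene_totals / m.n_cells},
        index=pd.Index(m.gene_ids, name="gene"),
    )

    # cross-validated predictions
    preds = {s: np.full(X.shape, np.nan) for s in cfg.strategies}
    for fold in folds:
        w = _weights(np.setdiff1d(np.arange(m.n_genes), fold))
        for s in cfg.strategies:
            preds[s][fold, :] = _predict(X[fold, :], depths, w[s], cfg.pool_multiplier)
    for s in cfg.strategies:
        result[f"corr_{s}_cv"] = _rowwise_corr(preds[s], obs)

    # over-fitting mode: similarities/cover from all genes, no holdout
    w_all = _weights(np.arange(m.n_genes))
    for s in cfg.strategies:
        pred = _predict(X, depths, w_all[s], cfg.pool_multiplier)
        result[f"corr_{s}_nocv"] = _rowwise_corr(pred, obs)
    return result
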