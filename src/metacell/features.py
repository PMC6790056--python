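"""Feature-gene selection for the cell-cell similarity computation.

Similarities are computed over individual genes rather than reduced
dimensions, so the feature set F directly controls what "transcriptional
state" means downstream.  Two per-gene scores drive selection:

* the *normalized size correlation* -- the Pearson correlation of a gene's
  counts with per-cell depth, centered against the mean correlation of genes
  with comparable totals (20 equal-occupancy expression bins).  Genes tracking
  library size score near 0 after centering; state-specific genes score
  negative.
* the *niche score* -- the fraction of a gene's molecules found in its top 5%
  highest-expressing cells, minus the expectation of the same statistic under
  multinomial sampling proportional to cell depth (estimated by a small
  fixed-seed Monte Carlo, so the operation stays deterministic).  Genes
  restricted to a cell subpopulation score high.

These are documented surrogates for scores whose exact published definitions
are not reproduced here; they sit behind the statistics table so alternative
definitions can be swapped in without touching selection logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CountMatrix, DataError, ParameterError, downsample_cells

__all__ = ["FeatureParams", "FeatureSet", "gene_stats", "select_features"]

_NICHE_TOP_FRACTION = 0.05
_NICHE_NULL_DRAWS = 25


@dataclass
class FeatureParams:
    min_total_umi: int = 300
    min_umi_per_cell: int = 3
    min_cells_at_min: int = 3
    size_corr_max: float = -0.1
    niche_score_min: float = 0.1
    var_mean_min: float | None = None  # replaces the corr/niche clause when set
    gene_blacklist: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for v in (self.min_total_umi, self.min_umi_per_cell, self.min_cells_at_min):
            if v < 0:
                raise ParameterError("count thresholds must be non-negative")
        if not np.isfinite(self.size_corr_max) or not np.isfinite(self.niche_score_min):
            raise ParameterError("score thresholds must be finite")
        self.gene_blacklist = frozenset(self.gene_blacklist)


@dataclass
class FeatureSet:
    """Selected feature genes plus the statistics table they were drawn from."""

    gene_ids: np.ndarray
    stats: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(self.gene_ids) == 0:
            raise DataError("feature set is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def export(self, genes_path, stats_path=None) -> None:
        with open(genes_path, "w") as fh:
            for g in self.gene_ids:
                fh.write(f"{g}\n")
        if stats_path is not None:
            self.stats.to_csv(stats_path, sep="\t", index_label="gene")


def _pearson_rows_vs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Correlation of each row of ``x`` with the vector ``y``; 0 on zero variance."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = xc @ yc
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    out = np.zeros(x.shape[0])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def gene_stats(
    m: CountMatrix,
    min_umi_per_cell: int = 3,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-gene statistics table used by :func:`select_features`.

    Columns: ``total_umi``, ``n_cells_at_min`` (cells with at least
    ``min_umi_per_cell`` molecules), ``size_corr`` (raw depth correlation),
    ``size_corr_norm`` (centered against 20 expression-matched bins),
    ``niche_score``, and ``var_mean`` (variance/mean on counts down-sampled to
    the minimum cell depth, removing depth confounding).  All-zero genes get
    zeros throughout, never NaN.
    """
    if m.n_cells < 2:
        raise DataError("gene statistics require at least 2 cells")
    X = m.dense().astype(float)
    depths = m.cell_totals.astype(float)
    totals = m.gene_totals.astype(float)
    n_genes, n_cells = X.shape

    # raw and bin-centered size correlation
    size_corr = _pearson_rows_vs(X, depths)
    order = np.argsort(totals, kind="stable")
    size_corr_norm = np.zeros(n_genes)
    for chunk in np.array_split(order, min(20, n_genes)):
        if chunk.size:
            size_corr_norm[chunk] = size_corr[chunk] - size_corr[chunk].mean()

    # niche score: observed top-5% occupancy minus its multinomial expectation
    k = max(1, int(np.ceil(_NICHE_TOP_FRACTION * n_cells)))
    top_sorted = np.sort(X, axis=1)[:, ::-1][:, :k]
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_frac = np.where(totals > 0, top_sorted.sum(axis=1) / np.maximum(totals, 1), 0.0)
    rng = np.random.default_rng(rng_seed)
    depth_p = depths / depths.sum()
    exp_frac = np.zeros(n_genes)
    nz = totals > 0
    for _ in range(_NICHE_NULL_DRAWS):
        for g in np.flatnonzero(nz):
            draw = rng.multinomial(int(totals[g]), depth_p)
            top = np.partition(draw, n_cells - k)[n_cells - k :]
            exp_frac[g] += top.sum() / totals[g]
    exp_frac[nz] /= _NICHE_NULL_DRAWS
    niche = np.where(nz, obs_frac - exp_frac, 0.0)

    # variance/mean on depth-equalized counts
    target = int(depths.min())
    ds = downsample_cells(m, max(target, 1), rng_seed=rng_seed).dense().astype(float)
    mu = ds.mean(axis=1)
    var = ds.var(axis=1, ddof=1)
    var_mean = np.where(mu > 0, var / np.maximum(mu, 1e-300), 0.0)

    return pd.DataFrame(
        {
            "total_umi": totals.astype(np.int64),
            "n_cells_at_min": (X >= min_umi_per_cell).sum(axis=1).astype(np.int64),
            "size_corr": size_corr,
            "size_corr_norm": size_corr_norm,
            "niche_score": niche,
            "var_mean": var_mean,
        },
        index=pd.Index(m.gene_ids, name="gene"),
    )


def select_features(stats: pd.DataFrame, p: FeatureParams) -> FeatureSet:
    """Apply the selection rule to a statistics table.

    A gene is retained iff it passes (a) the score clause -- normalized size
    correlation below ``size_corr_max`` OR niche score above
    ``niche_score_min``, replaced by ``var_mean > var_mean_min`` when that
    alternative criterion is set -- (b) ``total_umi >= min_total_umi``, (c) at
    least ``min_cells_at_min`` cells at ``min_umi_per_cell`` molecules, and
    (d) is not blacklisted.
    """
    if p.var_mean_min is not None:
        score_ok = stats["var_mean"] > p.var_mean_min
    else:
        score_ok = (stats["size_corr_norm"] < p.size_corr_max) | (
            stats["niche_score"] > p.niche_score_min
        )
    keep = (
        score_ok
        & (stats["total_umi"] >= p.min_total_umi)
        & (stats["n_cells_at_min"] >= p.min_cells_at_min)
        & ~stats.index.isin(p.gene_blacklist)
    )
    if not keep.any():
        raise DataError(
            "feature selection returned no genes; relax min_total_umi or the "
            "size-correlation/niche thresholds"
        )
    return FeatureSet(stats.index[keep].to_numpy(), stats.loc[keep].copy())
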