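"""Metacell expression profiles and log-fold enrichment.

The expression intensity of gene g in metacell k is summarized by a
regularized geometric mean of its counts over member cells, normalized by
mean depth:

    p_gk = (exp[ mean_{i in M_k} log(1 + u_gi) ] - 1) / mean_{i in M_k} u_i

(natural log inside, so p_gk is the geometric mean of 1+u minus one; a gene
absent from the metacell maps to exactly 0).  An alternative reading that
moves the -1 inside the exponent is available as ``variant="exp_shift"``; it
differs from the default by the constant factor e^-1 only when counts are
nonzero, and is kept purely for comparison.

Relative expression is the log2 fold enrichment over the across-metacell
median:

    lfp_gk = log2((p_gk + eps) / median_k'(p_gk' + eps))

so for every gene the median lfp over metacells is exactly 0 when the number
of metacells is odd.  ``eps`` (default 1e-4) regularizes unexpressed genes
and should be adapted to typical metacell molecule totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CountMatrix, DataError, ParameterError
from .partition import Assignment
from .refine import MetacellCover

__all__ = ["MCProfile", "geometric_profile", "lfp", "compute_profiles", "marker_genes"]


def geometric_profile(
    m: CountMatrix,
    cover: MetacellCover | Assignment,
    variant: str = "gm_minus_1",
) -> np.ndarray:
    """Regularized geometric-mean frequencies, genes x metacells."""
    n_mc = cover.n_mc
    if n_mc == 0:
        raise DataError("cover has no metacells")
    X = m.dense().astype(float)
    depths = m.cell_totals.astype(float)
    out = np.empty((m.n_genes, n_mc))
    for k in range(n_mc):
        mem = np.flatnonzero(cover.mc == k)
        if mem.size == 0:
            raise DataError(f"empty metacell {k}")
        mean_log = np.log1p(X[:, mem]).mean(axis=1)
        if variant == "gm_minus_1":
            num = np.expm1(mean_log)
        elif variant == "exp_shift":
            num = np.exp(mean_log - 1.0)
        else:
            raise ParameterError(f"unknown variant {variant!r}")
        out[:, k] = num / depths[mem].mean()
    return out


def lfp(p: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """log2 fold enrichment of p_gk over the per-gene median across metacells."""
    if eps <= 0:
        raise ParameterError("eps must be positive")
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] < 1:
        raise DataError("profile table must be genes x metacells with >= 1 metacell")
    reg = p + eps
    med = np.median(reg, axis=1, keepdims=True)
    return np.log2(reg / med)


@dataclass
class MCProfile:
    """Per-metacell gene frequencies and enrichments."""

    p_gk: pd.DataFrame  # genes x metacells
    lfp_gk: pd.DataFrame
    eps_lfp: float = 1e-4

    def export(self, p_path, lfp_path) -> None:
        self.p_gk.to_csv(p_path, sep="\t", index_label="gene")
        self.lfp_gk.to_csv(lfp_path, sep="\t", index_label="gene")


def compute_profiles(
    m: CountMatrix,
    cover: MetacellCover | Assignment,
    eps: float = 1e-4,
    variant: str = "gm_minus_1",
) -> MCProfile:
    p = geometric_profile(m, cover, variant=variant)
    cols = [f"mc{k}" for k in range(p.shape[1])]
    idx = pd.Index(m.gene_ids, name="gene")
    return MCProfile(
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(lfp(p, eps), index=idx, columns=cols),
        eps_lfp=eps,
    )


def marker_genes(profile: MCProfile, top_n: int = 10) -> dict[str, list[str]]:
    """Per-metacell top enriched genes (heatmap row ordering helper)."""
    out: dict[str, list[str]] = {}
    for col in profile.lfp_gk.columns:
        out[col] = profile.lfp_gk[col].sort_values(ascending=False).head(top_n).index.tolist()
    return out
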