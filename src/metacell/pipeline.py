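"""End-to-end orchestration: counts -> metacell cover -> profiles -> layout.

Every stage is a pure function of (inputs, config, seed); per-stage RNG
streams are spawned from the global seed, so reruns with one seed are
bit-identical.  Each stage's output is persisted as plain text under the run
directory, and a manifest records the package version, the seeds, and a hash
of the full parameter set.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    CountMatrix,
    DataError,
    filter_cells_and_genes,
    load_umi_matrix,
    write_umi_matrix,
)
from .features import FeatureSet, gene_stats, select_features
from .balanced_graph import BalancedGraph, build_balanced_graph
from .partition import Assignment, partition_graph
from .consensus import consensus_partition
from .refine import (
    MetacellCover,
    filter_outliers,
    outlier_fold,
    pool_frequencies,
    split_heterogeneous,
)
from .profiles import MCProfile, compute_profiles
from .diagnostics import AdherenceReport, binomial_adherence, closure
from .layout2d import Layout, compute_layout
from .config import PipelineConfig
from .synthetic import generate, make_preset

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    matrix: CountMatrix
    features: FeatureSet
    graph: BalancedGraph
    cover: MetacellCover
    profile: MCProfile
    layout: Layout
    adherence: AdherenceReport | None
    closure: np.ndarray
    outlier_report: pd.DataFrame
    manifest: dict
    truth: pd.DataFrame | None = None  # present for synthetic inputs


def _stage_seeds(global_seed: int) -> dict:
    names = ["downsample", "stats", "partition", "resample", "split", "adherence", "layout"]
    ss = np.random.SeedSequence(global_seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, ss)}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline described by ``cfg``.

    Stages: load -> filter -> feature selection -> balanced graph ->
    consensus partition (or direct partition when ``n_boot`` is 0) ->
    parametric outlier filter -> heterogeneity split -> profiles ->
    diagnostics -> 2D layout.  Intermediates are written under ``out_dir``
    (defaults to ``cfg.out_dir``).
    """
    if cfg.input_path is None and cfg.synthetic_preset is None:
        from .config import ConfigError

        raise ConfigError("either input_path or synthetic_preset is required")
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.rng_seed)
    t0 = time.time()
    stage = "load"
    try:
        truth = None
        if cfg.synthetic_preset is not None:
            spec = make_preset(cfg.synthetic_preset, rng_seed=cfg.rng_seed)
            m, truth = generate(spec)
            truth.to_csv(out / "truth.tsv", sep="\t")
        else:
            m = load_umi_matrix(cfg.input_path, cfg.input_format)
        _log_stage(stage, t0, m)

        stage = "filter"
        m = filter_cells_and_genes(m, cfg.cell_filter)
        write_umi_matrix(m, out / "filtered_matrix", format="mtx_triplet")
        _log_stage(stage, t0, m)

        stage = "features"
        stats = gene_stats(m, cfg.features.min_umi_per_cell, rng_seed=seeds["stats"])
        fset = select_features(stats, cfg.features)
        fset.export(out / "features.txt", out / "gene_stats.tsv")
        log.info("stage=%s selected %d feature genes", stage, len(fset))

        stage = "balanced_graph"
        g = build_balanced_graph(m, fset, cfg.graph, rng_seed=seeds["downsample"])
        g.write_edges(out / "balanced_graph_edges.tsv")
        _log_stage(stage, t0, m)

        stage = "partition"
        bp = cfg.partition
        if cfg.resample.n_boot > 0:
            import dataclasses as _dc

            rp = _dc.replace(cfg.resample, rng_seed=seeds["resample"])
            bp = _dc.replace(bp, rng_seed=seeds["partition"])
            assignment, cooc = consensus_partition(g, bp, rp, cfg.cooc)
            cooc.export(out / "cooc_stats.tsv")
        else:
            import dataclasses as _dc

            assignment = partition_graph(g, _dc.replace(bp, rng_seed=seeds["partition"]))
        assignment.export(out / "assignment_raw.tsv", m.cell_ids)
        _log_stage(stage, t0, m)

        stage = "outlier_filter"
        if assignment.n_mc == 0:
            raise DataError("partitioning produced no metacells")
        p_gk = pool_frequencies(m, assignment)
        folds = outlier_fold(m, p_gk, assignment)
        cover, outlier_report = filter_outliers(folds, cfg.outlier, assignment)
        rep = outlier_report.copy()
        if len(rep):
            rep["cell"] = m.cell_ids[rep["cell"].to_numpy()]
            rep["gene"] = m.gene_ids[rep["gene"].to_numpy()]
        rep.to_csv(out / "outlier_report.tsv", sep="\t", index=False)
        _log_stage(stage, t0, m)

        stage = "split"
        import dataclasses as _dc

        cover = split_heterogeneous(m, cover, _dc.replace(cfg.split, rng_seed=seeds["split"]))
        cover.export(out / "cover.tsv", m.cell_ids)
        _log_stage(stage, t0, m)

        stage = "profiles"
        profile = compute_profiles(m, cover, eps=cfg.eps_lfp)
        profile.export(out / "p_gk.tsv", out / "lfp.tsv")

        stage = "diagnostics"
        clo = closure(g, cover)
        pd.DataFrame({"metacell": np.arange(cover.n_mc), "closure": clo}).to_csv(
            out / "closure.tsv", sep="\t", index=False
        )
        adherence = None
        if cfg.adherence_nulls > 0:
            adherence = binomial_adherence(
                m, cover, n_null=cfg.adherence_nulls, rng_seed=seeds["adherence"]
            )
            adherence.export(out / "adherence.tsv")
        _log_stage(stage, t0, m)

        stage = "layout"
        lay = compute_layout(g, cover, _dc.replace(cfg.layout, rng_seed=seeds["layout"]))
        lay.export(out / "layout.tsv", m.cell_ids)
        _log_stage(stage, t0, m)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise

    manifest = {
        "version": __version__,
        "rng_seed": cfg.rng_seed,
        "stage_seeds": seeds,
        "params_hash": cfg.params_hash(),
        "n_cells": int(m.n_cells),
        "n_genes": int(m.n_genes),
        "n_features": int(len(fset)),
        "n_metacells": int(cover.n_mc),
        "n_outliers": int(cover.outlier_mask.sum()),
        "wall_seconds": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        matrix=m,
        features=fset,
        graph=g,
        cover=cover,
        profile=profile,
        layout=lay,
        adherence=adherence,
        closure=clo,
        outlier_report=outlier_report,
        manifest=manifest,
        truth=truth,
    )


def _log_stage(stage: str, t0: float, m: CountMatrix) -> None:
    log.info(
        "stage=%s elapsed=%.1fs cells=%d genes=%d", stage, time.time() - t0, m.n_cells, m.n_genes
    )
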