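"""Pipeline configuration: one flat, human-editable YAML with per-stage blocks.

Shipped presets mirror the published whole-dataset parameter sets:

``pbmc``      K=100, 500 resamples at rho=0.75, alpha=10, beta=3, K_core=30,
              t_lfc=3 ("8-fold or more"), eps_lfp=1e-4.
``worm``      cell window [100, 8000] UMIs, K=150, 1000 resamples, consensus
              partition with size_min=30, t_lfc=4.
``planaria``  cell window [500, 18000] UMIs, otherwise as worm, t_lfc=4.5.

These presets describe full-scale runs; tests and the acceptance script use
deliberately smaller resample counts (documented in docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core_data import CellFilterParams, ParameterError
from .features import FeatureParams
from .balanced_graph import GraphParams
from .partition import PartitionParams
from .consensus import CoocGraphParams, ResampleParams
from .refine import OutlierParams, SplitParams
from .layout2d import LayoutParams

__all__ = ["PipelineConfig", "ConfigError", "load_config", "preset_config", "PRESETS"]

PRESETS = ("pbmc", "worm", "planaria")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """All parameter blocks plus paths and the global seed.

    ``n_boot = 0`` switches the consensus stage off and partitions the
    balanced graph directly (cheap exploratory runs).
    """

    input_path: str | None = None
    input_format: str = "mtx_triplet"
    synthetic_preset: str | None = None
    out_dir: str = "metacell_out"
    rng_seed: int = 0

    cell_filter: CellFilterParams = field(default_factory=lambda: CellFilterParams(min_umi=100))
    features: FeatureParams = field(default_factory=FeatureParams)
    graph: GraphParams = field(default_factory=GraphParams)
    partition: PartitionParams | None = None  # default derived from graph.K
    resample: ResampleParams = field(default_factory=ResampleParams)
    cooc: CoocGraphParams = field(default_factory=CoocGraphParams)
    outlier: OutlierParams = field(default_factory=OutlierParams)
    split: SplitParams = field(default_factory=SplitParams)
    layout: LayoutParams = field(default_factory=LayoutParams)
    eps_lfp: float = 1e-4
    adherence_nulls: int = 0  # 0 skips the (expensive) adherence diagnostics

    def __post_init__(self) -> None:
        if self.partition is None:
            self.partition = PartitionParams.for_K(self.graph.K)
        if self.partition.size_min >= self.graph.K:
            raise ConfigError("partition.size_min must be smaller than graph.K")
        if self.cooc.k_core > self.graph.beta * self.graph.K:
            raise ConfigError("cooc.k_core must not exceed beta * K (max in-degree)")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def params_hash(self) -> str:
        """Hash of all parameters (and the input identity, not the out_dir)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_BLOCKS = {
    "cell_filter": CellFilterParams,
    "features": FeatureParams,
    "graph": GraphParams,
    "partition": PartitionParams,
    "resample": ResampleParams,
    "cooc": CoocGraphParams,
    "outlier": OutlierParams,
    "split": SplitParams,
    "layout": LayoutParams,
}


def _build_config(raw: dict) -> PipelineConfig:
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _BLOCKS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            cls = _BLOCKS[key]
            try:
                if key == "cooc" and "partition" in value and isinstance(value["partition"], dict):
                    value = dict(value)
                    value["partition"] = PartitionParams(**value["partition"])
                if key in ("cell_filter", "features") and "gene_blacklist" in value:
                    value = dict(value)
                    value["gene_blacklist"] = frozenset(value["gene_blacklist"])
                kwargs[key] = cls(**value)
            except (TypeError, ParameterError, ValueError) as exc:
                raise ConfigError(f"invalid {key} section: {exc}") from exc
        else:
            kwargs[key] = value
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file into a validated :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return _build_config(raw)


def preset_config(name: str, **overrides) -> PipelineConfig:
    """Named full-scale parameter presets (see module docstring)."""
    if name == "pbmc":
        raw = dict(
            cell_filter=CellFilterParams(min_umi=800),
            graph=GraphParams(K=100, alpha=10.0, beta=3.0),
            resample=ResampleParams(n_boot=500, rho=0.75),
            cooc=CoocGraphParams(k_core=30, partition=PartitionParams(size_min=25)),
            outlier=OutlierParams(t_lfc=3.0),
        )
    elif name == "worm":
        raw = dict(
            cell_filter=CellFilterParams(min_umi=100, max_umi=8000),
            features=FeatureParams(size_corr_max=-0.1, niche_score_min=0.1),
            graph=GraphParams(K=150, alpha=10.0, beta=3.0),
            resample=ResampleParams(n_boot=1000, rho=0.75),
            cooc=CoocGraphParams(k_core=30, partition=PartitionParams(size_min=30)),
            outlier=OutlierParams(t_lfc=4.0),
        )
    elif name == "planaria":
        raw = dict(
            cell_filter=CellFilterParams(min_umi=500, max_umi=18000),
            features=FeatureParams(size_corr_max=-0.1, niche_score_min=0.05),
            graph=GraphParams(K=150, alpha=10.0, beta=3.0),
            resample=ResampleParams(n_boot=1000, rho=0.75),
            cooc=CoocGraphParams(k_core=30, partition=PartitionParams(size_min=30)),
            outlier=OutlierParams(t_lfc=4.5),
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; expected one of {PRESETS}")
    raw.update(overrides)
    return PipelineConfig(**raw)
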