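"""Ground-truthed synthetic UMI fixtures.

Cells are drawn as multinomial samples from per-type gene-frequency profiles,
the sampling model the metacell construction assumes.  The generator supports
discrete types, continuous two-anchor gradients (mixture coefficient
``lambda`` drawn uniformly), doublets (average of two distinct type profiles
sampled at double depth, emulating two co-encapsulated lysates), and rare
outlier cells, each labeled in the returned truth table.

Presets used throughout the test suite:

``null_multinomial``
    one transcriptional state, 600 genes with a smoothly decaying frequency
    spectrum, 1000 cells at a fixed depth of 800 molecules -- the calibration
    fixture for the multinomial-adherence diagnostics.
``five_types``
    five well-separated states (pairwise total-variation distance 0.5 by
    construction), 300 cells each, 600 genes, lognormal depths around 800.
``gradient``
    two anchor profiles plus 600 cells sampled from lambda*p_a+(1-lambda)*p_b.
``doublet_spike``
    two distant types, 500 cells each, plus 2% 50/50 doublets at double depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import CountMatrix, DataError, ParameterError

__all__ = ["SyntheticSpec", "generate", "make_preset", "PRESET_NAMES"]

PRESET_NAMES = ("five_types", "gradient", "doublet_spike", "null_multinomial")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset.

    ``depth_model`` is either ``("fixed", d)`` or ``("lognormal", mu, sigma)``
    where ``mu``/``sigma`` parametrize the natural-log depth distribution.
    ``gradient_pairs`` entries are ``(type_a, type_b, n_cells)``; such cells
    draw ``lambda ~ Uniform(0, 1)`` and sample from the mixed profile.
    ``outlier_spec`` is ``(profile, count)`` for a rare extra state.
    """

    n_genes: int
    type_profiles: np.ndarray  # (n_types, n_genes), rows sum to 1
    cells_per_type: Sequence[int]
    depth_model: tuple = ("lognormal", float(np.log(800.0)), 0.4)
    gradient_pairs: Sequence[tuple] = field(default_factory=list)
    doublet_rate: float = 0.0
    outlier_spec: tuple | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.type_profiles = np.atleast_2d(np.asarray(self.type_profiles, dtype=float))
        if self.type_profiles.shape[0] == 0:
            raise DataError("at least one type profile is required")
        if self.type_profiles.shape[1] != self.n_genes:
            raise DataError("profile width does not match n_genes")
        if np.any(self.type_profiles < 0):
            raise DataError("profiles must be non-negative")
        sums = self.type_profiles.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise DataError("each type profile must sum to 1 (within 1e-12)")
        if not 0.0 <= self.doublet_rate <= 1.0:
            raise ParameterError("doublet_rate must lie in [0, 1]")
        if len(self.cells_per_type) != self.type_profiles.shape[0]:
            raise DataError("cells_per_type length must match number of profiles")


def _draw_depths(rng: np.random.Generator, model: tuple, n: int) -> np.ndarray:
    if model[0] == "fixed":
        return np.full(n, int(model[1]), dtype=np.int64)
    if model[0] == "lognormal":
        _, mu, sigma = model
        return np.maximum(np.round(rng.lognormal(mu, sigma, size=n)), 1).astype(np.int64)
    raise ParameterError(f"unknown depth model {model[0]!r}")


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its ground-truth label table from ``spec``.

    Returns ``(matrix, truth)`` where ``truth`` has one row per cell with
    columns ``type`` (originating type index; for doublets the first parent,
    for gradient cells the pair label ``a|b``), ``lam`` (anchor-a mixing
    weight; NaN for non-gradient cells), ``is_doublet`` and ``is_outlier``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    profiles: list[np.ndarray] = []
    types: list[str] = []
    lams: list[float] = []
    doublet: list[bool] = []
    outlier: list[bool] = []
    depths: list[int] = []

    n_types = spec.type_profiles.shape[0]
    for t in range(n_types):
        n = int(spec.cells_per_type[t])
        d = _draw_depths(rng, spec.depth_model, n)
        for i in range(n):
            profiles.append(spec.type_profiles[t])
            types.append(str(t))
            lams.append(np.nan)
            doublet.append(False)
            outlier.append(False)
            depths.append(int(d[i]))

    for (ta, tb, n) in spec.gradient_pairs:
        lam = rng.uniform(0.0, 1.0, size=n)
        d = _draw_depths(rng, spec.depth_model, n)
        for i in range(n):
            profiles.append(
                lam[i] * spec.type_profiles[ta] + (1.0 - lam[i]) * spec.type_profiles[tb]
            )
            types.append(f"{ta}|{tb}")
            lams.append(float(lam[i]))
            doublet.append(False)
            outlier.append(False)
            depths.append(int(d[i]))

    if spec.doublet_rate > 0 and n_types >= 2:
        n_base = int(np.sum(spec.cells_per_type))
        n_doub = int(round(spec.doublet_rate * n_base))
        for _ in range(n_doub):
            ta, tb = rng.choice(n_types, size=2, replace=False)
            d = int(_draw_depths(rng, spec.depth_model, 2).sum())  # two lysates
            profiles.append(0.5 * (spec.type_profiles[ta] + spec.type_profiles[tb]))
            types.append(str(ta))
            lams.append(np.nan)
            doublet.append(True)
            outlier.append(False)
            depths.append(d)

    if spec.outlier_spec is not None:
        prof, count = spec.outlier_spec
        prof = np.asarray(prof, dtype=float)
        prof = prof / prof.sum()
        d = _draw_depths(rng, spec.depth_model, int(count))
        for i in range(int(count)):
            profiles.append(prof)
            types.append("outlier")
            lams.append(np.nan)
            doublet.append(False)
            outlier.append(True)
            depths.append(int(d[i]))

    n_cells = len(profiles)
    counts = np.empty((n_cells, spec.n_genes), dtype=np.int64)
    for i in range(n_cells):
        counts[i] = rng.multinomial(depths[i], profiles[i])

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    gene_ids = [f"g{j:04d}" for j in range(spec.n_genes)]
    m = CountMatrix(gene_ids, cell_ids, sp.csr_matrix(counts.T))
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "type": types,
            "lam": lams,
            "is_doublet": doublet,
            "is_outlier": outlier,
        }
    ).set_index("cell_id")
    return m, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _block_profiles(n_genes: int, n_types: int, block: int) -> np.ndarray:
    """Type profiles: half the mass uniform on a private marker block, half on
    a shared, mildly decaying housekeeping spectrum.  Pairwise total-variation
    distance between any two types is 0.5."""
    shared_start = n_types * block
    n_shared = n_genes - shared_start
    if n_shared <= 0:
        raise ParameterError("marker blocks exceed the gene count")
    decay = 0.995 ** np.arange(n_shared)
    shared = 0.5 * decay / decay.sum()
    out = np.zeros((n_types, n_genes))
    for t in range(n_types):
        out[t, t * block : (t + 1) * block] = 0.5 / block
        out[t, shared_start:] = shared
    return out


def _decaying_profile(n_genes: int) -> np.ndarray:
    w = 1.0 / (np.arange(n_genes) + 50.0)
    return w / w.sum()


def perturbed_profiles(
    n_genes: int, n_types: int, sigma: float = 0.8, rng_seed: int = 0
) -> np.ndarray:
    """Type profiles where *every* gene varies across types.

    Each type multiplies a shared decaying base spectrum by iid lognormal
    factors exp(sigma * z) and renormalizes, so between-type expression
    differences exist at every mean-expression level -- the regime the
    prediction harness needs (block profiles leave shared genes constant
    across cells, which caps their predictability at zero).
    """
    rng = np.random.default_rng(rng_seed)
    base = _decaying_profile(n_genes)
    prof = base[None, :] * np.exp(sigma * rng.standard_normal((n_types, n_genes)))
    return prof / prof.sum(axis=1, keepdims=True)


def make_preset(name: str, rng_seed: int = 0) -> SyntheticSpec:
    """Return the fixed, versioned spec for one of the named presets."""
    if name == "five_types":
        return SyntheticSpec(
            n_genes=600,
            type_profiles=_block_profiles(600, 5, 60),
            cells_per_type=[300] * 5,
            depth_model=("lognormal", float(np.log(800.0)), 0.4),
            rng_seed=rng_seed,
        )
    if name == "gradient":
        return SyntheticSpec(
            n_genes=600,
            type_profiles=_block_profiles(600, 2, 60),
            cells_per_type=[0, 0],
            depth_model=("lognormal", float(np.log(800.0)), 0.4),
            gradient_pairs=[(0, 1, 600)],
            rng_seed=rng_seed,
        )
    if name == "doublet_spike":
        return SyntheticSpec(
            n_genes=600,
            type_profiles=_block_profiles(600, 2, 60),
            cells_per_type=[500, 500],
            depth_model=("lognormal", float(np.log(800.0)), 0.4),
            doublet_rate=0.02,
            rng_seed=rng_seed,
        )
    if name == "null_multinomial":
        return SyntheticSpec(
            n_genes=600,
            type_profiles=_decaying_profile(600)[None, :],
            cells_per_type=[1000],
            depth_model=("fixed", 800),
            rng_seed=rng_seed,
        )
    raise ParameterError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
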