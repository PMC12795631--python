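"""Synthetic landscapes with a known species-environment relationship.

This module generates every input the pipeline needs at desk scale:
spatially autocorrelated environmental layers, a categorical land-cover
layer, occurrence records sampled from a known logistic-of-features
suitability surface, "future" stacks as parameterized perturbations of the
current layers (several noise-perturbed variants per emissions scenario,
standing in for distinct climate models), and a small set of contiguous
labelled regions for zonal statistics.

Because the generating truth is known, downstream fits can be checked for
parameter-direction recovery, and the overlay stages can be exercised
end-to-end without any external geodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .occurrences import OccurrenceSet
from .raster import (CATEGORICAL_VARS, STATIC_VARS, VARIABLE_VOCAB, GridRaster,
                     RasterStack, align_stack)


@dataclass
class TrueModel:
    """Generative species-environment relationship on the logit scale.

    Suitability is ``invlogit(intercept + sum(linear_i * x_i) +
    sum(quadratic_i * x_i^2) + class offsets)``; categorical variables enter
    through per-class offsets. If ``prevalence_target`` is set, the intercept
    is shifted (at evaluation time) so that mean suitability over valid cells
    hits the target.
    """

    linear_coeffs: Dict[str, float] = field(default_factory=dict)
    quadratic_coeffs: Dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    prevalence_target: float | None = None
    class_offsets: Dict[str, Dict[int, float]] = field(default_factory=dict)

    def variables(self) -> set:
        return set(self.linear_coeffs) | set(self.quadratic_coeffs) | set(self.class_offsets)


@dataclass
class ScenarioSpec:
    """Parameterized perturbation standing in for one emissions scenario.

    Continuous layers transform as ``x -> scale * x + shift`` plus
    variant-specific Gaussian noise; each of the ``n_gcm_variants`` variants
    gets independent noise, emulating disagreement between climate models.
    A fraction of land-cover cells is reassigned to a designated degraded
    class. Elevation and human-influence layers are copied unchanged
    (assumed constant over time).
    """

    scenario_tag: str
    shifts: Dict[str, float] = field(default_factory=dict)
    scales: Dict[str, float] = field(default_factory=dict)
    lucc_transition_fraction: float = 0.0
    n_gcm_variants: int = 1
    variant_noise_sd: float = 0.0
    degraded_class: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lucc_transition_fraction <= 1):
            raise ValueError("lucc_transition_fraction must lie in [0, 1]")
        if self.n_gcm_variants < 1:
            raise ValueError("n_gcm_variants must be >= 1")
        if self.variant_noise_sd < 0:
            raise ValueError("variant_noise_sd must be >= 0")


def _smooth_field(shape, autocorr_range, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    return gaussian_filter(noise, sigma=autocorr_range, mode="reflect")


def generate_env_stack(shape, variables: Sequence[str], autocorr_range: float,
                       seed: int, n_lucc_classes: int = 4,
                       cell_size: float = 1.0, crs_label: str = "synthetic") -> RasterStack:
    """Generate a stack of spatially autocorrelated layers.

    Continuous layers are smoothed Gaussian noise standardized to mean 0 and
    sd 1 over valid cells; a LUCC layer, if requested, is a smoothed field
    quantile-binned into ``n_lucc_classes`` integer classes (1..k), which
    yields contiguous-looking patches. Deterministic given the seed.
    """
    if shape[0] < 20 or shape[1] < 20:
        raise ValueError("shape must be at least 20x20")
    unknown = [v for v in variables if v not in VARIABLE_VOCAB]
    if unknown:
        raise ValueError(f"unknown variable name(s) {unknown}")
    if not (3 <= n_lucc_classes <= 6):
        raise ValueError("n_lucc_classes must lie in [3, 6]")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    layers: Dict[str, GridRaster] = {}
    for name in variables:
        fld = _smooth_field(shape, autocorr_range, rng)
        if name in CATEGORICAL_VARS:
            qs = np.quantile(fld, np.linspace(0, 1, n_lucc_classes + 1)[1:-1])
            codes = (np.digitize(fld, qs) + 1).astype(np.int32)
            values = codes
        else:
            values = (fld - fld.mean()) / fld.std()
        layers[name] = GridRaster(values=values, nodata_mask=mask.copy(),
                                  origin_x=0.0, origin_y=shape[0] * cell_size,
                                  cell_size=cell_size, crs_label=crs_label)
    return align_stack(layers, scenario_tag="current")


def true_suitability(stack: RasterStack, model: TrueModel) -> GridRaster:
    """Evaluate the generative suitability surface on a stack, in [0, 1]."""
    missing = model.variables() - set(stack.names)
    if missing:
        raise ValueError(f"true model references absent variables {sorted(missing)}")
    grid = stack.grid
    eta = np.full(stack.shape, float(model.intercept))
    for var, c in model.linear_coeffs.items():
        eta += c * stack.layers[var].values
    for var, c in model.quadratic_coeffs.items():
        eta += c * stack.layers[var].values ** 2
    for var, offsets in model.class_offsets.items():
        codes = stack.layers[var].values
        for code, off in offsets.items():
            eta += np.where(codes == code, off, 0.0)
    valid = stack.valid_mask
    if model.prevalence_target is not None:
        t = model.prevalence_target
        f = lambda d: expit(eta[valid] + d).mean() - t
        delta = brentq(f, -50, 50)
        eta = eta + delta
    suit = expit(eta)
    suit[~valid] = 0.0
    return grid.copy_with(values=suit, nodata_mask=~valid)


def sample_occurrences(truth: GridRaster, n: int, seed: int,
                       species: str = "bear") -> OccurrenceSet:
    """Sample presence points with cell probability proportional to truth.

    Cells are drawn with replacement, and one point is placed uniformly
    within each drawn cell, so nearby draws can share a cell (spatial
    thinning later collapses them). Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vals = np.where(truth.valid_mask, truth.values, 0.0).astype(float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("truth surface must lie in [0, 1]")
    total = vals.sum()
    if total <= 0:
        raise ValueError("truth surface is all zero; cannot sample occurrences")
    rng = np.random.default_rng(seed)
    flat_p = (vals / total).ravel()
    idx = rng.choice(flat_p.size, size=n, replace=True, p=flat_p)
    rows, cols = np.unravel_index(idx, truth.shape)
    u = rng.random(n)
    v = rng.random(n)
    xs = truth.origin_x + (cols + u) * truth.cell_size
    ys = truth.origin_y - (rows + v) * truth.cell_size
    return OccurrenceSet(species=species, points=list(zip(xs, ys)), source="synthetic")


def perturb_future(base: RasterStack, spec: ScenarioSpec, seed: int) -> List[RasterStack]:
    """Produce the scenario's climate-model variant stacks from a base stack.

    Each variant applies the scenario's shift/scale to continuous layers plus
    its own Gaussian noise; the land-cover layer has a fixed fraction of its
    (not-yet-degraded) cells reassigned to the degraded class; static layers
    are copied unchanged.
    """
    unknown = (set(spec.shifts) | set(spec.scales)) - set(base.names)
    if unknown:
        raise ValueError(f"scenario references absent variables {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    variants: List[RasterStack] = []
    for i in range(spec.n_gcm_variants):
        layers: Dict[str, GridRaster] = {}
        for name, layer in base.layers.items():
            if name in STATIC_VARS:
                layers[name] = layer.copy_with(values=layer.values.copy())
            elif name in CATEGORICAL_VARS:
                codes = layer.values.copy()
                degraded = spec.degraded_class
                if degraded is None:
                    degraded = int(codes[layer.valid_mask].max())
                eligible = np.flatnonzero(layer.valid_mask.ravel()
                                          & (codes.ravel() != degraded))
                n_valid = int(layer.valid_mask.sum())
                n_change = min(int(round(spec.lucc_transition_fraction * n_valid)),
                               eligible.size)
                if n_change > 0:
                    chosen = rng.choice(eligible, size=n_change, replace=False)
                    flat = codes.ravel()
                    flat[chosen] = degraded
                    codes = flat.reshape(layer.shape)
                layers[name] = layer.copy_with(values=codes)
            else:
                scale = spec.scales.get(name, 1.0)
                shift = spec.shifts.get(name, 0.0)
                vals = scale * layer.values + shift
                if spec.variant_noise_sd > 0:
                    vals = vals + rng.normal(0.0, spec.variant_noise_sd, layer.shape)
                layers[name] = layer.copy_with(values=vals)
        tag = f"{spec.scenario_tag}/gcm{i + 1}"
        variants.append(align_stack(layers, scenario_tag=tag))
    return variants


def generate_regions(shape, k: int, seed: int, cell_size: float = 1.0,
                     crs_label: str = "synthetic") -> GridRaster:
    """Partition the grid into k contiguous regions coded 1..k.

    Regions are nearest-seed (Voronoi) cells around k random seed cells;
    Euclidean Voronoi cells are convex, hence contiguous on the grid.
    """
    n_cells = shape[0] * shape[1]
    if not (2 <= k <= 10):
        raise ValueError("k must lie in [2, 10]")
    if k > n_cells:
        raise ValueError("k exceeds cell count")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n_cells, size=k, replace=False)
    sr, sc = np.unravel_index(seeds, shape)
    rows, cols = np.indices(shape)
    d2 = (rows[..., None] - sr) ** 2 + (cols[..., None] - sc) ** 2
    codes = (np.argmin(d2, axis=-1) + 1).astype(np.int32)
    return GridRaster(values=codes, nodata_mask=np.zeros(shape, dtype=bool),
                      origin_x=0.0, origin_y=shape[0] * cell_size,
                      cell_size=cell_size, crs_label=crs_label)
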