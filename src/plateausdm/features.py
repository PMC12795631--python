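"""Feature construction for the maximum-entropy engine.

Continuous variables expand into linear, quadratic, pairwise-product and
hinge features (hinge knots at the deciles of the training values, both
orientations); categorical variables expand into one indicator per observed
class. Every feature is scaled to [0, 1] using bounds taken from the
training landscape and clamped back to [0, 1] when evaluated on new
scenarios, so projections never extrapolate beyond the trained feature
range.

Per-feature L1 penalties follow the default regularization rule of the
maximum-entropy SDM tool: beta_f = multiplier x base(class, m) x s_f /
sqrt(m), where base(class, m) is a per-feature-class tuning value
interpolated in the number of presences m (tables below) and s_f is the
standard deviation of the feature over the presence sites (floored to keep
the penalty non-degenerate for features nearly constant on presences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._util import log_stage
from .config import RunConfig
from .raster import RasterStack

#: Default L1-regularization interpolation tables, per feature class:
#: (presence counts, base beta values). Flat extrapolation outside the range.
BETA_TABLES: Dict[str, Tuple[Tuple[float, ...], Tuple[float, ...]]] = {
    "lqp": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "categorical": ((0, 10, 17), (0.65, 0.5, 0.25)),
    "hinge": ((0, 1), (0.5, 0.5)),
}

N_HINGE_KNOTS = 9  # deciles 10%..90%

#: Floor on the per-feature presence standard deviation entering the penalty,
#: so features that are (nearly) constant on the presences still carry a
#: non-degenerate L1 weight instead of an unbounded coefficient.
MIN_FEATURE_SD = 0.05


def base_beta(feature_class: str, n_presences: int) -> float:
    """Interpolated base regularization for a feature class at a presence count."""
    xs, ys = BETA_TABLES[feature_class]
    return float(np.interp(n_presences, xs, ys))


@dataclass(frozen=True)
class Feature:
    """One model feature; ``lo``/``hi`` are the training-data scaling bounds."""

    kind: str                      # linear | quadratic | product | hinge_fwd | hinge_rev | categorical
    variables: Tuple[str, ...]
    knot: float | None = None      # hinge knot (raw variable units)
    category: int | None = None    # categorical class code
    lo: float = 0.0
    hi: float = 1.0

    def label(self) -> str:
        v = "*".join(self.variables)
        if self.kind in ("hinge_fwd", "hinge_rev"):
            return f"{self.kind}({v}@{self.knot:.4g})"
        if self.kind == "categorical":
            return f"cat({v}={self.category})"
        return f"{self.kind}({v})"

    def raw_value(self, env: Dict[str, np.ndarray]) -> np.ndarray:
        x = env[self.variables[0]]
        if self.kind == "linear":
            return x
        if self.kind == "quadratic":
            return x * x
        if self.kind == "product":
            return x * env[self.variables[1]]
        if self.kind == "hinge_fwd":
            denom = self.hi - self.knot
            return np.maximum(0.0, x - self.knot) / denom
        if self.kind == "hinge_rev":
            denom = self.knot - self.lo
            return np.maximum(0.0, self.knot - x) / denom
        if self.kind == "categorical":
            return (x == self.category).astype(float)
        raise ValueError(f"unknown feature kind {self.kind!r}")

    def value(self, env: Dict[str, np.ndarray]) -> np.ndarray:
        """Scaled-to-[0,1] feature value, clamped to the training range."""
        f = self.raw_value(env)
        if self.kind in ("linear", "quadratic", "product"):
            f = (f - self.lo) / (self.hi - self.lo)
        return np.clip(f, 0.0, 1.0)


_CLASS_OF_KIND = {
    "linear": "lqp", "quadratic": "lqp", "product": "lqp",
    "hinge_fwd": "hinge", "hinge_rev": "hinge", "categorical": "categorical",
}


@dataclass
class FeatureSet:
    features: List[Feature]
    betas: np.ndarray
    n_presences: int
    continuous: Tuple[str, ...] = ()
    categorical: Tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.features)

    def labels(self) -> List[str]:
        return [f.label() for f in self.features]

    def evaluate(self, env: Dict[str, np.ndarray]) -> np.ndarray:
        """Feature matrix (n_cells x n_features), each column in [0, 1]."""
        return np.column_stack([f.value(env) for f in self.features])


def build_features(stack: RasterStack, presence_cells: Sequence[int],
                   config: RunConfig) -> FeatureSet:
    """Construct the full feature set for a stack and training presences.

    Scaling bounds and hinge-knot deciles are taken over the stack's valid
    cells; per-feature penalties are the class base value interpolated at the
    presence count, times ``config.regularization_multiplier``. Variables
    with zero range contribute no features (logged).
    """
    n_pres = len(presence_cells)
    if n_pres < 1:
        raise ValueError("need at least one presence to build features")
    valid = stack.valid_mask.ravel()
    env = {name: layer.values.ravel()[valid]
           for name, layer in stack.layers.items()}
    cont = []
    for name in stack.continuous_names():
        if env[name].max() - env[name].min() <= 0:
            log_stage("build_features", variable=name, warning="zero range; skipped")
            continue
        cont.append(name)
    feats: List[Feature] = []
    for name in cont:
        x = env[name]
        lo, hi = float(x.min()), float(x.max())
        feats.append(Feature("linear", (name,), lo=lo, hi=hi))
        feats.append(Feature("quadratic", (name,), lo=float((x * x).min()),
                             hi=float((x * x).max())))
    for i, a in enumerate(cont):
        for b in cont[i + 1:]:
            p = env[a] * env[b]
            if p.max() - p.min() > 0:
                feats.append(Feature("product", (a, b), lo=float(p.min()), hi=float(p.max())))
    for name in cont:
        x = env[name]
        lo, hi = float(x.min()), float(x.max())
        knots = np.quantile(x, np.linspace(0.1, 0.9, N_HINGE_KNOTS))
        for k in knots:
            k = float(k)
            if hi - k > 0:
                feats.append(Feature("hinge_fwd", (name,), knot=k, lo=lo, hi=hi))
            if k - lo > 0:
                feats.append(Feature("hinge_rev", (name,), knot=k, lo=lo, hi=hi))
    cats = []
    for name in stack.categorical_names():
        classes = np.unique(env[name])
        if classes.size < 2:
            log_stage("build_features", variable=name, warning="single class; skipped")
            continue
        cats.append(name)
        for c in classes:
            feats.append(Feature("categorical", (name,), category=int(c)))
    pres_idx = np.asarray(presence_cells, dtype=int)
    pres_env = {name: layer.values.ravel()[pres_idx]
                for name, layer in stack.layers.items()}
    betas = np.empty(len(feats))
    for j, f in enumerate(feats):
        base = base_beta(_CLASS_OF_KIND[f.kind], n_pres)
        sd = float(np.std(f.value(pres_env))) if n_pres > 1 else MIN_FEATURE_SD
        sd = max(sd, MIN_FEATURE_SD)
        betas[j] = config.regularization_multiplier * base * sd / np.sqrt(n_pres)
    return FeatureSet(features=feats, betas=betas, n_presences=n_pres,
                      continuous=tuple(cont), categorical=tuple(cats))
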