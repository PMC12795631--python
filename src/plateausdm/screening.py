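"""Collinearity screening of environmental layers.

Pairwise Pearson correlations are computed among continuous layers over the
stack's combined valid mask; variables are then greedily eliminated until no
remaining pair exceeds the cutoff (default |r| > 0.7). Categorical layers
bypass Pearson screening (correlation on class codes is meaningless) and are
always kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pandas as pd

from ._util import log_stage
from .raster import RasterStack


@dataclass
class CorrelationMatrix:
    variables: Tuple[str, ...]
    r: np.ndarray  # symmetric, diagonal 1; NaN rows mark zero-variance layers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


@dataclass
class ScreeningResult:
    kept: List[str]
    dropped: List[Tuple[str, float, str]]  # (name, max |r| at drop time, partner)
    categorical_kept: List[str] = field(default_factory=list)

    def all_kept(self) -> List[str]:
        return self.kept + self.categorical_kept


def pairwise_correlation(stack: RasterStack) -> CorrelationMatrix:
    """Pearson correlations among continuous layers over shared valid cells."""
    names = stack.continuous_names()
    if len(names) < 2:
        raise ValueError("need at least two continuous layers")
    valid = stack.valid_mask
    data = np.stack([stack.layers[n].values[valid] for n in names])
    sds = data.std(axis=1)
    zero_var = sds == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[zero_var, :] = np.nan
    r[:, zero_var] = np.nan
    np.fill_diagonal(r, 1.0)
    if zero_var.any():
        log_stage("pairwise_correlation",
                  zero_variance=",".join(np.array(names)[zero_var]))
    return CorrelationMatrix(variables=tuple(names), r=r)


def select_variables(cm: CorrelationMatrix, cutoff: float = 0.7,
                     categorical: Tuple[str, ...] = ()) -> ScreeningResult:
    """Greedy elimination of collinear variables.

    While any remaining pair has |r| > cutoff, drop the variable with the
    largest mean absolute correlation to the other remaining variables (ties
    broken by reverse lexical order of names, i.e. the lexically greatest
    name is dropped). Zero-variance variables (NaN correlations) are treated
    as maximally droppable and removed first.
    """
    names = list(cm.variables)
    r = np.abs(cm.r.copy())
    active = list(range(len(names)))
    dropped: List[Tuple[str, float, str]] = []

    def offdiag(i, others):
        return np.array([r[i, j] for j in others if j != i])

    while True:
        nan_idx = [i for i in active if np.isnan(offdiag(i, active)).any()] \
            if len(active) > 1 else []
        if nan_idx:
            victim = max(nan_idx, key=lambda i: names[i])
            dropped.append((names[victim], float("nan"), ""))
            active.remove(victim)
            continue
        over = [(i, j) for ii, i in enumerate(active) for j in active[ii + 1:]
                if r[i, j] > cutoff]
        if not over:
            break
        mean_abs = {i: offdiag(i, active).mean() for i in active}
        best = max(mean_abs.values())
        candidates = [i for i in active if mean_abs[i] >= best - 1e-12]
        victim = max(candidates, key=lambda i: names[i])
        others = [j for j in active if j != victim]
        partner = max(others, key=lambda j: r[victim, j])
        dropped.append((names[victim], float(r[victim, partner]), names[partner]))
        active.remove(victim)
    kept = [names[i] for i in active]
    log_stage("select_variables", kept=",".join(kept),
              dropped=",".join(d[0] for d in dropped) or "-")
    return ScreeningResult(kept=kept, dropped=dropped,
                           categorical_kept=list(categorical))


def screen_stack(stack: RasterStack, cutoff: float = 0.7) -> ScreeningResult:
    """Convenience wrapper: correlate, eliminate, keep categoricals."""
    cm = pairwise_correlation(stack)
    return select_variables(cm, cutoff=cutoff, categorical=tuple(stack.categorical_names()))
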