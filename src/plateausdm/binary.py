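"""Threshold-based binary range maps and multi-model consensus.

Continuous suitability is converted to a presence/absence range map with the
maximum training sensitivity-plus-specificity (MTSPS) threshold, and
several climate-model variants of a future scenario are combined by
consensus intersection: a cell counts as suitable in the future only if
every variant agrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .raster import GridRaster, RasterError


@dataclass
class BinaryMap:
    """Boolean range map; ``True`` marks suitable cells (valid cells only)."""

    raster: GridRaster            # boolean values
    threshold_used: float
    species: str = ""
    scenario_tag: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.raster.values

    @property
    def suitable_count(self) -> int:
        return int(self.raster.values.sum())


def mtsps_threshold(scores_presence: Sequence[float],
                    scores_background: Sequence[float]) -> float:
    """Threshold maximizing training sensitivity + specificity.

    Candidates are the sorted unique pooled scores. At threshold t,
    sensitivity is the fraction of presences with score >= t and specificity
    the fraction of background with score < t. Ties in the objective are
    broken by the lowest threshold, so the returned value is itself a
    presence or background score and sensitivity 1 stays attainable.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    cand = np.unique(np.concatenate([sp, sb]))
    sp_sorted = np.sort(sp)
    sb_sorted = np.sort(sb)
    sens = 1.0 - np.searchsorted(sp_sorted, cand, side="left") / sp.size
    spec = np.searchsorted(sb_sorted, cand, side="left") / sb.size
    obj = sens + spec
    # lowest candidate among ties (tolerance absorbs 1-ulp rounding noise)
    best = np.flatnonzero(obj >= obj.max() - 1e-12)[0]
    return float(cand[best])


def binarize(suitability: GridRaster, threshold: float, species: str = "",
             scenario_tag: str = "") -> BinaryMap:
    """Binarize a [0, 1] suitability map; a cell is suitable iff value >= t.

    The boundary is inclusive so that the MTSPS threshold (itself a presence
    score) keeps that presence suitable.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    vals = suitability.values
    valid = suitability.valid_mask
    if np.any((vals[valid] < 0) | (vals[valid] > 1)):
        raise ValueError("suitability values must lie in [0, 1]")
    suitable = (vals >= threshold) & valid
    return BinaryMap(raster=suitability.copy_with(values=suitable),
                     threshold_used=float(threshold), species=species,
                     scenario_tag=scenario_tag)


def consensus_intersection(maps: List[BinaryMap]) -> BinaryMap:
    """Cell-wise AND across climate-model variants of one scenario."""
    if not maps:
        raise ValueError("need at least one binary map")
    first = maps[0]
    out = first.raster.values.copy()
    for m in maps[1:]:
        if not m.raster.same_geometry(first.raster):
            raise RasterError("consensus inputs have mismatched geometry")
        if m.species != first.species:
            raise ValueError("consensus inputs mix species")
        out &= m.raster.values
    tag = first.scenario_tag.split("/")[0] if first.scenario_tag else ""
    return BinaryMap(raster=first.raster.copy_with(values=out),
                     threshold_used=first.threshold_used,
                     species=first.species, scenario_tag=tag)
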