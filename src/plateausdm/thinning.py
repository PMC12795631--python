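"""Grid-based spatial thinning of occurrence records.

Occurrences are binned on a coarse thinning grid (default 10 km x 10 km,
anchored at the environmental raster origin) and one point per occupied
thinning cell is retained, chosen uniformly at random. This reduces spatial
autocorrelation and sampling-effort bias before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import log_stage
from .occurrences import OccurrenceSet
from .raster import GridRaster


@dataclass
class ThinningReport:
    species: str
    n_input: int
    n_retained: int
    n_outside: int
    thinning_cell: float
    seed: int


def thin_occurrences(occ: OccurrenceSet, grid: GridRaster, thinning_cell: float,
                     seed: int) -> tuple[OccurrenceSet, ThinningReport]:
    """Retain one random occurrence per occupied thinning-grid cell.

    Parameters
    ----------
    occ
        Input occurrences; points outside the grid bounds are dropped (and
        counted in the report/log).
    grid
        Raster supplying the origin the thinning grid is anchored to.
    thinning_cell
        Thinning cell side length in map units; must be at least the model
        cell size.
    seed
        Selects which point survives in each multi-point cell. The retained
        COUNT is seed-invariant; output is sorted by thinning-cell index.
    """
    if len(occ) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    if thinning_cell < grid.cell_size:
        raise ValueError("thinning cell must be at least the model cell size")
    pts = np.asarray(occ.points, dtype=float)
    inside = grid.contains(pts[:, 0], pts[:, 1])
    n_outside = int((~inside).sum())
    if n_outside:
        log_stage("thin_occurrences", species=occ.species, dropped_outside=n_outside)
    pts = pts[inside]
    if pts.size == 0:
        raise ValueError("no occurrences inside the grid bounds")
    col = np.floor((pts[:, 0] - grid.origin_x) / thinning_cell).astype(int)
    row = np.floor((grid.origin_y - pts[:, 1]) / thinning_cell).astype(int)
    rng = np.random.default_rng(seed)
    chosen: dict[tuple[int, int], int] = {}
    by_cell: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(row, col)):
        by_cell.setdefault(key, []).append(i)
    for key in sorted(by_cell):
        members = by_cell[key]
        chosen[key] = members[rng.integers(len(members))] if len(members) > 1 else members[0]
    kept = [tuple(pts[chosen[key]]) for key in sorted(chosen)]
    report = ThinningReport(species=occ.species, n_input=len(occ),
                            n_retained=len(kept), n_outside=n_outside,
                            thinning_cell=float(thinning_cell), seed=int(seed))
    log_stage("thin_occurrences", species=occ.species, n_input=report.n_input,
              n_retained=report.n_retained, seed=seed)
    return OccurrenceSet(species=occ.species, points=kept, source=occ.source), report
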