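"""Predator-prey overlay classification and zonal change statistics.

From a predator (brown bear) binary range map and a combined prey map
(marmot / pika), every valid cell is classified as:

* ``S1`` ideal range — predator and prey habitat overlap;
* ``S2`` stepping stone — prey habitat without predator habitat;
* ``S3`` potential conflict zone — predator habitat without prey, where
  bears are pushed toward alternative (often anthropogenic) food sources;
* ``NONE`` — neither.

The module also computes per-region zonal areas and proportions, signed
percent changes between scenarios, and range-centroid shifts (distance and
compass bearing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from ._util import log_stage, round_half_up
from .binary import BinaryMap
from .raster import GridRaster, RasterError

NONE, S1, S2, S3 = 0, 1, 2, 3
CLASS_LABELS = {NONE: "NONE", S1: "S1", S2: "S2", S3: "S3"}


@dataclass
class ScenarioPartition:
    """Categorical raster with codes {0 NONE, 1 S1, 2 S2, 3 S3}."""

    classes: GridRaster
    scenario_tag: str
    prey_rule: str

    def counts(self) -> Dict[str, int]:
        valid = self.classes.valid_mask
        vals = self.classes.values[valid]
        return {CLASS_LABELS[c]: int((vals == c).sum()) for c in (S1, S2, S3, NONE)}


def prey_layer(marmot: BinaryMap, pika: BinaryMap, rule: str = "union") -> BinaryMap:
    """Combine the two prey ranges; ``union`` (either) or ``both`` (and)."""
    if not marmot.raster.same_geometry(pika.raster):
        raise RasterError("prey maps have mismatched geometry")
    if rule == "union":
        vals = marmot.values | pika.values
    elif rule == "both":
        vals = marmot.values & pika.values
    else:
        raise ValueError(f"unknown prey rule {rule!r}; expected 'union' or 'both'")
    return BinaryMap(raster=marmot.raster.copy_with(values=vals),
                     threshold_used=float("nan"), species="prey",
                     scenario_tag=marmot.scenario_tag)


def classify_scenarios(bear: BinaryMap, prey: BinaryMap,
                       prey_rule: str = "union") -> ScenarioPartition:
    """Partition valid cells into S1/S2/S3/NONE from predator and prey maps."""
    if not bear.raster.same_geometry(prey.raster):
        raise RasterError("bear and prey maps have mismatched geometry")
    b = bear.values
    p = prey.values
    codes = np.zeros(b.shape, dtype=np.int32)
    codes[b & p] = S1
    codes[~b & p] = S2
    codes[b & ~p] = S3
    valid = bear.raster.valid_mask
    codes[~valid] = 0
    return ScenarioPartition(classes=bear.raster.copy_with(values=codes),
                             scenario_tag=bear.scenario_tag, prey_rule=prey_rule)


def zonal_areas(target: "BinaryMap | ScenarioPartition", regions: GridRaster,
                cell_area_km2: float = 1.0,
                region_names: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Per-(class, region) areas and within-class proportions.

    Returns a table with columns label, region, scenario_tag, area_km2,
    proportion_pct; proportions are 100 x region area / total class area
    (so they sum to 100 over regions for each class). Classes with no
    cells produce no rows (logged).
    """
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    if isinstance(target, BinaryMap):
        if not target.raster.same_geometry(regions):
            raise RasterError("map and regions have mismatched geometry")
        label_of = {1: target.species or "suitable"}
        codes = target.values.astype(np.int32)
        scenario = target.scenario_tag
        valid = target.raster.valid_mask
    else:
        if not target.classes.same_geometry(regions):
            raise RasterError("partition and regions have mismatched geometry")
        label_of = {c: CLASS_LABELS[c] for c in (S1, S2, S3)}
        codes = target.classes.values
        scenario = target.scenario_tag
        valid = target.classes.valid_mask
    valid = valid & regions.valid_mask
    rows = []
    for code, label in label_of.items():
        in_class = (codes == code) & valid
        total = int(in_class.sum())
        if total == 0:
            log_stage("zonal_areas", label=label, scenario=scenario,
                      warning="class has no cells")
            continue
        region_codes = np.unique(regions.values[valid])
        for rc in region_codes:
            n = int((in_class & (regions.values == rc)).sum())
            rname = region_names[int(rc)] if region_names else f"region{int(rc)}"
            rows.append({"label": label, "region": rname, "scenario_tag": scenario,
                         "area_km2": n * cell_area_km2,
                         "proportion_pct": 100.0 * n / total})
    return pd.DataFrame(rows, columns=["label", "region", "scenario_tag",
                                       "area_km2", "proportion_pct"])


@dataclass
class ChangeMetric:
    label: str
    baseline_km2: float
    future_km2: float

    @property
    def percent_change(self) -> float:
        return percent_change(self.baseline_km2, self.future_km2)


def percent_change(baseline_km2: float, future_km2: float) -> float:
    """Signed percent change 100 (future - baseline) / baseline, 2 decimals."""
    if baseline_km2 <= 0:
        raise ValueError("baseline area must be positive")
    return round_half_up(100.0 * (future_km2 - baseline_km2) / baseline_km2, 2)


def regional_proportion(table: pd.DataFrame, region: str,
                        label: str | None = None,
                        scenario_tag: str | None = None) -> float:
    """Share (%) of one region in a class's total area, 2 decimals.

    ``table`` is a zonal-area table (or any frame with region/area_km2
    columns); optional label / scenario_tag filters select one class when the
    table mixes several.
    """
    df = table
    if label is not None:
        df = df[df["label"] == label]
    if scenario_tag is not None:
        df = df[df["scenario_tag"] == scenario_tag]
    if df.empty:
        raise ValueError("no rows match the requested class")
    if region not in set(df["region"]):
        raise ValueError(f"region {region!r} not present")
    total = df["area_km2"].sum()
    part = df.loc[df["region"] == region, "area_km2"].sum()
    return round_half_up(100.0 * part / total, 2)


def areas_table(label: str, scenario_tag: str,
                areas_by_region: Mapping[str, float]) -> pd.DataFrame:
    """Build a zonal-area table directly from per-region areas (km^2)."""
    total = sum(areas_by_region.values())
    rows = [{"label": label, "region": r, "scenario_tag": scenario_tag,
             "area_km2": a, "proportion_pct": 100.0 * a / total if total else 0.0}
            for r, a in areas_by_region.items()]
    return pd.DataFrame(rows)


@dataclass
class Centroid:
    x: float
    y: float
    crs_label: str = "synthetic"


def centroid(binmap: BinaryMap) -> Centroid:
    """Unweighted mean center of the suitable cells' centers."""
    rows, cols = np.nonzero(binmap.values)
    if rows.size == 0:
        raise ValueError("cannot take the centroid of an empty range")
    xs, ys = binmap.raster.cell_center(rows, cols)
    return Centroid(x=float(xs.mean()), y=float(ys.mean()),
                    crs_label=binmap.raster.crs_label)


def centroid_shift(a: Centroid, b: Centroid) -> tuple[float, float]:
    """Displacement from a to b: (Euclidean distance, bearing clockwise from north).

    A zero-length shift reports bearing 0 (logged as undefined).
    """
    if a.crs_label != b.crs_label:
        raise ValueError("centroids are in different coordinate systems")
    dx = b.x - a.x
    dy = b.y - a.y
    dist = float(np.hypot(dx, dy))
    if dist == 0.0:
        log_stage("centroid_shift", warning="zero shift; bearing undefined")
        return 0.0, 0.0
    bearing = float(np.degrees(np.arctan2(dx, dy)) % 360.0)
    return dist, bearing
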