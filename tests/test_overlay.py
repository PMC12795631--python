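"""S1/S2/S3 classification, zonal statistics, changes and centroid shifts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plateausdm import (areas_table, centroid, centroid_shift,
                        classify_scenarios, percent_change, prey_layer,
                        regional_proportion, zonal_areas)
from plateausdm.binary import BinaryMap
from plateausdm.overlay import NONE, S1, S2, S3, Centroid

from conftest import make_raster


def _bm(values, species="bear", tag="current"):
    return BinaryMap(raster=make_raster(np.asarray(values, dtype=bool)),
                     threshold_used=0.5, species=species, scenario_tag=tag)


def test_prey_rules_match_boolean_oracle():
    rng = np.random.default_rng(0)
    m = rng.random((12, 12)) > 0.5
    p = rng.random((12, 12)) > 0.5
    union = prey_layer(_bm(m, "marmot"), _bm(p, "pika"), "union")
    both = prey_layer(_bm(m, "marmot"), _bm(p, "pika"), "both")
    assert np.array_equal(union.values, m | p)
    assert np.array_equal(both.values, m & p)
    with pytest.raises(ValueError, match="unknown prey rule"):
        prey_layer(_bm(m, "marmot"), _bm(p, "pika"), "xor")


def test_classification_truth_table():
    bear = _bm([[True, False], [True, False]])
    prey = _bm([[True, True], [False, False]], "prey")
    part = classify_scenarios(bear, prey)
    assert part.classes.values.tolist() == [[S1, S2], [S3, NONE]]


def test_partition_identities_on_random_maps():
    """|S1|+|S3| = |bear|, |S1|+|S2| = |prey|; classes disjoint & complete."""
    rng = np.random.default_rng(1)
    for _ in range(50):
        b = rng.random((15, 15)) > rng.random()
        p = rng.random((15, 15)) > rng.random()
        part = classify_scenarios(_bm(b), _bm(p, "prey"))
        c = part.counts()
        assert c["S1"] + c["S3"] == int(b.sum())
        assert c["S1"] + c["S2"] == int(p.sum())
        assert sum(c.values()) == part.classes.values.size


def test_zonal_areas_hand_count():
    suit = np.zeros((10, 10), dtype=bool)
    suit[:1, :7] = True          # 7 cells in region A (top half)
    suit[9, :3] = True           # 3 cells in region B (bottom half)
    regions = make_raster(np.repeat([[1], [2]], [5, 5], axis=0) * np.ones((10, 10), int))
    za = zonal_areas(_bm(suit), regions, cell_area_km2=1.0)
    a = za[za["region"] == "region1"].iloc[0]
    b = za[za["region"] == "region2"].iloc[0]
    assert (a["area_km2"], a["proportion_pct"]) == (7.0, 70.0)
    assert (b["area_km2"], b["proportion_pct"]) == (3.0, 30.0)


def test_zonal_single_region_is_100_percent():
    suit = np.ones((6, 6), dtype=bool)
    regions = make_raster(np.ones((6, 6), dtype=int))
    za = zonal_areas(_bm(suit), regions, 1.0)
    assert za["proportion_pct"].tolist() == [100.0]


def test_zonal_empty_class_yields_no_rows():
    suit = np.zeros((6, 6), dtype=bool)
    regions = make_raster(np.ones((6, 6), dtype=int))
    za = zonal_areas(_bm(suit), regions, 1.0)
    assert za.empty


def test_zonal_areas_sum_to_class_total():
    rng = np.random.default_rng(2)
    suit = rng.random((20, 20)) > 0.6
    regions = make_raster(rng.integers(1, 5, (20, 20)))
    za = zonal_areas(_bm(suit), regions, 2.5)
    assert za["area_km2"].sum() == pytest.approx(suit.sum() * 2.5)
    assert za["proportion_pct"].sum() == pytest.approx(100.0, abs=0.05)


@pytest.mark.parametrize("base,fut,expected", [
    (672069.89, 524734.89, -21.92),
    (673196.01, 787833.15, 17.03),
    (100.0, 100.0, 0.0),
])
def test_percent_change_matches_reported_values(base, fut, expected):
    assert percent_change(base, fut) == pytest.approx(expected, abs=0.005)


@settings(derandomize=True, max_examples=100)
@given(base=st.floats(1e-3, 1e7), p=st.floats(-99.99, 400.0))
def test_percent_change_roundtrip_property(base, p):
    assert percent_change(base, base * (1 + p / 100)) == pytest.approx(p, abs=0.005)


def test_percent_change_zero_baseline_rejected():
    with pytest.raises(ValueError):
        percent_change(0.0, 10.0)


def test_regional_proportion_on_area_table():
    table = areas_table("marmot", "current",
                        {"A": 600.0, "B": 300.0, "C": 100.0})
    assert regional_proportion(table, "A") == pytest.approx(60.0)
    total = sum(regional_proportion(table, r) for r in ("A", "B", "C"))
    assert total == pytest.approx(100.0, abs=0.05)
    with pytest.raises(ValueError, match="not present"):
        regional_proportion(table, "D")


def test_centroid_closed_forms():
    one = np.zeros((9, 9), dtype=bool)
    one[4, 6] = True
    c = centroid(_bm(one))
    assert (c.x, c.y) == (6.5, 9 - 4.5)
    rng = np.random.default_rng(3)
    many = rng.random((9, 9)) > 0.5
    c2 = centroid(_bm(many))
    rows, cols = np.nonzero(many)
    assert c2.x == pytest.approx((cols + 0.5).mean())
    assert c2.y == pytest.approx((9 - rows - 0.5).mean())


def test_centroid_symmetric_pair_at_origin():
    a = Centroid(-3.0, 4.0)
    b = Centroid(3.0, -4.0)
    mid_dist, _ = centroid_shift(a, b)
    assert mid_dist == pytest.approx(10.0)


def test_centroid_shift_bearing_quadrants():
    origin = Centroid(0.0, 0.0)
    dist, bearing = centroid_shift(origin, Centroid(-1.0, 1.0))
    assert bearing == pytest.approx(315.0)        # northwest
    assert dist == pytest.approx(np.sqrt(2))
    _, east = centroid_shift(origin, Centroid(1.0, 0.0))
    assert east == pytest.approx(90.0)
    d0, b0 = centroid_shift(origin, Centroid(0.0, 0.0))
    assert (d0, b0) == (0.0, 0.0)


def test_centroid_empty_map_rejected():
    with pytest.raises(ValueError, match="empty"):
        centroid(_bm(np.zeros((5, 5), dtype=bool)))
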