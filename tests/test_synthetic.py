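"""Synthetic landscape generators: determinism, standardization, truth
surfaces and scenario perturbations."""

import numpy as np
import pytest
from scipy.stats import chisquare

from plateausdm import (GridRaster, ScenarioSpec, TrueModel, generate_env_stack,
                        generate_regions, perturb_future, sample_occurrences,
                        true_suitability)

from conftest import make_raster


def test_generator_deterministic_under_seed():
    a = generate_env_stack((50, 50), ["Bio12", "ELE"], 10.0, seed=1)
    b = generate_env_stack((50, 50), ["Bio12", "ELE"], 10.0, seed=1)
    for name in a.names:
        assert np.array_equal(a.layers[name].values, b.layers[name].values)


def test_continuous_layers_standardized():
    stack = generate_env_stack((50, 50), ["Bio12", "ELE"], 10.0, seed=2)
    for name in stack.continuous_names():
        v = stack.layers[name].values[stack.valid_mask]
        assert abs(v.mean()) < 0.05
        assert abs(v.std() - 1) < 0.05


def test_lucc_layer_classes():
    stack = generate_env_stack((30, 30), ["LUCC"], 3.0, seed=3, n_lucc_classes=4)
    codes = np.unique(stack.layers["LUCC"].values)
    assert set(codes) <= {1, 2, 3, 4}
    assert len(codes) == 4


def test_unknown_variable_rejected():
    with pytest.raises(ValueError, match="unknown variable"):
        generate_env_stack((30, 30), ["Bio1"], 3.0, seed=1)


def test_true_suitability_closed_forms(cont_stack):
    # all-zero model -> constant 0.5
    flat = true_suitability(cont_stack, TrueModel())
    assert np.allclose(flat.values[flat.valid_mask], 0.5)
    # very negative intercept -> suitability approaches 0 monotonically
    lo = true_suitability(cont_stack, TrueModel(intercept=-10))
    lower = true_suitability(cont_stack, TrueModel(intercept=-20))
    assert lo.values.max() < 1e-3
    assert np.all(lower.values[lower.valid_mask] <= lo.values[lo.valid_mask])


def test_true_suitability_single_cell_value():
    # invlogit(2*1 - 1) = invlogit(1) ~ 0.7311 on a constructed one-hot layer
    vals = np.zeros((20, 20))
    vals[0, 0] = 1.0
    layer = make_raster(vals)
    from plateausdm import align_stack
    stack = align_stack({"Bio12": layer})
    s = true_suitability(stack, TrueModel(linear_coeffs={"Bio12": 2.0}, intercept=-1.0))
    assert s.values[0, 0] == pytest.approx(0.73105857863, abs=1e-9)


def test_true_suitability_monotone_in_positive_coefficient():
    grad = np.tile(np.linspace(-2, 2, 40), (40, 1))
    from plateausdm import align_stack
    stack = align_stack({"Bio12": make_raster(grad)})
    s = true_suitability(stack, TrueModel(linear_coeffs={"Bio12": 1.5}))
    rowvals = s.values[0]
    assert np.all(np.diff(rowvals) > 0)


def test_sample_occurrences_single_hot_cell():
    vals = np.zeros((25, 25))
    vals[7, 9] = 1.0
    truth = make_raster(vals)
    occ = sample_occurrences(truth, 10, seed=4)
    rows, cols = truth.point_to_cell(*np.array(occ.points).T)
    assert np.all(rows == 7) and np.all(cols == 9)


def test_sample_occurrences_uniform_truth_multinomial():
    truth = make_raster(np.ones((5, 5)))
    occ = sample_occurrences(truth, 1000, seed=5)
    rows, cols = truth.point_to_cell(*np.array(occ.points).T)
    counts = np.bincount(rows * 5 + cols, minlength=25)
    assert chisquare(counts).pvalue > 0.001


def test_sample_occurrences_deterministic():
    truth = make_raster(np.random.default_rng(0).random((25, 25)))
    a = sample_occurrences(truth, 50, seed=6)
    b = sample_occurrences(truth, 50, seed=6)
    assert a.points == b.points


def test_sample_occurrences_all_zero_truth_raises():
    with pytest.raises(ValueError, match="all zero"):
        sample_occurrences(make_raster(np.zeros((25, 25))), 5, seed=1)


def test_identity_perturbation_returns_base(small_stack):
    spec = ScenarioSpec("RCP2.6", n_gcm_variants=2)
    variants = perturb_future(small_stack, spec, seed=7)
    assert len(variants) == 2
    for v in variants:
        for name in small_stack.names:
            assert np.array_equal(v.layers[name].values, small_stack.layers[name].values)


def test_shift_moves_mean_exactly(small_stack):
    spec = ScenarioSpec("RCP4.5", shifts={"Bio12": 1.0})
    (v,) = perturb_future(small_stack, spec, seed=8)
    d = v.layers["Bio12"].values - small_stack.layers["Bio12"].values
    assert abs(d.mean() - 1.0) < 1e-9
    assert np.allclose(v.layers["ELE"].values, small_stack.layers["ELE"].values)


def test_lucc_transition_count():
    stack = generate_env_stack((20, 20), ["LUCC"], 3.0, seed=9)
    spec = ScenarioSpec("RCP8.5", lucc_transition_fraction=0.25, degraded_class=4)
    (v,) = perturb_future(stack, spec, seed=10)
    changed = int((v.layers["LUCC"].values != stack.layers["LUCC"].values).sum())
    assert changed == 100  # 25% of 400 cells


def test_static_layers_copied_unchanged():
    stack = generate_env_stack((25, 25), ["Bio12", "ELE", "HII"], 3.0, seed=12)
    spec = ScenarioSpec("RCP8.5", shifts={"Bio12": 0.5}, scales={"Bio12": 1.2},
                        variant_noise_sd=0.3)
    (v,) = perturb_future(stack, spec, seed=13)
    for name in ("ELE", "HII"):
        assert np.array_equal(v.layers[name].values, stack.layers[name].values)


def test_regions_partition_and_determinism():
    r1 = generate_regions((10, 10), 2, seed=14)
    r2 = generate_regions((10, 10), 2, seed=14)
    assert np.array_equal(r1.values, r2.values)
    assert set(np.unique(r1.values)) == {1, 2}
    # region areas sum to total valid area
    counts = np.bincount(r1.values.ravel())[1:]
    assert counts.sum() == 100


def test_regions_contiguous():
    from scipy.ndimage import label
    r = generate_regions((30, 30), 6, seed=15)
    for code in range(1, 7):
        _, n = label(r.values == code)
        assert n == 1
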