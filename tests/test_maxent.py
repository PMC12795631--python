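"""Maximum-entropy engine: fitting, prediction, AUC, contributions,
background sampling and replicated evaluation."""

import numpy as np
import pytest
from scipy.special import logsumexp

from plateausdm import (OccurrenceSet, RunConfig, TrueModel, build_features,
                        evaluate_auc, fit_maxent, generate_env_stack,
                        percent_contribution, predict_logistic, predict_raw,
                        run_replicates, sample_background, sample_occurrences,
                        true_suitability, thin_occurrences)
from plateausdm.features import Feature, FeatureSet
from plateausdm.maxent import (env_at_cells, points_to_cells, valid_cells,
                               variable_effect_direction)


@pytest.fixture(scope="module")
def fitted():
    """One signal-bearing fit shared by several structural assertions."""
    cfg = RunConfig(random_seed=1, background_n=800)
    stack = generate_env_stack((40, 40), ["Bio12", "ELE"], 4.0, seed=5)
    truth = true_suitability(stack, TrueModel(linear_coeffs={"Bio12": 2.0},
                                              intercept=-1.0))
    occ = sample_occurrences(truth, 150, seed=3)
    pres = points_to_cells(stack, occ)
    bg = sample_background(stack, 800, seed=11)
    feats = build_features(stack, pres, cfg)
    model = fit_maxent(feats, stack, pres, bg, cfg)
    return cfg, stack, pres, bg, model


def test_raw_normalizes_over_training_landscape(fitted):
    _, stack, _, _, model = fitted
    raw = predict_raw(model, stack)
    total = raw.values.ravel()[model.train_cells].sum()
    assert total == pytest.approx(1.0, abs=1e-6)


def test_gain_trace_non_decreasing(fitted):
    *_, model = fitted
    assert np.all(np.diff(model.gain_trace) >= -1e-12)


def test_positive_effect_direction_recovered(fitted):
    *_, model = fitted
    assert variable_effect_direction(model, "Bio12") == 1.0


def test_one_parameter_fit_matches_grid_search_oracle(fitted):
    """Restricting to a single linear feature, coordinate descent must agree
    with a brute-force grid search of the same penalized gain."""
    cfg, stack, pres, bg, _ = fitted
    x = stack.layers["Bio12"].values
    lin = Feature("linear", ("Bio12",), lo=float(x.min()), hi=float(x.max()))
    full = build_features(stack, pres, cfg)
    fs = FeatureSet(features=[lin], betas=full.betas[:1].copy(),
                    n_presences=len(pres), continuous=("Bio12",))
    model = fit_maxent(fs, stack, pres, bg, cfg)
    land = model.train_cells
    F = fs.evaluate(env_at_cells(stack, land))[:, 0]
    pbar = F[np.searchsorted(land, pres)].mean()
    beta = fs.betas[0]
    grid = np.linspace(-20, 20, 8001)
    gains = [pbar * l - (logsumexp(l * F) - np.log(F.size)) - beta * abs(l)
             for l in grid]
    lam_star = grid[int(np.argmax(gains))]
    assert model.lam[0] == pytest.approx(lam_star, abs=0.01)
    assert model.lam[0] > 0  # presences concentrate at high Bio12


def test_no_signal_fit_is_near_uniform():
    """Presences drawn uniformly from the landscape: the penalized gain stays
    near zero and the model has no held-out discrimination (the training
    presences themselves score slightly above 0.5 from benign overfitting)."""
    cfg = RunConfig(random_seed=2, background_n=800)
    stack = generate_env_stack((40, 40), ["Bio12", "ELE"], 4.0, seed=6)
    cells = valid_cells(stack)
    rng = np.random.default_rng(7)
    draw = rng.choice(cells, 200, replace=False)
    pres, held_out = np.sort(draw[:100]), np.sort(draw[100:])
    bg = sample_background(stack, 800, seed=8)
    feats = build_features(stack, pres, cfg)
    model = fit_maxent(feats, stack, pres, bg, cfg)
    assert model.metadata["final_gain"] < 0.05
    lg = predict_logistic(model, stack).values.ravel()
    auc = evaluate_auc(lg[held_out], lg[bg])
    assert abs(auc - 0.5) < 0.07


def test_uniform_model_logistic_is_tau_everywhere():
    """lambda = 0: raw = 1/N, H = log N, logistic = tau = 0.5 exactly."""
    cfg = RunConfig(random_seed=3, background_n=400)
    stack = generate_env_stack((30, 30), ["Bio12"], 3.0, seed=9)
    x = stack.layers["Bio12"].values
    lin = Feature("linear", ("Bio12",), lo=float(x.min()), hi=float(x.max()))
    fs = FeatureSet(features=[lin], betas=np.array([1e6]),  # infinite penalty pins lambda at 0
                    n_presences=10, continuous=("Bio12",))
    cells = valid_cells(stack)
    pres = cells[:10]
    bg = cells
    model = fit_maxent(fs, stack, pres, bg, cfg)
    assert np.all(model.lam == 0)
    N = model.train_cells.size
    assert model.entropy == pytest.approx(np.log(N), abs=1e-9)
    raw = predict_raw(model, stack)
    assert np.allclose(raw.values[raw.valid_mask], 1.0 / N)
    lg = predict_logistic(model, stack)
    assert np.allclose(lg.values[lg.valid_mask], 0.5, atol=1e-12)


def test_projection_beyond_training_range_is_clamped_finite(fitted):
    cfg, stack, pres, bg, model = fitted
    shifted = generate_env_stack((40, 40), ["Bio12", "ELE"], 4.0, seed=5)
    for name in shifted.names:
        shifted.layers[name].values[:] = shifted.layers[name].values * 5 + 3
    raw = predict_raw(model, shifted)
    assert np.all(np.isfinite(raw.values))


def test_missing_variable_rejected(fitted):
    *_, model = fitted
    stack = generate_env_stack((40, 40), ["Bio12"], 4.0, seed=5)
    with pytest.raises(ValueError, match="lacks model variables"):
        predict_raw(model, stack)


# -- AUC ------------------------------------------------------------------


def _auc_bruteforce(sp, sb):
    wins = sum((a > b) + 0.5 * (a == b) for a in sp for b in sb)
    return wins / (len(sp) * len(sb))


@pytest.mark.parametrize("sp,sb,expected", [
    ([0.8, 0.9], [0.1, 0.2], 1.0),
    ([0.5, 0.5], [0.5, 0.5], 0.5),
    ([0.3, 0.7], [0.5], 0.5),
])
def test_auc_examples(sp, sb, expected):
    assert evaluate_auc(sp, sb) == pytest.approx(expected)


def test_auc_equals_pair_counting_oracle():
    rng = np.random.default_rng(10)
    for _ in range(20):
        sp = rng.integers(0, 20, rng.integers(1, 200)) / 20
        sb = rng.integers(0, 20, rng.integers(1, 200)) / 20
        assert evaluate_auc(sp, sb) == pytest.approx(_auc_bruteforce(list(sp), list(sb)))


def test_auc_empty_rejected():
    with pytest.raises(ValueError):
        evaluate_auc([], [0.5])


# -- contributions --------------------------------------------------------


def test_single_variable_model_gets_full_contribution(fitted):
    cfg, stack, pres, bg, _ = fitted
    x = stack.layers["Bio12"].values
    lin = Feature("linear", ("Bio12",), lo=float(x.min()), hi=float(x.max()))
    full = build_features(stack, pres, cfg)
    fs = FeatureSet(features=[lin], betas=full.betas[:1].copy(),
                    n_presences=len(pres), continuous=("Bio12",))
    model = fit_maxent(fs, stack, pres, bg, cfg)
    pc = percent_contribution(model)
    assert pc["Bio12"] == pytest.approx(100.0)


def test_contributions_sum_to_100(fitted):
    *_, model = fitted
    assert sum(percent_contribution(model).values()) == pytest.approx(100.0, abs=0.01)


def test_symmetric_variables_split_contribution_evenly():
    """Two independent, equally informative variables share the credit."""
    cfg = RunConfig(random_seed=4, background_n=800)
    shares = []
    for seed in range(3):
        stack = generate_env_stack((40, 40), ["Bio12", "ELE"], 4.0, seed=40 + seed)
        truth = true_suitability(stack, TrueModel(
            linear_coeffs={"Bio12": 1.5, "ELE": 1.5}, intercept=-1.5))
        occ = sample_occurrences(truth, 180, seed=50 + seed)
        pres = points_to_cells(stack, occ)
        bg = sample_background(stack, 800, seed=60 + seed)
        model = fit_maxent(build_features(stack, pres, cfg), stack, pres, bg, cfg)
        shares.append(percent_contribution(model)["Bio12"])
    assert 35 < float(np.mean(shares)) < 65


# -- background sampling --------------------------------------------------


def test_background_oversized_request_returns_all_cells(cont_stack):
    n_valid = int(cont_stack.valid_mask.sum())
    bg = sample_background(cont_stack, n_valid + 500, seed=1)
    assert bg.size == n_valid


def test_background_deterministic(cont_stack):
    a = sample_background(cont_stack, 100, seed=2)
    b = sample_background(cont_stack, 100, seed=2)
    assert np.array_equal(a, b)


def test_background_inclusion_matches_hypergeometric():
    """Per-cell inclusion frequency over many seeds ~ n/N (binomial 3 sd)."""
    stack = generate_env_stack((25, 40), ["Bio12"], 3.0, seed=12)  # 1000 cells
    n, N, trials = 100, 1000, 200
    counts = np.zeros(N)
    for s in range(trials):
        counts[sample_background(stack, n, seed=s)] += 1
    p = n / N
    sd = np.sqrt(trials * p * (1 - p))
    assert np.all(np.abs(counts - trials * p) <= max(6 * sd, 25))
    assert abs(counts.mean() - trials * p) < 3 * sd / np.sqrt(N) * 10


# -- replicated evaluation ------------------------------------------------


def test_replicate_split_sizes():
    """8 presences at 25% test fraction -> 6 train / 2 test."""
    n, frac = 8, 0.25
    n_test = max(1, int(np.floor(n * frac)))
    assert (n - n_test, n_test) == (6, 2)


def test_run_replicates_deterministic_and_reports(fast_config):
    stack = generate_env_stack((40, 40), ["Bio12", "ELE"], 4.0, seed=13)
    truth = true_suitability(stack, TrueModel(linear_coeffs={"Bio12": 2.0},
                                              intercept=-1.0))
    occ = sample_occurrences(truth, 120, seed=14)
    thinned, _ = thin_occurrences(occ, stack.grid, 2.0, seed=15)
    r1 = run_replicates(stack, thinned, fast_config, master_seed=77)
    r2 = run_replicates(stack, thinned, fast_config, master_seed=77)
    assert r1.report.per_replicate.equals(r2.report.per_replicate)
    assert np.array_equal(r1.mean_logistic.values, r2.mean_logistic.values)
    df = r1.report.per_replicate
    assert len(df) == fast_config.replicates
    assert ((df["train_auc"] >= 0) & (df["train_auc"] <= 1)).all()
    assert ((df["mtsps_threshold"] >= 0) & (df["mtsps_threshold"] <= 1)).all()
    assert sum(r1.report.percent_contribution.values()) == pytest.approx(100, abs=0.01)


def test_run_replicates_too_few_presences_rejected(fast_config):
    stack = generate_env_stack((40, 40), ["Bio12", "ELE"], 4.0, seed=16)
    occ = OccurrenceSet("bear", [(5.5, 5.5), (10.5, 10.5), (20.5, 20.5)])
    with pytest.raises(ValueError, match="at least 8"):
        run_replicates(stack, occ, fast_config)
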