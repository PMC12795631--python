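"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs distribution q(x) = exp(eta(x)) / Z over the training
landscape (background plus presence cells), eta(x) = sum_f lambda_f f(x),
fitted by maximizing the L1-penalized gain

    gain = mean over presences of eta(x)  -  log mean_x exp(eta(x))
           -  sum_f beta_f |lambda_f|,

which at lambda = 0 is exactly 0 (the uniform distribution). The optimizer
is cyclic coordinate descent with an exact 1-D line search per feature:
along one coordinate the gain is strictly concave, so a bounded scalar
search finds the global 1-D optimum, and only improving steps are accepted
— the gain trace is non-decreasing by construction. Gain increments are
credited to each updated feature's source variable(s), which after
normalization gives the familiar percent-contribution table.

Raw output divides exp(eta) by the stored normalizer Z; the logistic output
p = tau e^H raw / (1 - tau + tau e^H raw) calibrates raw suitability with
the entropy H of the fitted distribution and the prevalence constant tau
(default 0.5, under which a cell indistinguishable from the landscape
average scores 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import rankdata

from ._util import derive_seed, log_stage
from .binary import mtsps_threshold
from .config import RunConfig
from .features import FeatureSet, build_features
from .occurrences import OccurrenceSet
from .raster import GridRaster, RasterStack

_LAMBDA_BOUND = 60.0  # coefficients are bounded; features live in [0, 1]


# -- cell plumbing --------------------------------------------------------


def valid_cells(stack: RasterStack) -> np.ndarray:
    """Flat indices of the stack's combined-valid cells."""
    return np.flatnonzero(stack.valid_mask.ravel())


def env_at_cells(stack: RasterStack, cells: np.ndarray) -> Dict[str, np.ndarray]:
    return {name: layer.values.ravel()[cells] for name, layer in stack.layers.items()}


def points_to_cells(stack: RasterStack, occ: OccurrenceSet,
                    dedupe: bool = True) -> np.ndarray:
    """Map occurrence points to flat cell indices on the stack grid.

    Points outside the grid or on nodata cells are dropped with a log line;
    duplicate cells are collapsed by default (one presence per model cell).
    """
    grid = stack.grid
    pts = np.asarray(occ.points, dtype=float)
    inside = grid.contains(pts[:, 0], pts[:, 1])
    rows, cols = grid.point_to_cell(pts[inside, 0], pts[inside, 1])
    flat = rows * stack.shape[1] + cols
    on_valid = stack.valid_mask.ravel()[flat]
    cells = flat[on_valid]
    n_lost = len(pts) - int(on_valid.sum())
    if n_lost:
        log_stage("points_to_cells", species=occ.species, dropped=n_lost)
    if dedupe:
        cells = np.unique(cells)
    return cells


def sample_background(stack: RasterStack, n: int, seed: int) -> np.ndarray:
    """Uniform sample of n valid cells without replacement (all if fewer)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cells = valid_cells(stack)
    if cells.size == 0:
        raise ValueError("stack has no valid cells")
    if n >= cells.size:
        log_stage("sample_background", requested=n, available=cells.size,
                  note="using all valid cells")
        return cells.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(cells, size=n, replace=False))


# -- model ----------------------------------------------------------------


@dataclass
class MaxEntModel:
    feature_set: FeatureSet
    lam: np.ndarray
    log_Z: float                  # log sum over training landscape of exp(eta)
    entropy: float                # H of the fitted raw distribution
    tau: float
    train_cells: np.ndarray       # unique training-landscape flat cell indices
    gain_credits: Dict[str, float]
    gain_trace: np.ndarray        # penalized gain after each full cycle
    metadata: Dict = field(default_factory=dict)

    def eta(self, env: Dict[str, np.ndarray]) -> np.ndarray:
        return self.feature_set.evaluate(env) @ self.lam


def fit_maxent(features: FeatureSet, stack: RasterStack,
               presence_cells: Sequence[int], background_cells: Sequence[int],
               config: RunConfig) -> MaxEntModel:
    """Fit the penalized maximum-entropy model by coordinate descent.

    The training landscape is the union of background and presence cells.
    Convergence is declared when a full cycle improves the gain by less than
    ``config.convergence_tol``; otherwise the best iterate is returned with
    ``converged=False`` in the metadata.
    """
    presence_cells = np.asarray(presence_cells, dtype=int)
    background_cells = np.asarray(background_cells, dtype=int)
    if presence_cells.size < 2:
        raise ValueError("need at least two presences")
    land = np.unique(np.concatenate([presence_cells, background_cells]))
    pres_rows = np.searchsorted(land, presence_cells)
    env = env_at_cells(stack, land)
    F = features.evaluate(env)
    N, d = F.shape
    betas = features.betas
    pbar = F[pres_rows].mean(axis=0)
    logN = np.log(N)

    lam = np.zeros(d)
    eta = np.zeros(N)
    credits = np.zeros(d)

    def penalized_gain() -> float:
        return (pbar @ lam) - (logsumexp(eta) - logN) - betas @ np.abs(lam)

    gain = 0.0
    trace = [gain]
    converged = False
    n_cycles = 0
    for cycle in range(config.max_iterations):
        n_cycles = cycle + 1
        cycle_start_gain = gain
        for j in range(d):
            m = eta.max()
            w = np.exp(eta - m)
            W = w.sum()
            fj = F[:, j]
            grad = pbar[j] - (w @ fj) / W
            # subgradient optimality: a zero coefficient stays zero
            if lam[j] == 0.0 and abs(grad) <= betas[j] + 1e-12:
                continue

            def neg_h(delta, fj=fj, w=w, W=W, j=j):
                move = np.log((w @ np.exp(delta * fj)) / W)
                pen = betas[j] * (abs(lam[j] + delta) - abs(lam[j]))
                return -(pbar[j] * delta - move - pen)

            lo = -_LAMBDA_BOUND - lam[j]
            hi = _LAMBDA_BOUND - lam[j]
            res = minimize_scalar(neg_h, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-7})
            delta = float(res.x)
            improve = -float(res.fun)
            if improve > 1e-12:
                lam[j] += delta
                eta = eta + delta * fj
                gain += improve
                credits[j] += improve
        trace.append(gain)
        if gain - cycle_start_gain < config.convergence_tol:
            converged = True
            break
    if not converged:
        log_stage("fit_maxent", warning="max_iterations reached before convergence")

    log_Z = float(logsumexp(eta))
    log_raw = eta - log_Z
    entropy = float(-(np.exp(log_raw) @ log_raw))
    per_var: Dict[str, float] = {}
    for j, feat in enumerate(features.features):
        share = credits[j] / len(feat.variables)
        for v in feat.variables:
            per_var[v] = per_var.get(v, 0.0) + share
    meta = dict(n_presence=int(presence_cells.size),
                n_background=int(background_cells.size),
                iterations=n_cycles, converged=converged,
                final_gain=float(penalized_gain()))
    return MaxEntModel(feature_set=features, lam=lam, log_Z=log_Z,
                       entropy=entropy, tau=config.tau, train_cells=land,
                       gain_credits=per_var, gain_trace=np.asarray(trace),
                       metadata=meta)


def predict_raw(model: MaxEntModel, stack: RasterStack) -> GridRaster:
    """Raw output exp(eta)/Z on the stack's valid cells.

    On the training stack the raw values sum to 1 over the training
    landscape. Features are clamped to their training [0, 1] range, so
    projection to new scenarios never extrapolates.
    """
    missing = (set(model.feature_set.continuous) | set(model.feature_set.categorical)) \
        - set(stack.names)
    if missing:
        raise ValueError(f"stack lacks model variables {sorted(missing)}")
    cells = valid_cells(stack)
    eta = model.eta(env_at_cells(stack, cells))
    raw = np.exp(eta - model.log_Z)
    out = np.zeros(stack.shape)
    out.ravel()[cells] = raw
    return stack.grid.copy_with(values=out, nodata_mask=~stack.valid_mask)


def predict_logistic(model: MaxEntModel, stack: RasterStack) -> GridRaster:
    """Logistic suitability in (0, 1): tau e^H raw / (1 - tau + tau e^H raw)."""
    raw = predict_raw(model, stack)
    r = raw.values
    num = model.tau * np.exp(model.entropy) * r
    p = num / ((1.0 - model.tau) + num)
    p[~raw.valid_mask] = 0.0
    return raw.copy_with(values=p)


def evaluate_auc(scores_presence: Sequence[float],
                 scores_background: Sequence[float]) -> float:
    """Rank-based AUC: P(presence outscores background), ties count 0.5."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("score lists must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    r1 = ranks[:sp.size].sum()
    return float((r1 - sp.size * (sp.size + 1) / 2) / (sp.size * sb.size))


def percent_contribution(model: MaxEntModel) -> Dict[str, float]:
    """Per-variable percent of positive training-gain increments, summing to 100."""
    credits = {v: max(0.0, c) for v, c in model.gain_credits.items()}
    total = sum(credits.values())
    if total <= 0:
        log_stage("percent_contribution", warning="zero total gain; uniform split")
        vars_ = list(model.feature_set.continuous) + list(model.feature_set.categorical)
        return {v: 100.0 / len(vars_) for v in vars_}
    return {v: 100.0 * c / total for v, c in credits.items()}


# -- replicated evaluation ------------------------------------------------


@dataclass
class EvalReport:
    per_replicate: pd.DataFrame    # replicate, train_auc, test_auc, mtsps_threshold
    percent_contribution: Dict[str, float]

    @property
    def mean_test_auc(self) -> float:
        return float(self.per_replicate["test_auc"].mean())

    @property
    def mean_train_auc(self) -> float:
        return float(self.per_replicate["train_auc"].mean())

    @property
    def mean_threshold(self) -> float:
        return float(self.per_replicate["mtsps_threshold"].mean())

    def aggregates(self) -> Dict[str, float]:
        df = self.per_replicate
        return {
            "train_auc_mean": float(df["train_auc"].mean()),
            "train_auc_sd": float(df["train_auc"].std(ddof=1)) if len(df) > 1 else 0.0,
            "test_auc_mean": float(df["test_auc"].mean()),
            "test_auc_sd": float(df["test_auc"].std(ddof=1)) if len(df) > 1 else 0.0,
            "mtsps_mean": float(df["mtsps_threshold"].mean()),
            "mtsps_sd": float(df["mtsps_threshold"].std(ddof=1)) if len(df) > 1 else 0.0,
        }


@dataclass
class ReplicateResult:
    mean_logistic: GridRaster
    report: EvalReport
    models: List[MaxEntModel]
    threshold: float               # replicate-mean MTSPS
    background_cells: np.ndarray


def run_replicates(stack: RasterStack, occ: OccurrenceSet, config: RunConfig,
                   master_seed: int | None = None) -> ReplicateResult:
    """Repeated random train/test subsampling with replicate-mean outputs.

    Each replicate holds out ``test_fraction`` of the presences (at least
    one), fits on the rest, and records train/test AUC and the replicate's
    MTSPS threshold computed on TRAINING presences against the background.
    The final suitability map is the cell-wise mean of replicate logistic
    maps and the final threshold the mean of replicate MTSPS values.
    """
    if master_seed is None:
        master_seed = config.random_seed
    presence = points_to_cells(stack, occ)
    n = presence.size
    if n < 8:
        raise ValueError(f"need at least 8 presence cells after thinning, got {n}")
    n_test = max(1, int(np.floor(n * config.test_fraction)))
    background = sample_background(stack, config.background_n,
                                  derive_seed(master_seed, "background", occ.species))
    mean_map = np.zeros(stack.shape)
    rows = []
    contribs: List[Dict[str, float]] = []
    models: List[MaxEntModel] = []
    for r in range(config.replicates):
        rng = np.random.default_rng(derive_seed(master_seed, "replicate", occ.species, r))
        perm = rng.permutation(n)
        test_cells = presence[perm[:n_test]]
        train_cells = presence[perm[n_test:]]
        feats = build_features(stack, train_cells, config)
        model = fit_maxent(feats, stack, train_cells, background, config)
        logistic = predict_logistic(model, stack)
        flat = logistic.values.ravel()
        sb = flat[background]
        s_train = flat[train_cells]
        s_test = flat[test_cells]
        rows.append({"replicate": r,
                     "train_auc": evaluate_auc(s_train, sb),
                     "test_auc": evaluate_auc(s_test, sb),
                     "mtsps_threshold": mtsps_threshold(s_train, sb)})
        contribs.append(percent_contribution(model))
        models.append(model)
        mean_map += logistic.values
    mean_map /= config.replicates
    mean_map[~stack.valid_mask] = 0.0
    df = pd.DataFrame(rows)
    all_vars = sorted({v for c in contribs for v in c})
    mean_contrib = {v: float(np.mean([c.get(v, 0.0) for c in contribs])) for v in all_vars}
    total = sum(mean_contrib.values())
    if total > 0:
        mean_contrib = {v: 100.0 * c / total for v, c in mean_contrib.items()}
    report = EvalReport(per_replicate=df, percent_contribution=mean_contrib)
    grid = stack.grid.copy_with(values=mean_map, nodata_mask=~stack.valid_mask)
    log_stage("run_replicates", species=occ.species, n_presence=n,
              mean_test_auc=round(report.mean_test_auc, 4),
              mean_threshold=round(report.mean_threshold, 4))
    return ReplicateResult(mean_logistic=grid, report=report, models=models,
                           threshold=report.mean_threshold, background_cells=background)


def project_mean_logistic(models: List[MaxEntModel], stack: RasterStack) -> GridRaster:
    """Cell-wise mean of the replicate models' logistic maps on a new stack."""
    if not models:
        raise ValueError("no models to project")
    acc = np.zeros(stack.shape)
    for m in models:
        acc += predict_logistic(m, stack).values
    acc /= len(models)
    acc[~stack.valid_mask] = 0.0
    return stack.grid.copy_with(values=acc, nodata_mask=~stack.valid_mask)


def variable_effect_direction(model: MaxEntModel, variable: str,
                              n_grid: int = 101) -> float:
    """Sign of the fitted additive effect of one continuous variable.

    Evaluates the sum of the model's single-variable features of ``variable``
    along a grid spanning its training range and returns the slope sign of a
    least-squares line through that partial response (+1, -1, or 0).
    """
    feats = [(j, f) for j, f in enumerate(model.feature_set.features)
             if f.variables == (variable,) and f.kind != "categorical"]
    if not feats:
        return 0.0
    lin = [f for _, f in feats if f.kind == "linear"]
    lo = min(f.lo for f in lin) if lin else min(f.lo for _, f in feats)
    hi = max(f.hi for f in lin) if lin else max(f.hi for _, f in feats)
    xs = np.linspace(lo, hi, n_grid)
    partial = np.zeros(n_grid)
    for j, f in feats:
        partial += model.lam[j] * f.value({variable: xs})
    slope = np.polyfit(xs, partial, 1)[0]
    return float(np.sign(slope)) if abs(slope) > 1e-12 else 0.0
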