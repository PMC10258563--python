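"""Benchmark axes: MI alignment, occlusion faithfulness, randomization checks.

* Alignment: Kraskov–Stögbauer–Grassberger (KSG) k-nearest-neighbour mutual
  information between an attribution map and a reference map (planted
  ground truth or GLM contrast), with Pearson correlation as a secondary
  linear metric.
* Faithfulness: decoding accuracy as a function of the fraction of
  highest-relevance voxels set to zero, and the first occlusion rate at
  which accuracy drops to chance (1/C).
* Sanity checks: MI between the attributions of the trained model and of a
  weight-randomized model (model randomization test) or of a model trained
  on shuffled labels (data randomization test); low MI means the method is
  sensitive to model parameters / training data.
* Method comparison: indicator-coded linear model of a score on method,
  with a 94% bias-corrected bootstrap interval per coefficient; a method
  differs meaningfully from the baseline if its interval excludes 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import digamma

from . import decoder as decoder_mod
from .attribution import AttributionParams, AttributionVolume, attribute_batch
from .synthetic import TrialVolume, stack_trials

__all__ = [
    "MISpec",
    "FaithfulnessCurve",
    "ComparisonResult",
    "ksg_mutual_information",
    "alignment_score",
    "occlude",
    "faithfulness_curve",
    "default_rate_grid",
    "data_randomization_check",
    "model_randomization_check",
    "compare_methods",
]


@dataclass
class MISpec:
    """KSG estimator settings: k neighbours, seeded tie-break noise."""

    n_neighbors: int = 3
    tie_noise_scale: float = 1e-10
    voxel_subsample: int | None = None
    seed: int = 0

    def validate(self):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


def ksg_mutual_information(xvec, yvec, spec: MISpec | None = None,
                           clip: bool = True) -> float:
    """KSG estimate of I(X;Y) in nats from two paired sample vectors.

    Chebyshev-ball variant: with eps_i the distance to the k-th neighbour in
    the joint (max-norm) space, ``I = psi(N) + psi(k) - <psi(nx+1) + psi(ny+1)>``
    where nx, ny count marginal neighbours strictly inside eps_i.  Negative
    estimates are clipped to 0 unless ``clip=False``.
    """
    spec = spec or MISpec()
    spec.validate()
    x = np.asarray(xvec, dtype=float).ravel()
    y = np.asarray(yvec, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("input vectors must have equal length")
    k = spec.n_neighbors
    if len(x) < k + 2:
        raise ValueError(f"need at least {k + 2} samples for k={k}")
    rng = np.random.default_rng(spec.seed)
    if spec.voxel_subsample is not None and len(x) > spec.voxel_subsample:
        idx = rng.choice(len(x), size=spec.voxel_subsample, replace=False)
        x, y = x[idx], y[idx]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector; MI degenerate, returning 0")
        return 0.0
    # seeded tie-breaking jitter, scaled to the data
    x = x + spec.tie_noise_scale * max(x.std(), 1e-30) * rng.normal(size=x.shape)
    y = y + spec.tie_noise_scale * max(y.std(), 1e-30) * rng.normal(size=y.shape)
    n = len(x)
    joint = np.column_stack([x, y])
    dist, _ = cKDTree(joint).query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    xs = np.sort(x)
    ys = np.sort(y)
    nx = (np.searchsorted(xs, x + eps, side="left")
          - np.searchsorted(xs, x - eps, side="right"))
    ny = (np.searchsorted(ys, y + eps, side="left")
          - np.searchsorted(ys, y - eps, side="right"))
    # counts include the point itself; psi(n+1) with n excluding self
    mi = digamma(n) + digamma(k) - float(np.mean(digamma(nx) + digamma(ny)))
    return max(mi, 0.0) if clip else mi


def alignment_score(attr_map: np.ndarray, ref_map: np.ndarray, mask: np.ndarray,
                    spec: MISpec | None = None) -> tuple[float, float]:
    """MI (primary) and Pearson r (secondary) between two masked maps."""
    if attr_map.shape != ref_map.shape or attr_map.shape != mask.shape:
        raise ValueError("maps and mask must share the grid")
    a = attr_map[mask]
    r = ref_map[mask]
    mi = ksg_mutual_information(a, r, spec)
    if a.std() == 0 or r.std() == 0:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(a, r)[0, 1])
    return mi, pearson


# ---------------------------------------------------------------------------
# occlusion faithfulness


def default_rate_grid() -> np.ndarray:
    """21 occlusion rates from 0 to 0.5 in steps of 0.025."""
    return np.round(np.arange(21) * 0.025, 6)


def occlusion_order(relevance: np.ndarray, mask: np.ndarray,
                    absolute: bool = False) -> np.ndarray:
    """Flat in-mask voxel indices sorted by descending relevance.

    Ties are broken by ascending voxel index (stable sort), so occlusion is
    fully deterministic.
    """
    flat_idx = np.flatnonzero(mask.ravel())
    rel = relevance.ravel()[flat_idx]
    if absolute:
        rel = np.abs(rel)
    order = np.argsort(-rel, kind="stable")
    return flat_idx[order]


def occlude(x: TrialVolume, relevance, rate: float,
            absolute_rank: bool = False) -> TrialVolume:
    """Zero the ceil(rate * n_mask) highest-relevance voxels of a trial."""
    if not 0.0 <= rate <= 0.5:
        raise ValueError("occlusion rate must lie in [0, 0.5]")
    rel = relevance.relevance if isinstance(relevance, AttributionVolume) else np.asarray(relevance)
    if rel.shape != x.values.shape:
        raise ValueError("relevance and trial must share the grid")
    n_occ = int(np.ceil(rate * int(x.mask.sum())))
    values = x.values.copy()
    if n_occ > 0:
        order = occlusion_order(rel, x.mask, absolute=absolute_rank)
        values.ravel()[order[:n_occ]] = 0.0
    return TrialVolume(values=values, mask=x.mask, label=x.label,
                       subject_id=x.subject_id, run_id=x.run_id, trial_id=x.trial_id)


@dataclass
class FaithfulnessCurve:
    """Accuracy vs occlusion rate plus the chance-crossing rate."""

    method: str
    occlusion_rates: np.ndarray
    accuracy_at_rate: np.ndarray
    chance_level: float
    critical_rate: float | None = field(default=None)
    censored: bool = False

    def __post_init__(self):
        rates = np.asarray(self.occlusion_rates, dtype=float)
        if np.any(np.diff(rates) <= 0):
            raise ValueError("occlusion rates must be strictly increasing")
        if self.critical_rate is None and not self.censored:
            below = np.flatnonzero(np.asarray(self.accuracy_at_rate) <= self.chance_level + 1e-12)
            if below.size:
                self.critical_rate = float(rates[below[0]])
            else:
                self.censored = True


def faithfulness_curve(model, test_trials: list[TrialVolume],
                       attributions: list[AttributionVolume],
                       rate_grid: np.ndarray | None = None,
                       absolute_rank: bool = False) -> FaithfulnessCurve:
    """Occlusion curve of one method's attributions on one trained model.

    ``attributions`` must cover every test trial (matched by trial_id).
    Accuracy at rate 0 is the unoccluded test accuracy; accuracies below
    chance are retained.
    """
    rates = default_rate_grid() if rate_grid is None else np.asarray(rate_grid, dtype=float)
    by_trial = {a.trial_id: a for a in attributions}
    missing = [t.trial_id for t in test_trials if t.trial_id not in by_trial]
    if missing:
        raise ValueError(f"missing attributions for trials {missing[:3]}...")
    X, y, _, _, _ = stack_trials(test_trials)
    n_mask = int(test_trials[0].mask.sum())
    orders = [occlusion_order(by_trial[t.trial_id].relevance, t.mask, absolute=absolute_rank)
              for t in test_trials]
    accs = []
    for rate in rates:
        n_occ = int(np.ceil(rate * n_mask))
        Xo = X.copy()
        if n_occ > 0:
            for i, order in enumerate(orders):
                Xo[i].ravel()[order[:n_occ]] = 0.0
        accs.append(float((model.predict(Xo) == y).mean()))
    method = attributions[0].method if attributions else "unknown"
    return FaithfulnessCurve(method=method, occlusion_rates=rates,
                             accuracy_at_rate=np.array(accs),
                             chance_level=1.0 / model.n_classes)


# ---------------------------------------------------------------------------
# randomization sanity checks


def _mean_attribution_mi(model_a, model_b, trials, methods,
                         params: AttributionParams, spec: MISpec) -> pd.DataFrame:
    """Per-method mean (over trials) MI between two models' attributions,
    next to the self-comparison ceiling of model_a."""
    rows = []
    mask = trials[0].mask
    for method in methods:
        if method == "input_control":
            attrs_a = [a.values * mask for a in trials]
            attrs_b = [a.values * mask for a in trials]
            self_maps = attrs_a
        else:
            attrs_a = [a.relevance for a in attribute_batch(model_a, trials, method, params)]
            attrs_b = [a.relevance for a in attribute_batch(model_b, trials, method, params)]
            self_maps = attrs_a
        mi_cross, mi_self = [], []
        for i, t in enumerate(trials):
            sp = MISpec(spec.n_neighbors, spec.tie_noise_scale,
                        spec.voxel_subsample, spec.seed + i)
            mi_cross.append(ksg_mutual_information(attrs_a[i][t.mask], attrs_b[i][t.mask], sp))
            mi_self.append(ksg_mutual_information(self_maps[i][t.mask], self_maps[i][t.mask], sp))
        mi_cross_m = float(np.mean(mi_cross))
        mi_self_m = float(np.mean(mi_self))
        rows.append({"method": method, "mi": mi_cross_m, "mi_self": mi_self_m,
                     "insensitive": mi_cross_m >= 0.9 * mi_self_m})
    return pd.DataFrame(rows)


def model_randomization_check(model, test_trials, methods,
                              params: AttributionParams | None = None,
                              spec: MISpec | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """MI between attributions of the trained model and a random-weight twin.

    Low MI (relative to the self-comparison ceiling ``mi_self``) indicates
    the method is sensitive to the model parameters; the ``insensitive``
    flag marks methods whose cross-model MI stays at >= 90% of the ceiling.
    The reserved method name ``input_control`` (relevance = input) is a
    deliberately model-independent control.
    """
    params = params or AttributionParams()
    spec = spec or MISpec()
    cfg = decoder_mod.DecoderConfig(**{**model.config.__dict__, "seed": seed + 7919})
    random_model = decoder_mod.build_model(cfg, model.grid_shape, model.classes,
                                           use_bias=model.use_bias,
                                           use_batchnorm=model.use_batchnorm)
    return _mean_attribution_mi(model, random_model, test_trials, methods, params, spec)


def data_randomization_check(model, train_trials, test_trials, methods,
                             params: AttributionParams | None = None,
                             spec: MISpec | None = None,
                             n_epochs_memorize: int = 300,
                             memorize_threshold: float = 0.9,
                             seed: int = 0):
    """MI between attributions of the trained model and a shuffled-label twin.

    A model with the original architecture is trained for a fixed, long
    period on a label-shuffled copy of the training pool so that it
    memorizes the random assignment; the check aborts unless training
    accuracy exceeds ``memorize_threshold`` while the accuracy on a
    held-out *shuffled-label* validation split stays near chance.  (The
    validation labels are shuffled too, exactly as in a random split of the
    shuffled pool: they are independent of anything the model can predict,
    so the expected accuracy is 1/C.  Accuracy against the *true* labels
    would not do as a guard — on data with class structure a memorizing
    model generalizes the plurality shuffled label of each class and can
    score far *below* chance on truth; it is reported as a diagnostic.)

    Returns ``(table, diagnostics)``.
    """
    params = params or AttributionParams()
    spec = spec or MISpec()
    X, y, _, _, _ = stack_trials(train_trials)
    rng = np.random.default_rng(seed)
    y_shuffled = y[rng.permutation(len(y))]
    n_val = max(1, int(round(0.2 * len(X))))
    perm = rng.permutation(len(X))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    cfg = decoder_mod.DecoderConfig(**{**model.config.__dict__,
                                       "seed": seed + 104729, "dropout_rate": 0.0})
    twin = decoder_mod.build_model(cfg, model.grid_shape, model.classes,
                                   use_bias=model.use_bias,
                                   use_batchnorm=model.use_batchnorm)
    decoder_mod.train(twin, (X[tr_idx], y_shuffled[tr_idx]),
                      val_set=(X[val_idx], y_shuffled[val_idx]),
                      min_epochs=n_epochs_memorize, max_epochs=n_epochs_memorize,
                      seed=seed + 104729, restore_best=False)
    train_acc, _ = decoder_mod.evaluate(twin, (X[tr_idx], y_shuffled[tr_idx]))
    val_acc, _ = decoder_mod.evaluate(twin, (X[val_idx], y_shuffled[val_idx]))
    heldout_acc, _ = decoder_mod.evaluate(twin, test_trials)
    chance = 1.0 / model.n_classes
    diagnostics = {"memorization_accuracy": train_acc,
                   "validation_accuracy": val_acc,
                   "heldout_true_label_accuracy": heldout_acc,
                   "chance_level": chance}
    if train_acc < memorize_threshold:
        raise RuntimeError(
            f"shuffled-label model failed to memorize (train accuracy {train_acc:.2f}); "
            "increase n_epochs_memorize or model capacity")
    # tolerance accounts for the binomial noise of small validation splits;
    # with a few hundred validation trials the 10-point bound governs
    tol = max(0.10, 2.0 * np.sqrt(chance * (1 - chance) / n_val))
    if abs(val_acc - chance) > tol:
        raise RuntimeError(
            f"shuffled-label validation accuracy {val_acc:.2f} is not near chance {chance:.2f}")
    table = _mean_attribution_mi(model, twin, test_trials, methods, params, spec)
    return table, diagnostics


# ---------------------------------------------------------------------------
# method comparison statistic


@dataclass
class ComparisonResult:
    """Per-method coefficient vs the baseline with its 94% interval."""

    table: pd.DataFrame
    baseline: str
    level: float = 0.94


def compare_methods(scores: pd.DataFrame, baseline_method: str = "deeplift",
                    score_col: str = "score", level: float = 0.94,
                    n_boot: int = 2000, seed: int = 0) -> ComparisonResult:
    """Indicator-coded comparison of per-observation scores across methods.

    Fits ``score ~ 1 + method`` with the baseline as the unmodelled
    reference cell; each other method's coefficient is its mean difference
    from the baseline.  Intervals are bias-corrected bootstrap percentile
    intervals at the 94% level, with expanded percentile levels (Student-t
    quantiles scaled by sqrt(n/(n-1))) to correct the well-known narrowness
    of percentile intervals at small per-group sample sizes; a method is
    flagged ``meaningful`` if its interval excludes 0.
    """
    methods = sorted(scores["method"].unique())
    if baseline_method not in methods:
        raise ValueError(f"baseline {baseline_method!r} absent from scores")
    if len(methods) < 2:
        raise ValueError("need at least 2 methods to compare")
    groups = {m: scores.loc[scores["method"] == m, score_col].to_numpy(dtype=float)
              for m in methods}
    if min(len(g) for g in groups.values()) < 3:
        raise ValueError("need at least 3 observations per method")
    for m, g in groups.items():
        if np.ptp(g) == 0:
            warnings.warn(f"method {m!r} has identical scores (degenerate variance)")
    rng = np.random.default_rng(seed)
    base = groups[baseline_method]
    rows = []
    alpha = (1.0 - level) / 2.0
    for m in methods:
        if m == baseline_method:
            continue
        g = groups[m]
        coef = float(g.mean() - base.mean())
        boot_g = g[rng.integers(len(g), size=(n_boot, len(g)))].mean(axis=1)
        boot_b = base[rng.integers(len(base), size=(n_boot, len(base)))].mean(axis=1)
        boot = boot_g - boot_b
        # bias correction with expanded percentile levels
        prop = (np.sum(boot < coef) + 0.5 * np.sum(boot == coef)) / n_boot
        prop = min(max(prop, 1.0 / n_boot), 1.0 - 1.0 / n_boot)
        z0 = stats.norm.ppf(prop)
        df = len(g) + len(base) - 2
        n_eff = min(len(g), len(base))
        z_alpha = stats.t.ppf(alpha, df) * np.sqrt(n_eff / max(n_eff - 1, 1))
        lo_q = stats.norm.cdf(2 * z0 + z_alpha)
        hi_q = stats.norm.cdf(2 * z0 - z_alpha)
        lower, upper = np.quantile(boot, [lo_q, hi_q])
        rows.append({"method": m, "coefficient": coef,
                     "lower": float(lower), "upper": float(upper),
                     "meaningful": bool(lower > 0 or upper < 0)})
    return ComparisonResult(pd.DataFrame(rows), baseline_method, level)
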