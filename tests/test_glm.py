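"""Voxelwise GLM: oracle equivalence, calibration, contrasts, aggregation."""

import numpy as np
import pandas as pd
import pytest

from helpers import as_trials
from neuroxai.attribution import AttributionVolume
from neuroxai.glm import (DesignMatrix, aggregate_attributions, fit_voxelwise_glm,
                          ground_truth_reference, group_contrast, one_vs_rest_contrast,
                          smooth_volume, subject_contrast)
from neuroxai.synthetic import TrialVolume, ellipsoid_mask


def _design(frame, kinds=None):
    return DesignMatrix(pd.DataFrame(frame), kinds or {})


def test_ols_matches_normal_equations_oracle():
    """Voxelwise fit equals a direct normal-equations solve on 5^3 grids."""
    rng = np.random.default_rng(0)
    n, grid = 18, (5, 5, 5)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    Y = rng.normal(size=(n,) + grid)
    design = _design({"intercept": X[:, 0], "a": X[:, 1], "b": X[:, 2]})
    fit = fit_voxelwise_glm(Y, design)
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y.reshape(n, -1))
    assert np.allclose(fit.beta, beta_oracle, atol=1e-6)
    resid = Y.reshape(n, -1) - X @ beta_oracle
    assert np.allclose(fit.sigma2, (resid ** 2).sum(0) / (n - 3), atol=1e-6)


def test_exact_fit_two_condition_design_degenerate_t():
    cond = np.repeat([1.0, 0.0], 4)
    Y = np.where(cond, 3.0, 1.0)[:, None, None, None] * np.ones((8, 2, 2, 2))
    design = _design({"c1": cond, "c2": 1 - cond})
    fit = fit_voxelwise_glm(Y, design)
    cm = fit.contrast(np.array([1.0, -1.0]))
    assert np.allclose(cm.effect, 2.0)
    assert np.all(cm.degenerate)  # zero residual -> t flagged as degenerate
    assert np.all(np.isinf(cm.t))


def test_orthogonal_nuisance_leaves_contrast_unchanged():
    rng = np.random.default_rng(1)
    n = 24
    cond = np.tile([1.0, 0.0], n // 2)
    Y = rng.normal(size=(n, 3, 3, 3)) + cond[:, None, None, None]
    base = _design({"c1": cond, "c2": 1 - cond})
    fit0 = fit_voxelwise_glm(Y, base)
    nuis = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal to both columns
    aug = _design({"c1": cond, "c2": 1 - cond, "z": nuis})
    fit1 = fit_voxelwise_glm(Y, aug)
    c0 = fit0.contrast(np.array([1.0, -1.0]))
    c1 = fit1.contrast(np.array([1.0, -1.0, 0.0]))
    assert np.allclose(c0.effect, c1.effect, atol=1e-10)


def test_rank_deficiency_names_collinear_columns():
    n = 10
    a = np.arange(n, dtype=float)
    with pytest.raises(ValueError, match="collinear.*dup"):
        fit_voxelwise_glm(np.zeros((n, 2, 2, 2)),
                         _design({"a": a, "b": np.ones(n), "dup": 2 * a}))


def test_type_one_error_calibration():
    """Null contrast rejects at ~alpha over 2000 simulated voxels."""
    rng = np.random.default_rng(42)
    n = 16
    cond = np.tile([1.0, 0.0], n // 2)
    Y = rng.normal(size=(n, 2000))  # pure noise voxels, no signal
    design = _design({"c1": cond, "c2": 1 - cond})
    fit = fit_voxelwise_glm(Y[..., None, None], design)
    cm = fit.contrast(np.array([1.0, -1.0]))
    from scipy import stats
    p = 2 * stats.t.sf(np.abs(cm.t.ravel()), cm.df)
    rate = float((p < 0.05).mean())
    assert 0.03 <= rate <= 0.07


def test_subject_contrast_noise_free_recovers_construction(small_config):
    """Noise-free subject: one-vs-rest effect equals pattern_c - mean(others)."""
    from dataclasses import replace
    from neuroxai.synthetic import generate_dataset
    cfg = replace(small_config, noise_sd=0.0, subject_sd=0.0)
    dataset, patterns = generate_dataset(cfg)
    by_subject = {}
    for t in dataset.train:
        by_subject.setdefault(t.subject_id, []).append(t)
    trials = next(iter(by_subject.values()))
    maps = subject_contrast(trials)
    pw = {p.class_id: p.weights for p in patterns}
    for p in patterns:
        others = np.mean([pw[c] for c in pw if c != p.class_id], axis=0)
        assert np.allclose(maps[p.class_id].effect, p.weights - others, atol=1e-8)
        # on support voxels clear of other classes, the sign matches the pattern
        clear = p.support_mask.copy()
        for q in patterns:
            if q.class_id != p.class_id:
                clear &= ~q.support_mask
        assert np.all(np.sign(maps[p.class_id].effect[clear])
                      == np.sign(p.weights[clear]))


def test_two_class_contrast_antisymmetry():
    rng = np.random.default_rng(3)
    labels = ["a"] * 8 + ["b"] * 8
    X = rng.normal(size=(16, 4, 4, 4))
    trials = as_trials(X, labels=labels)
    maps = subject_contrast(trials)
    assert np.allclose(maps["a"].effect, -maps["b"].effect, atol=1e-10)
    assert np.allclose(maps["a"].t, -maps["b"].t, atol=1e-8)


def test_permuted_labels_center_statistics_at_zero(small_dataset):
    dataset, _ = small_dataset
    by_subject = {}
    for t in dataset.train:
        by_subject.setdefault(t.subject_id, []).append(t)
    trials = next(iter(by_subject.values()))
    labeled = subject_contrast(trials)
    rng = np.random.default_rng(7)
    labels = [t.label for t in trials]
    shuffled = [TrialVolume(t.values, t.mask, lab, t.subject_id, t.run_id, t.trial_id)
                for t, lab in zip(trials, rng.permutation(labels))]
    permuted = subject_contrast(shuffled)
    cls = sorted(labeled)[0]
    mask = trials[0].mask
    assert np.abs(permuted[cls].t[mask]).mean() < np.abs(labeled[cls].t[mask]).mean()


def test_single_class_subject_errors():
    trials = as_trials(np.zeros((4, 4, 4, 4)), labels=["a"] * 4)
    with pytest.raises(ValueError, match="single class"):
        subject_contrast(trials)


def test_group_contrast_smoothing_zero_is_identity():
    vol = np.random.default_rng(0).normal(size=(6, 6, 6))
    assert np.array_equal(smooth_volume(vol, 0.0), vol)
    assert not np.array_equal(smooth_volume(vol, 1.5), vol)


def test_group_contrast_identical_maps_degenerate():
    vol = np.random.default_rng(1).normal(size=(4, 4, 4))
    maps = {"a": [vol.copy() for _ in range(4)], "b": [-vol.copy() for _ in range(4)]}
    out = group_contrast(maps, smoothing_fwhm=0.0)
    assert np.allclose(out["a"].effect, vol, atol=1e-10)
    assert np.all(out["a"].degenerate | (out["a"].effect == 0))


def test_group_contrast_requires_three_subjects():
    with pytest.raises(ValueError, match="3 subjects"):
        group_contrast({"a": [np.zeros((4, 4, 4))] * 2, "b": [np.zeros((4, 4, 4))] * 2})


def test_group_recovers_pattern_on_synthetic_data(small_dataset):
    """Pipeline property: group maps correlate with the planted patterns."""
    dataset, patterns = small_dataset
    by_subject = {}
    for t in dataset.train:
        by_subject.setdefault(t.subject_id, []).append(t)
    classes = sorted({t.label for t in dataset.train})
    effects = {c: [] for c in classes}
    for subj in sorted(by_subject):
        maps = subject_contrast(by_subject[subj])
        for c in classes:
            effects[c].append(maps[c].effect)
    group = group_contrast(effects, smoothing_fwhm=1.5)
    mask = dataset.train[0].mask
    ref = ground_truth_reference(patterns)
    for c in classes:
        corr = np.corrcoef(group[c].z[mask], ref[c][mask])[0, 1]
        assert corr > 0.5


def test_signal_recoverability_t_contrast_ranks_support():
    """At default noise levels a pooled mass-univariate t-contrast ranks
    >=80% of support voxels above the 90th percentile of background voxels
    (in-mask voxels clear of every class's planted support)."""
    from neuroxai.glm import _indicators
    from neuroxai.synthetic import SyntheticConfig, generate_dataset
    dataset, patterns = generate_dataset(SyntheticConfig(seed=123))
    frame = _indicators([t.label for t in dataset.train], "class_",
                        drop_first=False, center=False)
    subj = _indicators([t.subject_id for t in dataset.train], "subject_",
                       drop_first=True, center=True)
    design = DesignMatrix(pd.concat([frame, subj], axis=1), {})
    fit = fit_voxelwise_glm(dataset.train, design)
    mask = dataset.train[0].mask
    any_support = np.zeros_like(mask)
    for p in patterns:
        any_support |= p.support_mask
    background = mask & ~any_support
    for p in patterns:
        cm = fit.contrast(one_vs_rest_contrast(design, "class_", p.class_id))
        thresh = np.quantile(np.abs(cm.t[background]), 0.9)
        support = p.support_mask & mask
        assert (np.abs(cm.t[support]) > thresh).mean() >= 0.8


def _fake_attributions(trials, runs, fn):
    out = []
    for run in runs:
        for t in trials:
            rel = fn(t, run)
            out.append(AttributionVolume(relevance=rel, method="fake", target=t.label,
                                         model_id=run, trial_id=t.trial_id))
    return out


def _aggregation_dataset(rng, n_subjects=4):
    trials = []
    mask = np.ones((4, 4, 4), dtype=bool)
    k = 0
    for s in range(n_subjects):
        for lab in ["a", "b"]:
            for i in range(4):
                vals = rng.normal(size=(4, 4, 4)) + (1.0 if lab == "a" else -1.0)
                trials.append(TrialVolume(vals, mask, lab, f"sub{s}",
                                          f"run{i % 2}", f"t{k:04d}"))
                k += 1
    return trials


def test_aggregate_single_run_reduces_to_plain_two_stage():
    rng = np.random.default_rng(5)
    trials = _aggregation_dataset(rng)
    attrs = _fake_attributions(trials, ["m0"], lambda t, r: t.values)
    # constant relevance_sum: force the degenerate-nuisance path
    for a in attrs:
        a.relevance_sum = 1.0
    subj_maps, group = aggregate_attributions(attrs, trials, smoothing_fwhm=0.0)
    # oracle: plain two-stage GLM on the same volumes
    by_subject = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    for s, ts in by_subject.items():
        oracle = subject_contrast(ts)
        for cls in ("a", "b"):
            assert np.allclose(subj_maps[(s, cls)], oracle[cls].effect, atol=1e-8)


def test_aggregate_duplicated_runs_leave_group_unchanged():
    rng = np.random.default_rng(6)
    trials = _aggregation_dataset(rng)
    single = _fake_attributions(trials, ["m0"], lambda t, r: t.values)
    double = _fake_attributions(trials, ["m0", "m1"], lambda t, r: t.values)
    _, g1 = aggregate_attributions(single, trials, smoothing_fwhm=0.0)
    _, g2 = aggregate_attributions(double, trials, smoothing_fwhm=0.0)
    for cls in ("a", "b"):
        assert np.allclose(g1[cls].effect, g2[cls].effect, atol=1e-8)


def test_aggregate_missing_cells_error():
    rng = np.random.default_rng(7)
    trials = _aggregation_dataset(rng)
    attrs = _fake_attributions(trials, ["m0"], lambda t, r: t.values)[:-1]
    with pytest.raises(ValueError, match="missing"):
        aggregate_attributions(attrs, trials)


def test_aggregate_matches_naive_two_loop_oracle():
    """Pipeline output equals an explicit subject-then-group OLS by hand."""
    rng = np.random.default_rng(8)
    trials = _aggregation_dataset(rng)
    attrs = _fake_attributions(trials, ["m0", "m1"],
                               lambda t, r: t.values * (1.0 if r == "m0" else 1.1))
    subj_maps, group = aggregate_attributions(attrs, trials, smoothing_fwhm=0.0)
    # naive oracle for one subject, class a
    subject = "sub0"
    maps = [a for a in attrs if a.trial_id in
            {t.trial_id for t in trials if t.subject_id == subject}]
    meta = {t.trial_id: t for t in trials}
    labels = np.array([meta[a.trial_id].label for a in maps])
    X_cols = [
        (labels == "a").astype(float),
        (labels == "b").astype(float),
    ]
    mruns = np.array([a.model_id for a in maps])
    col = (mruns == "m1").astype(float)
    X_cols.append(col - col.mean())
    fruns = np.array([meta[a.trial_id].run_id for a in maps])
    col = (fruns == "run1").astype(float)
    X_cols.append(col - col.mean())
    sums = np.array([a.relevance_sum for a in maps])
    X_cols.append(sums - sums.mean())
    X = np.column_stack(X_cols)
    Y = np.stack([a.relevance for a in maps]).reshape(len(maps), -1)
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    effect = (beta[0] - beta[1]).reshape((4, 4, 4))
    assert np.allclose(subj_maps[(subject, "a")], effect, atol=1e-6)


def test_ground_truth_reference_passthrough(small_dataset):
    _, patterns = small_dataset
    ref = ground_truth_reference(patterns)
    for p in patterns:
        assert ref[p.class_id] is p.weights
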