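"""Attribution methods: closed forms, sum rules, oracles, determinism."""

import numpy as np
import pytest

from helpers import (as_trials, make_linear_conv_model, make_linear_dense_model,
                     train_toy_cnn)
from neuroxai import nn
from neuroxai.attribution import (AttributionParams, attribute_batch, fold_model,
                                  METHODS, _backprop, _net_forward, batch_deeplift,
                                  batch_gradcam, batch_integrated_gradients,
                                  batch_lrp, gradcam)

GRID = (4, 4, 4)
N = 64


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="module")
def linear_setup(rng):
    w = rng.normal(size=N)
    b = 0.7
    model = make_linear_dense_model(GRID, w, b=b)
    x = np.abs(rng.normal(size=GRID)) + 0.1
    return model, w.reshape(GRID), b, x


def _attr(model, x, method, params=None, target="c0"):
    trials = as_trials(x[None], labels=[target])
    return attribute_batch(model, trials, method, params, targets=[target])[0].relevance


def test_linear_concordance_gradient_family(linear_setup):
    """On f = w.x + b: gradient -> |w|, smoothgrad -> |w|, IXG -> x*w."""
    model, w, b, x = linear_setup
    assert np.allclose(_attr(model, x, "gradient"), np.abs(w))
    p = AttributionParams(smoothgrad_K=5, seed=0)
    assert np.allclose(_attr(model, x, "smoothgrad", p), np.abs(w))
    assert np.allclose(_attr(model, x, "input_x_gradient"), x * w)


def test_linear_concordance_reference_family(linear_setup, rng):
    model, w, b, x = linear_setup
    # IG with zero baseline: exact x*w at any step count (constant gradient)
    p = AttributionParams(ig_steps=2, ig_baselines=("zero",))
    assert np.allclose(_attr(model, x, "integrated_gradients", p), x * w)
    # dual baseline: 0.5*(x*w) + 0.5*((x-mu)*w)
    ref = np.abs(rng.normal(size=(10,) + GRID))
    p2 = AttributionParams(ig_steps=2, reference_data=ref)
    mu = ref.mean(axis=0)
    assert np.allclose(_attr(model, x, "integrated_gradients", p2),
                       0.5 * x * w + 0.5 * (x - mu) * w)
    # DeepLift with reference r: (x - r) * w
    r = np.abs(rng.normal(size=GRID))
    p3 = AttributionParams(deeplift_reference=r)
    assert np.allclose(_attr(model, x, "deeplift", p3), (x - r) * w)
    # DeepLift default zero reference equals x*w
    assert np.allclose(_attr(model, x, "deeplift"), x * w)


def test_linear_concordance_deeplift_shap(linear_setup, rng):
    """Linear model: DeepLift SHAP = (x - mean of sampled references) * w."""
    model, w, b, x = linear_setup
    ref = np.abs(rng.normal(size=(7,) + GRID))
    p = AttributionParams(dlshap_K=20, reference_data=ref, seed=3)
    got = _attr(model, x, "deeplift_shap", p)
    # recompute the sampled-reference mean with the same seeded draw
    r = np.random.default_rng(3)
    sampled = [ref[r.integers(7, size=1)][0] for _ in range(20)]
    expected = (x - np.mean(sampled, axis=0)) * w
    assert np.allclose(got, expected)
    # K=1 equals plain DeepLift with that reference
    p1 = AttributionParams(dlshap_K=1, reference_data=ref, seed=5)
    r = np.random.default_rng(5)
    ref0 = ref[r.integers(7, size=1)][0]
    assert np.allclose(_attr(model, x, "deeplift_shap", p1),
                       _attr(model, x, "deeplift",
                             AttributionParams(deeplift_reference=ref0)))


def test_linear_concordance_lrp(linear_setup):
    """LRP-0 on a linear map with b=0 gives exactly x*w."""
    model, w, _, x = linear_setup
    model0 = make_linear_dense_model(GRID, w.ravel(), b=0.0)
    rel = _attr(model0, x, "lrp")
    assert np.allclose(rel, x * w, atol=1e-4)


def test_linear_concordance_guided_and_gradcam(rng):
    """Conv-containing linear-regime model: documented closed forms."""
    w = rng.normal(size=N)
    a = 2.0
    model = make_linear_conv_model(GRID, w, conv_weight=a)
    x = np.abs(rng.normal(size=GRID)) + 0.1  # positive input: ReLU inactive
    w_eff = (a * w).reshape(GRID)
    # guided backprop: at the single ReLU only positive top-down gradients
    # (the positive dense weights) survive -> a * max(w, 0)
    gbp = _attr(model, x, "guided_backprop")
    assert np.allclose(gbp, np.maximum(a * w, 0).reshape(GRID))
    # gradcam: alpha = mean(w), A = a*x -> cam = relu(mean(w) * a * x)
    cam = gradcam(model, as_trials(x[None], labels=["c0"])[0], target="c0")
    expected_cam = np.maximum(np.mean(w) * a * x, 0.0)
    assert np.allclose(cam, expected_cam)
    # guided gradcam = upsampled cam (identity here) * guided backprop
    ggc = _attr(model, x, "guided_gradcam")
    assert np.allclose(ggc, expected_cam * gbp)
    # plain gradient on the same model: |w_eff|
    assert np.allclose(_attr(model, x, "gradient"), np.abs(w_eff))


def test_constant_model_zero_gradient():
    model = make_linear_dense_model(GRID, np.zeros(N), b=1.0)
    x = np.random.default_rng(0).normal(size=GRID)
    assert np.allclose(_attr(model, x, "gradient"), 0.0)
    assert np.allclose(_attr(model, x, "input_x_gradient"), 0.0)


def test_input_x_gradient_zero_at_origin(linear_setup):
    model, w, _, _ = linear_setup
    assert np.allclose(_attr(model, np.zeros(GRID), "input_x_gradient"), 0.0)


def test_ig_zero_at_baseline(linear_setup):
    model, _, _, _ = linear_setup
    p = AttributionParams(ig_baselines=("zero",))
    assert np.allclose(_attr(model, np.zeros(GRID), "integrated_gradients", p), 0.0)


# ---------------------------------------------------------------------------
# trained toy CNN audits


@pytest.fixture(scope="module")
def toy():
    model = train_toy_cnn(grid=(8, 8, 8), bias_free=True)
    rng = np.random.default_rng(99)
    X = rng.normal(size=(4, 8, 8, 8))
    t_idx = np.array([0, 1, 2, 0])
    return fold_model(model), X, t_idx


def test_gradient_matches_finite_differences(toy):
    net, X, t_idx = toy
    g, _ = _backprop(net, X, t_idx)
    rng = np.random.default_rng(5)
    eps = 1e-5
    for _ in range(15):
        i = tuple(rng.integers(s) for s in X.shape)
        Xp, Xm = X.copy(), X.copy()
        Xp[i] += eps
        Xm[i] -= eps
        lp, _, _, _ = _net_forward(net, Xp)
        lm, _, _, _ = _net_forward(net, Xm)
        c = t_idx[i[0]]
        fd = (lp[i[0], c] - lm[i[0], c]) / (2 * eps)
        assert abs(fd - g[i]) < 1e-3 * max(1.0, abs(fd))


def test_ig_completeness_per_baseline(toy):
    net, X, t_idx = toy
    p = AttributionParams(ig_steps=256, ig_baselines=("zero",))
    r = batch_integrated_gradients(net, X, t_idx, p)
    lx, _, _, _ = _net_forward(net, X)
    lb, _, _, _ = _net_forward(net, np.zeros_like(X))
    fx = lx[np.arange(4), t_idx]
    fb = lb[np.arange(4), t_idx]
    assert np.all(np.abs(r.sum(axis=(1, 2, 3)) - (fx - fb)) <= 1e-3 * np.abs(fx - fb))


def test_deeplift_summation_to_delta(toy):
    net, X, t_idx = toy
    rng = np.random.default_rng(11)
    ref = rng.normal(size=X.shape[1:])
    r = batch_deeplift(net, X, t_idx, AttributionParams(), reference=ref)
    lx, _, _, _ = _net_forward(net, X)
    lb, _, _, _ = _net_forward(net, np.broadcast_to(ref, X.shape))
    delta = lx[np.arange(4), t_idx] - lb[np.arange(4), t_idx]
    assert np.all(np.abs(r.sum(axis=(1, 2, 3)) - delta) <= 1e-4 * np.abs(delta))


def test_deeplift_shap_summation_in_expectation(toy):
    net, X, t_idx = toy
    rng = np.random.default_rng(21)
    refs = rng.normal(size=(30,) + X.shape[1:])
    p = AttributionParams(dlshap_K=30, reference_data=refs, seed=13)
    from neuroxai.attribution import batch_deeplift_shap
    r = batch_deeplift_shap(net, X, t_idx, p)
    lx, _, _, _ = _net_forward(net, X)
    fx = lx[np.arange(4), t_idx]
    # oracle: mean f(b) over the same seeded reference draws
    rr = np.random.default_rng(13)
    fb = np.zeros(4)
    for _ in range(30):
        b = refs[rr.integers(30, size=4)]
        lb, _, _, _ = _net_forward(net, b)
        fb += lb[np.arange(4), t_idx]
    fb /= 30
    assert np.allclose(r.sum(axis=(1, 2, 3)), fx - fb, atol=1e-8)


def test_lrp_layerwise_conservation(toy):
    """Relevance sums stay equal to f(x) at every layer of a bias-free net."""
    net, X, t_idx = toy
    p = AttributionParams()
    lx, flat, pre_acts, acts = _net_forward(net, X)
    f = lx[np.arange(4), t_idx]
    # input-layer sum
    r_in = batch_lrp(net, X, t_idx, p)
    assert np.all(np.abs(r_in.sum(axis=(1, 2, 3)) - f) <= 1e-3 * np.abs(f))
    # intermediate layer: replay the dense LRP-0 step and check its sum too
    wc = net.dense_W[:, t_idx].T
    z = flat * wc
    denom = z.sum(axis=1)
    r_dense = z * (f / (denom + 1e-6 * np.sign(denom)))[:, None]
    assert np.all(np.abs(r_dense.sum(axis=1) - f) <= 1e-3 * np.abs(f))


def test_ixg_equals_deeplift_zero_reference_on_bias_free_net(toy):
    """Bias-free ReLU nets: InputXGradient == DeepLift with zero reference."""
    net, X, t_idx = toy
    from neuroxai.attribution import batch_input_x_gradient
    p = AttributionParams()
    ixg = batch_input_x_gradient(net, X, t_idx, p)
    dl = batch_deeplift(net, X, t_idx, p, reference=np.zeros(X.shape[1:]))
    # rescale multipliers equal gradients when the reference pre-activations
    # are all zero (bias-free network with zero input)
    assert np.allclose(ixg, dl, atol=1e-10)


def test_guided_backprop_nonnegative_on_positive_path(rng):
    """A single-path chain of positive weights yields non-negative relevance."""
    w = np.abs(rng.normal(size=N)) + 0.1
    model = make_linear_conv_model(GRID, w, conv_weight=1.5)
    x = np.abs(rng.normal(size=GRID))
    assert np.all(_attr(model, x, "guided_backprop") >= 0)


def test_guided_backprop_blocks_dead_relu():
    """Negative forward pre-activation zeroes relevance upstream of the unit."""
    w = np.ones(N)
    model = make_linear_conv_model(GRID, w, conv_weight=1.0)
    x = -np.ones(GRID)  # pre-activation negative everywhere
    assert np.allclose(_attr(model, x, "guided_backprop"), 0.0)


def test_gradcam_matches_naive_loop(toy):
    """Vectorised GradCam equals an explicit loop over kernels/positions."""
    net, X, t_idx = toy
    p = AttributionParams()
    cam = batch_gradcam(net, X, t_idx, p)
    logits, flat, pre_acts, acts = _net_forward(net, X)
    A = acts[-1]  # (B, K, d, h, w)
    seed = np.zeros_like(logits)
    seed[np.arange(4), t_idx] = 1.0
    dA = (seed @ net.dense_W.T).reshape(A.shape)
    for b in range(2):
        expected = np.zeros(A.shape[2:])
        for k in range(A.shape[1]):
            alpha = dA[b, k].mean()
            expected += alpha * A[b, k]
        expected = np.maximum(expected, 0.0)
        assert np.allclose(cam[b], expected, atol=1e-6)


def test_gradcam_relu_clamp_gives_zero_guided_gradcam():
    """If the pooled combination is non-positive everywhere, GGC is 0."""
    w = -np.ones(N)  # negative dense weights -> alpha < 0, A >= 0
    model = make_linear_conv_model(GRID, w, conv_weight=1.0)
    x = np.abs(np.random.default_rng(2).normal(size=GRID))
    assert np.allclose(_attr(model, x, "guided_gradcam"), 0.0)


def test_smoothgrad_seeded_determinism(toy):
    net, X, t_idx = toy
    from neuroxai.attribution import batch_smoothgrad
    p = AttributionParams(smoothgrad_K=5, seed=77)
    a = batch_smoothgrad(net, X, t_idx, p)
    b = batch_smoothgrad(net, X, t_idx, p)
    assert np.array_equal(a, b)


def test_smoothgrad_small_sigma_approaches_gradient(toy):
    net, X, t_idx = toy
    from neuroxai.attribution import batch_gradient, batch_smoothgrad
    p = AttributionParams(smoothgrad_K=8, smoothgrad_sigma=1e-9, seed=1)
    assert np.allclose(batch_smoothgrad(net, X, t_idx, p),
                       batch_gradient(net, X, t_idx, p), atol=1e-6)


def test_output_grid_and_masking_for_every_method(trained_small_model, small_dataset):
    dataset, _ = small_dataset
    trials = dataset.test[:2]
    from neuroxai.synthetic import stack_trials
    X, _, _, _, _ = stack_trials(dataset.train[:20])
    p = AttributionParams(smoothgrad_K=3, ig_steps=4, dlshap_K=3,
                          reference_data=X, seed=0)
    for method in METHODS:
        out = attribute_batch(trained_small_model, trials, method, p)
        for t, a in zip(trials, out):
            assert a.relevance.shape == t.values.shape
            assert np.all(a.relevance[~t.mask] == 0)
            assert np.isfinite(a.relevance).all()
            assert a.method == method


def test_unknown_method_raises(trained_small_model, small_dataset):
    dataset, _ = small_dataset
    with pytest.raises(KeyError, match="unknown attribution"):
        attribute_batch(trained_small_model, dataset.test[:1], "lime")
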