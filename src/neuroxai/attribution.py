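"""Nine attribution methods for volumetric CNN decoders, from their formulas.

Three families:

* sensitivity analyses — Gradient, SmoothGrad, Guided Backpropagation,
  Guided GradCam — score voxels by how sensitively the decoder output
  responds to them;
* reference-based attributions — InputXGradient, Integrated Gradients,
  DeepLift, DeepLift SHAP — contrast the response to the input with the
  response to a reference input;
* backward decomposition — LRP — redistributes the output backward through
  the network under a conservation constraint (LRP-0 at the dense output
  layer, LRP-gamma at the convolutions).

All methods operate on a "folded" evaluation-mode view of the decoder in
which batch normalization is absorbed into the adjacent convolution, so
every layer is linear followed by ReLU.  The attribution target defaults to
the pre-softmax logit of the decoded class (probabilities saturate under
softmax); dropout is always disabled.

Sign conventions follow each method's definition: Gradient, SmoothGrad,
Guided Backprop and Guided GradCam return non-negative (or ReLU-clamped)
maps, the reference-based methods and LRP return signed maps.  No global
absolute value is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .synthetic import TrialVolume

__all__ = [
    "AttributionParams",
    "AttributionVolume",
    "METHODS",
    "SENSITIVITY_METHODS",
    "REFERENCE_METHODS",
    "attribute_batch",
    "gradient_attribution",
    "smoothgrad",
    "input_x_gradient",
    "guided_backprop",
    "gradcam",
    "guided_gradcam",
    "integrated_gradients",
    "deeplift",
    "deeplift_shap",
    "lrp",
]

SENSITIVITY_METHODS = ["gradient", "smoothgrad", "guided_backprop", "guided_gradcam"]
REFERENCE_METHODS = ["input_x_gradient", "integrated_gradients", "deeplift",
                     "deeplift_shap", "lrp"]


@dataclass
class AttributionParams:
    """Shared knobs for all attribution methods.

    ``smoothgrad_K`` noise draws with standard deviation ``smoothgrad_sigma``
    (in input units); ``ig_steps`` midpoint-rule steps for the Integrated
    Gradients path integral; ``ig_baselines`` are averaged 0.5/0.5 (the
    all-zero input and the dataset mean); ``dlshap_K`` reference draws for
    DeepLift SHAP; ``lrp_gamma`` weights the positive-contribution term of
    the LRP-gamma rule.
    """

    smoothgrad_K: int = 50
    smoothgrad_sigma: float = 1.0
    smoothgrad_absolute: bool = True  # text reading; False averages signed gradients
    ig_steps: int = 64
    ig_baselines: tuple[str, ...] = ("zero", "dataset_mean")
    deeplift_reference: np.ndarray | None = None  # defaults to the all-zero volume
    dlshap_K: int = 50
    lrp_gamma: float = 0.25
    lrp_epsilon: float = 1e-6
    target_output: str = "logit"  # or "probability"
    guided_literal: bool = False  # mask only by gradient sign, not forward activation
    reference_data: np.ndarray | None = None  # (n, D, H, W) stack used for mean/SHAP refs
    seed: int = 0

    def validate(self) -> None:
        if self.smoothgrad_K < 1 or self.dlshap_K < 1:
            raise ValueError("sample counts must be >= 1")
        if self.smoothgrad_sigma <= 0:
            raise ValueError("smoothgrad_sigma must be positive")
        if self.ig_steps < 2:
            raise ValueError("ig_steps must be >= 2")
        if self.lrp_gamma < 0:
            raise ValueError("lrp_gamma must be >= 0")
        if self.target_output not in ("logit", "probability"):
            raise ValueError("target_output must be 'logit' or 'probability'")
        for b in self.ig_baselines:
            if b not in ("zero", "dataset_mean"):
                raise ValueError(f"unknown IG baseline {b!r}")


@dataclass
class AttributionVolume:
    """Per-trial, per-method, per-model-instance relevance map."""

    relevance: np.ndarray
    method: str
    target: str
    model_id: str
    trial_id: str
    relevance_sum: float = field(default=None)

    def __post_init__(self):
        if self.relevance_sum is None:
            self.relevance_sum = float(self.relevance.sum())


# ---------------------------------------------------------------------------
# folded (evaluation-mode) network view


@dataclass
class FoldedNet:
    convs: list[tuple[np.ndarray, np.ndarray, int]]  # (w, b, stride) per layer
    dense_W: np.ndarray
    dense_b: np.ndarray
    classes: np.ndarray
    grid_shape: tuple[int, ...]
    final_spatial: tuple[int, ...]


def fold_model(model) -> FoldedNet:
    """Absorb batch normalization into the convolutions (evaluation mode)."""
    convs = []
    for conv, bn in model.blocks:
        if bn is not None:
            w, b = bn.fold_into(conv.w, conv.b)
        else:
            w = conv.w
            b = conv.b if conv.b is not None else np.zeros(conv.w.shape[0])
        convs.append((w, b, conv.stride))
    dense_b = model.dense.b if model.dense.b is not None else np.zeros(model.dense.W.shape[1])
    return FoldedNet(convs, model.dense.W, dense_b, model.classes,
                     model.grid_shape, model.final_spatial)


def _net_forward(net: FoldedNet, X: np.ndarray):
    """Forward pass caching layer inputs and pre-activations."""
    x = np.asarray(X, dtype=np.float64)[:, None]
    acts = [x]       # acts[i]: input to conv layer i; acts[-1]: last conv output
    pre_acts = []
    for w, b, stride in net.convs:
        z = nn.conv3d(x, w, b, stride)
        pre_acts.append(z)
        x = np.maximum(z, 0.0)
        acts.append(x)
    flat = x.reshape(x.shape[0], -1)
    logits = flat @ net.dense_W + net.dense_b
    return logits, flat, pre_acts, acts


def _target_indices(net: FoldedNet, targets) -> np.ndarray:
    idx = np.searchsorted(net.classes, targets)
    idx = np.clip(idx, 0, len(net.classes) - 1)
    if np.any(net.classes[idx] != np.asarray(targets)):
        raise ValueError("unknown target class label")
    return idx


def _output_seed(logits: np.ndarray, t_idx: np.ndarray, target_output: str) -> np.ndarray:
    """d f / d logits for the selected scalar output f."""
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), t_idx] = 1.0
    if target_output == "logit":
        return onehot
    p = nn.softmax(logits)
    pc = p[np.arange(n), t_idx][:, None]
    return pc * (onehot - p)


def _backprop(net: FoldedNet, X, t_idx, target_output="logit", relu_rule="grad"):
    """Input-space gradient with a configurable ReLU backward rule."""
    logits, flat, pre_acts, acts = _net_forward(net, X)
    dlogits = _output_seed(logits, t_idx, target_output)
    da_flat = dlogits @ net.dense_W.T
    if not net.convs:
        return da_flat.reshape(X.shape), logits
    da = da_flat.reshape(acts[-1].shape)
    for i in range(len(net.convs) - 1, -1, -1):
        w, _, stride = net.convs[i]
        z = pre_acts[i]
        if relu_rule == "grad":
            dz = da * (z > 0)
        elif relu_rule == "guided":
            dz = da * (z > 0) * (da > 0)
        elif relu_rule == "guided_literal":
            dz = da * (da > 0)
        else:  # pragma: no cover
            raise ValueError(relu_rule)
        da = nn.conv3d_input_grad(dz, w, stride, acts[i].shape[2:])
    return da[:, 0], logits


def _check_finite(rel: np.ndarray, method: str) -> np.ndarray:
    if not np.all(np.isfinite(rel)):
        raise RuntimeError(f"non-finite relevance produced by {method}")
    return rel


# ---------------------------------------------------------------------------
# batched cores (B, D, H, W) -> (B, D, H, W)


def batch_gradient(net, X, t_idx, params: AttributionParams):
    g, _ = _backprop(net, X, t_idx, params.target_output)
    return _check_finite(np.abs(g), "gradient")


def batch_smoothgrad(net, X, t_idx, params: AttributionParams):
    rng = np.random.default_rng(params.seed)
    acc = np.zeros_like(np.asarray(X, dtype=np.float64))
    for _ in range(params.smoothgrad_K):
        noise = rng.normal(0.0, params.smoothgrad_sigma, size=X.shape)
        g, _ = _backprop(net, X + noise, t_idx, params.target_output)
        acc += np.abs(g) if params.smoothgrad_absolute else g
    return _check_finite(acc / params.smoothgrad_K, "smoothgrad")


def batch_input_x_gradient(net, X, t_idx, params: AttributionParams):
    g, _ = _backprop(net, X, t_idx, params.target_output)
    return _check_finite(g * X, "input_x_gradient")


def batch_guided_backprop(net, X, t_idx, params: AttributionParams):
    rule = "guided_literal" if params.guided_literal else "guided"
    g, _ = _backprop(net, X, t_idx, params.target_output, relu_rule=rule)
    return _check_finite(g, "guided_backprop")


def batch_gradcam(net, X, t_idx, params: AttributionParams):
    """Coarse relevance on the last convolution grid (before upsampling)."""
    if not net.convs:
        raise ValueError("GradCam requires at least one convolution layer")
    logits, flat, pre_acts, acts = _net_forward(net, X)
    dlogits = _output_seed(logits, t_idx, params.target_output)
    dA = (dlogits @ net.dense_W.T).reshape(acts[-1].shape)  # d f / d A of last conv
    alpha = dA.mean(axis=(2, 3, 4))                          # (B, K) pooled weights
    cam = np.einsum("bk,bkdhw->bdhw", alpha, acts[-1])
    return _check_finite(np.maximum(cam, 0.0), "gradcam")


def _upsample_to(vol: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    factors = [t / s for t, s in zip(shape, vol.shape)]
    out = ndimage.zoom(vol, factors, order=1, mode="nearest", grid_mode=True)
    if out.shape != tuple(shape):  # guard against rounding in odd shapes
        sl = tuple(slice(0, n) for n in shape)
        padded = np.zeros(shape)
        padded[tuple(slice(0, min(a, b)) for a, b in zip(shape, out.shape))] = out[sl]
        out = padded
    return out


def batch_guided_gradcam(net, X, t_idx, params: AttributionParams):
    cam = batch_gradcam(net, X, t_idx, params)
    gbp = batch_guided_backprop(net, X, t_idx, params)
    up = np.stack([_upsample_to(c, X.shape[1:]) for c in cam])
    return _check_finite(up * gbp, "guided_gradcam")


def _ig_single_baseline(net, X, t_idx, baseline, params):
    X = np.asarray(X, dtype=np.float64)
    diff = X - baseline
    acc = np.zeros_like(X)
    m = params.ig_steps
    for step in range(m):
        alpha = (step + 0.5) / m
        g, _ = _backprop(net, baseline + alpha * diff, t_idx, params.target_output)
        acc += g
    return diff * acc / m


def _resolve_baseline(name: str, X: np.ndarray, params: AttributionParams) -> np.ndarray:
    if name == "zero":
        return np.zeros_like(np.asarray(X, dtype=np.float64))
    if params.reference_data is None:
        raise ValueError("ig_baselines includes 'dataset_mean' but reference_data is unset")
    return np.broadcast_to(params.reference_data.mean(axis=0), X.shape).astype(np.float64)


def batch_integrated_gradients(net, X, t_idx, params: AttributionParams):
    maps = [_ig_single_baseline(net, X, t_idx, _resolve_baseline(b, X, params), params)
            for b in params.ig_baselines]
    return _check_finite(np.mean(maps, axis=0), "integrated_gradients")


def batch_deeplift(net, X, t_idx, params: AttributionParams, reference=None):
    """DeepLift multipliers: linear rule at conv/dense, rescale rule at ReLU."""
    if params.target_output != "logit":
        raise ValueError("DeepLift supports only the logit target")
    X = np.asarray(X, dtype=np.float64)
    if reference is None:
        reference = params.deeplift_reference
    ref = np.zeros_like(X) if reference is None else np.broadcast_to(reference, X.shape)
    logits_x, _, pre_x, acts_x = _net_forward(net, X)
    logits_b, _, pre_b, acts_b = _net_forward(net, ref)
    n = X.shape[0]
    seed = np.zeros_like(logits_x)
    seed[np.arange(n), t_idx] = 1.0
    m_flat = seed @ net.dense_W.T  # linear rule through the dense layer
    if not net.convs:
        return _check_finite((X - ref) * m_flat.reshape(X.shape), "deeplift")
    m = m_flat.reshape(acts_x[-1].shape)
    for i in range(len(net.convs) - 1, -1, -1):
        w, _, stride = net.convs[i]
        dz = pre_x[i] - pre_b[i]
        d_act = np.maximum(pre_x[i], 0.0) - np.maximum(pre_b[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(np.abs(dz) < 1e-7, (pre_x[i] > 0).astype(float), d_act / dz)
        m = nn.conv3d_input_grad(m * factor, w, stride, acts_x[i].shape[2:])
    return _check_finite((X - ref) * m[:, 0], "deeplift")


def batch_deeplift_shap(net, X, t_idx, params: AttributionParams):
    if params.reference_data is None:
        raise ValueError("deeplift_shap requires reference_data to sample references from")
    rng = np.random.default_rng(params.seed)
    n_ref = params.reference_data.shape[0]
    acc = np.zeros_like(np.asarray(X, dtype=np.float64))
    for _ in range(params.dlshap_K):
        refs = params.reference_data[rng.integers(n_ref, size=X.shape[0])]
        acc += batch_deeplift(net, X, t_idx, params, reference=refs)
    return _check_finite(acc / params.dlshap_K, "deeplift_shap")


def batch_lrp(net, X, t_idx, params: AttributionParams, layer_sums: list | None = None):
    """Composite LRP: LRP-0 at the dense output layer, LRP-gamma at convs.

    Relevance is seeded with the target logit f(x) and conserved from layer
    to layer (denominators are stabilized with a small signed epsilon and
    exclude the bias, so layer sums remain equal to f(x) up to the
    stabilizer).
    """
    if params.target_output != "logit":
        raise ValueError("LRP supports only the logit target")
    X = np.asarray(X, dtype=np.float64)
    eps = params.lrp_epsilon
    logits, flat, pre_acts, acts = _net_forward(net, X)
    n = X.shape[0]
    f = logits[np.arange(n), t_idx]
    # dense layer, LRP-0: r_i = a_i w_ic / (sum_i a_i w_ic) * f
    wc = net.dense_W[:, t_idx].T            # (B, n_flat)
    z = flat * wc
    denom = z.sum(axis=1)
    denom = denom + eps * np.where(denom >= 0, 1.0, -1.0)
    r = z * (f / denom)[:, None]
    if layer_sums is not None:
        layer_sums.append(r.sum(axis=1))
    if not net.convs:
        return _check_finite(r.reshape(X.shape), "lrp")
    r = r.reshape(acts[-1].shape)
    for i in range(len(net.convs) - 1, -1, -1):
        w, _, stride = net.convs[i]
        wg = w + params.lrp_gamma * np.maximum(w, 0.0)
        a = acts[i]
        zden = nn.conv3d(a, wg, None, stride)
        zden = zden + eps * np.where(zden >= 0, 1.0, -1.0)
        s = r / zden
        r = a * nn.conv3d_input_grad(s, wg, stride, a.shape[2:])
        if layer_sums is not None:
            layer_sums.append(r.sum(axis=(1, 2, 3, 4)))
    return _check_finite(r[:, 0], "lrp")


METHODS = {
    "gradient": batch_gradient,
    "smoothgrad": batch_smoothgrad,
    "input_x_gradient": batch_input_x_gradient,
    "guided_backprop": batch_guided_backprop,
    "guided_gradcam": batch_guided_gradcam,
    "integrated_gradients": batch_integrated_gradients,
    "deeplift": batch_deeplift,
    "deeplift_shap": batch_deeplift_shap,
    "lrp": batch_lrp,
}


# ---------------------------------------------------------------------------
# public API


def attribute_batch(model, trials: list[TrialVolume], method: str,
                    params: AttributionParams | None = None,
                    targets=None, model_id: str = "run00") -> list[AttributionVolume]:
    """Attribute a batch of trials with one method (shared forward passes).

    ``targets`` defaults to each trial's actual label — decoding decisions
    are always interpreted for the true mental state of the map.
    """
    params = params or AttributionParams()
    params.validate()
    if method not in METHODS:
        raise KeyError(f"unknown attribution method {method!r}; "
                       f"known: {sorted(METHODS)}")
    net = fold_model(model)
    X = np.stack([t.values for t in trials])
    if targets is None:
        targets = [t.label for t in trials]
    t_idx = _target_indices(net, targets)
    rel = METHODS[method](net, X, t_idx, params)
    out = []
    for i, t in enumerate(trials):
        r = rel[i] * t.mask
        out.append(AttributionVolume(
            relevance=r, method=method, target=str(targets[i]),
            model_id=model_id, trial_id=t.trial_id,
            relevance_sum=float(r[t.mask].sum())))
    return out


def _single(method):
    def call(model, x: TrialVolume, target=None, params=None, model_id="run00"):
        return attribute_batch(model, [x], method, params=params,
                               targets=None if target is None else [target],
                               model_id=model_id)[0]
    call.__name__ = method
    call.__qualname__ = method
    call.__doc__ = f"Single-trial wrapper around attribute_batch('{method}')."
    return call


gradient_attribution = _single("gradient")
smoothgrad = _single("smoothgrad")
input_x_gradient = _single("input_x_gradient")
guided_backprop = _single("guided_backprop")
guided_gradcam = _single("guided_gradcam")
integrated_gradients = _single("integrated_gradients")
deeplift = _single("deeplift")
deeplift_shap = _single("deeplift_shap")
lrp = _single("lrp")


def gradcam(model, x: TrialVolume, target=None, params=None):
    """Coarse GradCam relevance on the last convolution grid."""
    params = params or AttributionParams()
    params.validate()
    net = fold_model(model)
    X = x.values[None]
    t_idx = _target_indices(net, [target if target is not None else x.label])
    return batch_gradcam(net, X, t_idx, params)[0]
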