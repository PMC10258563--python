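"""Shared builders for diagnostic models used across the test suite."""

import numpy as np

from neuroxai.decoder import DecoderConfig, TrainedDecoder, build_model


def make_linear_dense_model(grid_shape, w, b=0.0, n_classes=2, target_col=0):
    """Decoder whose logit for class ``target_col`` is exactly w.x + b.

    A dense-only model (no convolutions): the network is globally linear,
    so every attribution method has a closed-form answer.
    """
    cfg = DecoderConfig(n_conv_layers=0, seed=0)
    model = build_model(cfg, grid_shape, [f"c{i}" for i in range(n_classes)],
                        use_bias=True, use_batchnorm=False)
    model.dense.W[:] = 0.0
    model.dense.W[:, target_col] = np.asarray(w, dtype=float).ravel()
    model.dense.b[:] = 0.0
    model.dense.b[target_col] = b
    return model


def make_linear_conv_model(grid_shape, w, conv_weight=1.0, n_classes=2, target_col=0):
    """Single 1x1x1-conv (stride 1, weight a > 0) + dense: f = a * w.x.

    On positive inputs the ReLU is inactive-free, so the model is linear;
    the convolution layer gives GradCam a feature map to pool while the
    coarse grid equals the input grid (upsampling is the identity).
    """
    assert conv_weight > 0
    cfg = DecoderConfig(n_conv_layers=1, n_kernels=1, kernel_size=1, seed=0)
    model = build_model(cfg, grid_shape, [f"c{i}" for i in range(n_classes)],
                        use_bias=False, use_batchnorm=False)
    conv, _ = model.blocks[0]
    conv.stride = 1
    conv.w[:] = conv_weight
    model.final_spatial = tuple(grid_shape)
    from neuroxai import nn
    model.dense = nn.Dense(int(np.prod(grid_shape)), n_classes, bias=False,
                           rng=np.random.default_rng(0))
    model.dense.W[:] = 0.0
    model.dense.W[:, target_col] = np.asarray(w, dtype=float).ravel()
    return model


def train_toy_cnn(grid=(8, 8, 8), n_classes=3, n_layers=2, n_kernels=4,
                  n_trials=40, epochs=8, seed=2, bias_free=True):
    """A small trained CNN (bias-free by default) for sum-rule audits."""
    rng = np.random.default_rng(seed)
    cfg = DecoderConfig(n_conv_layers=n_layers, n_kernels=n_kernels,
                        kernel_size=3, seed=seed)
    model = build_model(cfg, grid, [f"c{i}" for i in range(n_classes)],
                        use_bias=not bias_free, use_batchnorm=not bias_free)
    from neuroxai.decoder import train
    X = rng.normal(size=(n_trials,) + tuple(grid))
    y = np.array([f"c{i}" for i in rng.integers(n_classes, size=n_trials)])
    train(model, (X, y), max_epochs=epochs, min_epochs=epochs, seed=seed)
    return model


def as_trials(X, mask=None, labels=None, subject="sub01", run="run01"):
    """Wrap an array of volumes into TrialVolume objects."""
    from neuroxai.synthetic import TrialVolume
    X = np.asarray(X, dtype=float)
    if mask is None:
        mask = np.ones(X.shape[1:], dtype=bool)
    out = []
    for i in range(X.shape[0]):
        vals = np.where(mask, X[i], 0.0)
        out.append(TrialVolume(values=vals, mask=mask,
                               label="c0" if labels is None else labels[i],
                               subject_id=subject, run_id=run,
                               trial_id=f"t{i:04d}"))
    return out
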