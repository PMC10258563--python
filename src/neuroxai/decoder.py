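"""3D-CNN mental-state decoder: architecture, training, selection, ensembling.

The decoder is a stack of strided 3D-convolution layers (stride 2, batch
normalization on the linear convolution outputs, ReLU, optional dropout)
followed by a dense softmax output layer.  Training minimises cross-entropy
with Adam and stops early once the evaluation loss either fails to improve
on its previous best for three consecutive end-of-epoch evaluations or its
standard deviation over the last 10 evaluations falls to 0.01 or below —
never before epoch 10 and never after epoch 100.

Hyper-parameter selection scores each configuration with
``lambda = eps_V + (eps_V - eps_T)`` over stratified three-fold
cross-validation (mean validation error plus the generalization gap) and
keeps the configuration with the lowest score.  Final fits are a multi-seed
ensemble of 10 runs with fresh 90/10 train/validation splits; the run with
the best evaluation loss is flagged as the primary model.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .synthetic import stack_trials

__all__ = [
    "DecoderConfig",
    "TrainedDecoder",
    "HyperparamScore",
    "build_model",
    "train",
    "evaluate",
    "hyperparameter_search",
    "train_ensemble",
    "full_search_grid",
    "small_search_grid",
]

# the full hyper-parameter search space (192 configurations)
SEARCH_SPACE = {
    "n_conv_layers": [3, 4],
    "n_kernels": [4, 8, 16, 32],
    "kernel_size": [3, 5],
    "batch_size": [32, 64],
    "learning_rate": [3e-4, 1e-3],
    "dropout_rate": [0.0, 0.25, 0.5],
}


@dataclass
class DecoderConfig:
    n_conv_layers: int = 3
    n_kernels: int = 8
    kernel_size: int = 3
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self, strict_grid: bool = False) -> None:
        # 0 conv layers is allowed: a dense-only (linear) diagnostic model
        if self.n_conv_layers < 0 or self.n_kernels < 1 or self.kernel_size < 1:
            raise ValueError("architecture sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid optimization settings")
        if strict_grid:
            for key, domain in SEARCH_SPACE.items():
                if getattr(self, key) not in domain:
                    raise ValueError(f"{key}={getattr(self, key)} outside search domain {domain}")


def full_search_grid(seed: int = 0) -> list[DecoderConfig]:
    """All 192 configurations of the hyper-parameter search space."""
    keys = list(SEARCH_SPACE)
    return [DecoderConfig(**dict(zip(keys, vals)), seed=seed)
            for vals in itertools.product(*SEARCH_SPACE.values())]


def small_search_grid(seed: int = 0) -> list[DecoderConfig]:
    """Reduced 8-point subset of the search space for desk-scale runs."""
    combos = itertools.product([3, 4], [4, 8], [3], [32], [1e-3], [0.0, 0.25])
    keys = list(SEARCH_SPACE)
    return [DecoderConfig(**dict(zip(keys, vals)), seed=seed) for vals in combos]


@dataclass
class HyperparamScore:
    """Cross-validated score of one configuration."""

    config: DecoderConfig
    train_error: float
    val_error: float

    @property
    def lam(self) -> float:
        return self.val_error + (self.val_error - self.train_error)


class TrainedDecoder:
    """A 3D-CNN decoder with its configuration and training history."""

    def __init__(self, config: DecoderConfig, grid_shape, classes,
                 use_bias: bool = True, use_batchnorm: bool = True,
                 rng: np.random.Generator | None = None):
        config.validate()
        grid_shape = tuple(grid_shape)
        if 2 ** config.n_conv_layers > min(grid_shape):
            raise ValueError(
                f"grid {grid_shape} too small for {config.n_conv_layers} stride-2 layers")
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.config = config
        self.grid_shape = grid_shape
        self.classes = np.array(sorted(classes))
        self.use_bias = use_bias
        self.use_batchnorm = use_batchnorm
        self.blocks: list[tuple[nn.Conv3D, nn.BatchNorm3D | None]] = []
        spatial = grid_shape
        in_ch = 1
        for _ in range(config.n_conv_layers):
            conv = nn.Conv3D(in_ch, config.n_kernels, config.kernel_size,
                             stride=2, bias=use_bias, rng=rng)
            bn = nn.BatchNorm3D(config.n_kernels) if use_batchnorm else None
            self.blocks.append((conv, bn))
            spatial = nn.conv_output_shape(spatial, config.kernel_size, 2)
            in_ch = config.n_kernels
        self.final_spatial = spatial
        n_flat = in_ch * int(np.prod(spatial))
        self.dense = nn.Dense(n_flat, len(self.classes), bias=use_bias, rng=rng)
        self.history: list[dict] = []
        self.best_eval_loss: float = np.inf
        self.is_primary: bool = False

    # -- forward / backward ------------------------------------------------

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def parameter_count(self) -> int:
        return sum(int(p.size) for p in self.parameters())

    def parameters(self) -> list[np.ndarray]:
        out = []
        for conv, bn in self.blocks:
            out.extend(conv.params())
            if bn is not None:
                out.extend(bn.params())
        out.extend(self.dense.params())
        return out

    def label_index(self, labels) -> np.ndarray:
        idx = np.searchsorted(self.classes, labels)
        idx = np.clip(idx, 0, len(self.classes) - 1)
        if np.any(self.classes[idx] != np.asarray(labels)):
            raise ValueError("unknown class label")
        return idx

    def _forward(self, X: np.ndarray, train: bool, rng=None):
        """Forward pass on (B, D, H, W) input; returns logits and caches."""
        x = np.asarray(X, dtype=np.float64)[:, None]  # add channel axis
        caches = []
        for conv, bn in self.blocks:
            x_in = x
            z = conv.forward(x_in)
            bn_cache = None
            if bn is not None:
                z_bn, bn_cache = bn.forward(z, train=train)
            else:
                z_bn = z
            a = np.maximum(z_bn, 0.0)
            drop_mask = None
            if train and self.config.dropout_rate > 0:
                keep = 1.0 - self.config.dropout_rate
                drop_mask = (rng.random(a.shape) < keep) / keep
                a = a * drop_mask
            caches.append({"x_in": x_in, "pre_act": z_bn, "bn_cache": bn_cache,
                           "drop_mask": drop_mask})
            x = a
        flat = x.reshape(x.shape[0], -1)
        logits = self.dense.forward(flat)
        return logits, flat, caches

    def forward_logits(self, X: np.ndarray) -> np.ndarray:
        logits, _, _ = self._forward(X, train=False)
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward_logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.forward_logits(X), axis=1)]

    def _backward(self, dlogits: np.ndarray, flat: np.ndarray, caches):
        grads = {}
        dW = flat.T @ dlogits
        grads["dense"] = [dW] if self.dense.b is None else [dW, dlogits.sum(axis=0)]
        da = (dlogits @ self.dense.W.T).reshape(
            (flat.shape[0], self.config.n_kernels) + self.final_spatial)
        block_grads = []
        for idx in range(len(self.blocks) - 1, -1, -1):
            conv, bn = self.blocks[idx]
            cache = caches[idx]
            if cache["drop_mask"] is not None:
                da = da * cache["drop_mask"]
            dz_bn = da * (cache["pre_act"] > 0)
            if bn is not None:
                dz, dgamma, dbeta = bn.backward(dz_bn, cache["bn_cache"])
            else:
                dz, dgamma, dbeta = dz_bn, None, None
            dw, db = conv.param_grad(dz, cache["x_in"])
            g = [dw] if conv.b is None else [dw, db]
            if bn is not None:
                g.extend([dgamma, dbeta])
            block_grads.append(g)
            if idx > 0:
                da = conv.input_grad(dz, cache["x_in"].shape[2:])
        flat_grads = []
        for g in reversed(block_grads):
            flat_grads.extend(g)
        flat_grads.extend(grads["dense"])
        return flat_grads

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays, meta_layers = {}, []
        for i, (conv, bn) in enumerate(self.blocks):
            arrays[f"conv{i}_w"] = conv.w
            if conv.b is not None:
                arrays[f"conv{i}_b"] = conv.b
            if bn is not None:
                arrays[f"bn{i}_gamma"] = bn.gamma
                arrays[f"bn{i}_beta"] = bn.beta
                arrays[f"bn{i}_mean"] = bn.running_mean
                arrays[f"bn{i}_var"] = bn.running_var
        arrays["dense_W"] = self.dense.W
        if self.dense.b is not None:
            arrays["dense_b"] = self.dense.b
        meta = {
            "config": asdict(self.config),
            "grid_shape": list(self.grid_shape),
            "classes": [str(c) for c in self.classes],
            "use_bias": self.use_bias,
            "use_batchnorm": self.use_batchnorm,
            "history": self.history,
            "best_eval_loss": None if not np.isfinite(self.best_eval_loss)
                              else float(self.best_eval_loss),
            "is_primary": self.is_primary,
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TrainedDecoder":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        config = DecoderConfig(**meta["config"])
        model = cls(config, meta["grid_shape"], meta["classes"],
                    use_bias=meta["use_bias"], use_batchnorm=meta["use_batchnorm"])
        for i, (conv, bn) in enumerate(model.blocks):
            conv.w[:] = data[f"conv{i}_w"]
            if conv.b is not None:
                conv.b[:] = data[f"conv{i}_b"]
            if bn is not None:
                bn.gamma[:] = data[f"bn{i}_gamma"]
                bn.beta[:] = data[f"bn{i}_beta"]
                bn.running_mean[:] = data[f"bn{i}_mean"]
                bn.running_var[:] = data[f"bn{i}_var"]
        model.dense.W[:] = data["dense_W"]
        if model.dense.b is not None:
            model.dense.b[:] = data["dense_b"]
        model.history = meta["history"]
        model.best_eval_loss = meta["best_eval_loss"] if meta["best_eval_loss"] is not None else np.inf
        model.is_primary = meta["is_primary"]
        return model

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def build_model(config: DecoderConfig, grid_shape, classes,
                use_bias: bool = True, use_batchnorm: bool = True) -> TrainedDecoder:
    """Construct an (untrained) decoder; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    return TrainedDecoder(config, grid_shape, classes,
                          use_bias=use_bias, use_batchnorm=use_batchnorm, rng=rng)


def should_stop(eval_losses: list[float], min_epochs: int = 10,
                patience: int = 3, sd_window: int = 10,
                sd_threshold: float = 0.01) -> bool:
    """Early-stopping rule on the sequence of end-of-epoch evaluation losses.

    Rule (i): the loss has been worse than its previous best for ``patience``
    consecutive evaluations.  Rule (ii): the standard deviation of the last
    ``sd_window`` recorded losses does not exceed ``sd_threshold``.  Neither
    rule fires during the initial grace period of ``min_epochs`` epochs.
    """
    n = len(eval_losses)
    if n < min_epochs:
        return False
    best_idx = int(np.argmin(eval_losses))
    if n - 1 - best_idx >= patience:
        return True
    if n >= sd_window and float(np.std(eval_losses[-sd_window:])) <= sd_threshold:
        return True
    return False


def _as_arrays(data):
    if isinstance(data, tuple):
        return data
    X, y, _, _, _ = stack_trials(data)
    return X, y


def train(model: TrainedDecoder, train_set, val_split_fraction: float = 0.1,
          max_epochs: int = 100, min_epochs: int = 10,
          seed: int | None = None, val_set=None,
          restore_best: bool = True) -> TrainedDecoder:
    """Train with Adam + cross-entropy and the two-rule early stopping.

    ``train_set`` is a list of :class:`TrialVolume` or an ``(X, y)`` tuple.
    When ``val_set`` is None a random ``val_split_fraction`` of the training
    data is held out for the end-of-epoch evaluations.  The parameters from
    the epoch with the best evaluation loss are restored at the end unless
    ``restore_best`` is False (useful for deliberate-overfitting regimes,
    where the evaluation loss is not the quantity of interest).
    """
    X, y = _as_arrays(train_set)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    seed = model.config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if val_set is None:
        n = len(X)
        n_val = max(1, int(round(val_split_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        X_val, y_val = X[val_idx], y[val_idx]
    else:
        X_tr, y_tr = X, y
        X_val, y_val = _as_arrays(val_set)

    y_tr_idx = model.label_index(y_tr)
    y_val_idx = model.label_index(y_val)
    params = model.parameters()
    opt = nn.Adam(params, lr=model.config.learning_rate)
    bs = model.config.batch_size
    eval_losses: list[float] = []
    best_state = None

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(X_tr))
        losses, correct = [], 0
        for start in range(0, len(X_tr), bs):
            idx = order[start : start + bs]
            logits, flat, caches = model._forward(X_tr[idx], train=True, rng=rng)
            loss, dlogits = nn.cross_entropy(logits, y_tr_idx[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the input scaling")
            grads = model._backward(dlogits, flat, caches)
            opt.step(grads)
            losses.append(loss)
            correct += int((np.argmax(logits, axis=1) == y_tr_idx[idx]).sum())
        val_logits = model.forward_logits(X_val)
        val_loss, _ = nn.cross_entropy(val_logits, y_val_idx)
        val_acc = float((np.argmax(val_logits, axis=1) == y_val_idx).mean())
        eval_losses.append(val_loss)
        model.history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": correct / len(X_tr),
            "eval_loss": float(val_loss),
            "eval_accuracy": val_acc,
        })
        if val_loss < model.best_eval_loss:
            model.best_eval_loss = float(val_loss)
            best_state = [p.copy() for p in params]
        if epoch >= min_epochs and should_stop(eval_losses, min_epochs=min_epochs):
            break
    if restore_best and best_state is not None:
        for p, bp in zip(params, best_state):
            p[:] = bp
    return model


def evaluate(model: TrainedDecoder, trials) -> tuple[float, pd.DataFrame]:
    """Decoding accuracy and a row-normalized confusion matrix.

    Rows are true classes, columns predicted classes (both in the model's
    fixed alphabetical class order); each row sums to 1.
    """
    X, y = _as_arrays(trials)
    if len(X) == 0:
        raise ValueError("no trials to evaluate")
    pred = model.predict(X)
    acc = float((pred == y).mean())
    classes = model.classes
    counts = np.zeros((len(classes), len(classes)))
    for yi, pi in zip(model.label_index(y), model.label_index(pred)):
        counts[yi, pi] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(row_sums > 0, counts / row_sums, 0.0)
    return acc, pd.DataFrame(conf, index=classes, columns=classes)


def hyperparameter_search(grid: list[DecoderConfig], train_data, n_folds: int = 3,
                          max_epochs: int = 100,
                          ) -> tuple[HyperparamScore, pd.DataFrame]:
    """Stratified k-fold scoring of a configuration grid.

    Each configuration's mean decoding error on the fold-training and
    fold-validation data (``eps_T``, ``eps_V``) yields the selection score
    ``lambda = eps_V + (eps_V - eps_T)``; the configuration with the lowest
    score wins.  Returns the winner and the full score table.
    """
    if not grid:
        raise ValueError("empty configuration grid")
    X, y = _as_arrays(train_data)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("a class has fewer trials than folds; stratified folding impossible")
    scores = []
    for cfg in grid:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
        eps_t, eps_v = [], []
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            model = build_model(
                DecoderConfig(**{**asdict(cfg), "seed": cfg.seed + 1000 * fold}),
                X.shape[1:], np.unique(y))
            train(model, (X[tr], y[tr]), val_set=(X[va], y[va]),
                  max_epochs=max_epochs, seed=cfg.seed + 1000 * fold)
            acc_t, _ = evaluate(model, (X[tr], y[tr]))
            acc_v, _ = evaluate(model, (X[va], y[va]))
            eps_t.append(1.0 - acc_t)
            eps_v.append(1.0 - acc_v)
        scores.append(HyperparamScore(cfg, float(np.mean(eps_t)), float(np.mean(eps_v))))
    table = pd.DataFrame([{**asdict(s.config), "train_error": s.train_error,
                           "val_error": s.val_error, "lambda": s.lam} for s in scores])
    best = min(scores, key=lambda s: s.lam)
    return best, table


def train_ensemble(config: DecoderConfig, data, n_runs: int = 10,
                   seeds: list[int] | None = None, max_epochs: int = 100,
                   ) -> list[TrainedDecoder]:
    """Multi-seed ensemble: fresh 90/10 splits and initialisations per run.

    The run with the best evaluation loss is flagged ``is_primary``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_runs)]
    if len(seeds) != n_runs or len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct and match n_runs")
    X, y = _as_arrays(data)
    models = []
    for s in seeds:
        cfg = DecoderConfig(**{**asdict(config), "seed": s})
        model = build_model(cfg, X.shape[1:], np.unique(y))
        train(model, (X, y), seed=s, max_epochs=max_epochs)
        models.append(model)
    best = int(np.argmin([m.best_eval_loss for m in models]))
    models[best].is_primary = True
    return models
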