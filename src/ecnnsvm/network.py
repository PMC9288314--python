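"""The excitation-augmented 1-D CNN (E-CNN) and its training loop.

The fused gene vector of width F is presented to the network as F positions
with a single channel. Two kernel-size-1 convolutions (128 then 64 filters,
ReLU, dropout 0.3 after each) act as shared per-position channel mixers; a
squeeze-and-excitation (SE) block then computes one weight per channel —
global average pooling over positions, a bottleneck FC (compression ratio 4)
with ReLU, an expanding FC with sigmoid — and rescales the channels.
Channel-wise global average pooling feeds a two-layer classification head
FC(64->32, ReLU) -> FC(32->2); the 32-wide penultimate representation is
what the downstream SVM consumes.

Everything is implemented directly on numpy arrays with hand-written
backpropagation, so analytic gradients can be audited against finite
differences, and training is exactly reproducible from a seed on any
machine.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ECNNConfig",
    "ECNNModel",
    "EarlyStopper",
    "pointwise_conv_relu",
    "se_squeeze",
    "se_excite",
    "se_scale",
    "forward",
    "loss_and_grads",
    "softmax_cross_entropy",
    "init_params",
    "train_early_stop",
    "extract_features",
]


@dataclass
class ECNNConfig:
    """Architecture and optimization settings.

    Convolution filter counts, kernel size 1, dropout rates 0.3 and the SE
    compression ratio r=4 follow the reference architecture; bottleneck
    width is ``max(1, conv2_filters // se_ratio)``. ``use_se=False`` yields
    the plain-CNN ablation; ``se_residual`` adds the unweighted activations
    back after channel scaling. ``extract_layer`` selects the representation
    handed to the SVM: the 32-wide penultimate layer (default) or the 2-wide
    logits.
    """

    conv1_filters: int = 128
    conv1_kernel: int = 1
    dropout1_rate: float = 0.3
    conv2_filters: int = 64
    conv2_kernel: int = 1
    dropout2_rate: float = 0.3
    se_ratio: int = 4
    use_se: bool = True
    se_residual: bool = False
    fc_hidden: int = 32
    fc_units: int = 2
    extract_layer: str = "penultimate"   # or "logits"
    max_epochs: int = 300
    patience: int = 20
    batch_size: int = 16
    learning_rate: float = 3e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout1_rate < 1 and 0 <= self.dropout2_rate < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.se_ratio < 1:
            raise ValueError("se_ratio must be >= 1")
        if self.conv1_kernel != 1 or self.conv2_kernel != 1:
            raise ValueError("only kernel size 1 is supported")
        if self.extract_layer not in ("penultimate", "logits"):
            raise ValueError("extract_layer must be 'penultimate' or 'logits'")

    @property
    def se_bottleneck(self) -> int:
        return max(1, self.conv2_filters // self.se_ratio)


# ---------------------------------------------------------------------------
# elementary layers


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    # keep channel weights strictly inside (0, 1) even where float64 saturates
    return np.clip(out, 5e-324, 1.0 - 2**-53)


def pointwise_conv_relu(inp: np.ndarray, kernel: np.ndarray,
                        bias: np.ndarray) -> np.ndarray:
    """Kernel-size-1 convolution with ReLU.

    ``out[n, p, f] = relu(sum_c kernel[f, c] * inp[n, p, c] + bias[f])``;
    the position count is unchanged.
    """
    inp = np.asarray(inp, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if inp.shape[-1] != kernel.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {inp.shape[-1]}, kernel expects "
            f"{kernel.shape[1]}")
    return _relu(inp @ kernel.T + bias)


def se_squeeze(U: np.ndarray) -> np.ndarray:
    """Global average pooling: one scalar per channel, the mean over positions."""
    U = np.asarray(U, dtype=float)
    return U.mean(axis=-2)


def se_excite(z: np.ndarray, W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Channel weights ``s = sigmoid(W2 @ relu(W1 @ z))``, each in (0, 1)."""
    z = np.asarray(z, dtype=float)
    if W1.shape[1] != z.shape[-1] or W2.shape[1] != W1.shape[0]:
        raise ValueError("SE weight shapes inconsistent with channel vector")
    return _sigmoid(_relu(z @ W1.T) @ W2.T)


def se_scale(U: np.ndarray, s: np.ndarray, residual: bool = False) -> np.ndarray:
    """Rescale channels by their weights; ``residual`` adds U back."""
    U = np.asarray(U, dtype=float)
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != U.shape[-1]:
        raise ValueError("one weight per channel required")
    scaled = U * s[..., None, :]
    return U + scaled if residual else scaled


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax class scores; returns (loss, dlogits)."""
    n = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expv = np.exp(shifted)
    probs = expv / expv.sum(axis=1, keepdims=True)
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-300)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# full network


def init_params(n_features: int, config: ECNNConfig,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He initialization for ReLU layers, Glorot for the sigmoid/logit layers."""
    f1, f2 = config.conv1_filters, config.conv2_filters
    b = config.se_bottleneck
    h = config.fc_hidden

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    def glorot(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    return {
        # fitted input width, kept with the parameters so a forward pass can
        # reject vectors of the wrong length (never touched by the optimizer)
        "n_features": np.array(float(n_features)),
        "conv1_w": he((f1, 1), 1),
        "conv1_b": np.zeros(f1),
        "conv2_w": he((f2, f1), f1),
        "conv2_b": np.zeros(f2),
        "se_w1": he((b, f2), f2),
        "se_w2": glorot((f2, b), b, f2),
        "fc1_w": he((h, f2), f2),
        "fc1_b": np.zeros(h),
        "fc2_w": glorot((config.fc_units, h), h, config.fc_units),
        "fc2_b": np.zeros(config.fc_units),
    }


def forward(
    x: np.ndarray,
    params: dict[str, np.ndarray],
    config: ECNNConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
    se_override: np.ndarray | float | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Full forward pass on a batch of fused feature vectors.

    ``x`` has shape (n, F); it is reshaped to F positions x 1 channel. In
    training mode inverted-dropout masks are drawn from ``rng`` (first the
    post-conv1 mask, then the post-conv2 mask, each a Bernoulli(1 - rate)
    draw scaled by 1/(1 - rate)); in eval mode the pass is deterministic.
    ``se_override`` pins the channel weights to a constant (e.g. 1.0 for the
    SE-ablation identity). Returns (logits, cache of named intermediates).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a batch of flat feature vectors")
    n, F = x.shape
    if "n_features" in params and round(float(params["n_features"])) != F:
        raise ValueError(
            f"input width {F} does not match the fitted width "
            f"{round(float(params['n_features']))}")
    x3 = x[:, :, None]
    cache: dict = {"x": x3}

    a1 = pointwise_conv_relu(x3, params["conv1_w"], params["conv1_b"])
    cache["conv1"] = a1
    if training and config.dropout1_rate > 0:
        if rng is None:
            raise ValueError("training mode requires an rng for dropout")
        keep = 1.0 - config.dropout1_rate
        mask1 = (rng.random(a1.shape) < keep) / keep
    else:
        mask1 = None
    d1 = a1 if mask1 is None else a1 * mask1
    cache["mask1"], cache["dropout1"] = mask1, d1

    a2 = pointwise_conv_relu(d1, params["conv2_w"], params["conv2_b"])
    cache["conv2"] = a2
    if training and config.dropout2_rate > 0:
        keep = 1.0 - config.dropout2_rate
        mask2 = (rng.random(a2.shape) < keep) / keep
    else:
        mask2 = None
    d2 = a2 if mask2 is None else a2 * mask2
    cache["mask2"], cache["dropout2"] = mask2, d2

    if se_override is not None:
        s = np.broadcast_to(np.asarray(se_override, dtype=float),
                            (n, config.conv2_filters))
        cache["se_z"] = None
        cache["se_s"] = s
        cache["se_mode"] = "override"
        scaled = se_scale(d2, s, residual=config.se_residual)
    elif config.use_se:
        z = se_squeeze(d2)
        t_pre = z @ params["se_w1"].T
        t = _relu(t_pre)
        s = _sigmoid(t @ params["se_w2"].T)
        cache["se_z"], cache["se_tpre"], cache["se_t"], cache["se_s"] = z, t_pre, t, s
        cache["se_mode"] = "learned"
        scaled = se_scale(d2, s, residual=config.se_residual)
    else:
        cache["se_z"] = cache["se_s"] = None
        cache["se_mode"] = "off"
        scaled = d2
    cache["scaled"] = scaled

    pooled = scaled.mean(axis=1)
    cache["pooled"] = pooled
    h_pre = pooled @ params["fc1_w"].T + params["fc1_b"]
    h = _relu(h_pre)
    cache["fc1_pre"], cache["fc1"] = h_pre, h
    logits = h @ params["fc2_w"].T + params["fc2_b"]
    cache["logits"] = logits
    return logits, cache


def _backward(params: dict, config: ECNNConfig, cache: dict,
              dlogits: np.ndarray) -> dict[str, np.ndarray]:
    """Backpropagate mean-loss gradients through the cached forward pass."""
    F = cache["x"].shape[1]
    grads: dict[str, np.ndarray] = {}
    if "n_features" in params:
        grads["n_features"] = np.zeros(())

    h = cache["fc1"]
    grads["fc2_w"] = dlogits.T @ h
    grads["fc2_b"] = dlogits.sum(axis=0)
    dh = dlogits @ params["fc2_w"]
    dh_pre = dh * (cache["fc1_pre"] > 0)
    grads["fc1_w"] = dh_pre.T @ cache["pooled"]
    grads["fc1_b"] = dh_pre.sum(axis=0)
    dpooled = dh_pre @ params["fc1_w"]

    dscaled = np.broadcast_to(dpooled[:, None, :] / F, cache["scaled"].shape)

    d2 = cache["dropout2"]
    mode = cache["se_mode"]
    if mode == "learned":
        s = cache["se_s"]
        dd2 = dscaled * s[:, None, :]
        ds = (dscaled * d2).sum(axis=1)
        if config.se_residual:
            dd2 = dd2 + dscaled
        ds_pre = ds * s * (1.0 - s)
        grads["se_w2"] = ds_pre.T @ cache["se_t"]
        dt = ds_pre @ params["se_w2"]
        dt_pre = dt * (cache["se_tpre"] > 0)
        grads["se_w1"] = dt_pre.T @ cache["se_z"]
        dz = dt_pre @ params["se_w1"]
        dd2 = dd2 + np.broadcast_to(dz[:, None, :] / F, d2.shape)
    elif mode == "override":
        s = cache["se_s"]
        dd2 = dscaled * s[:, None, :]
        if config.se_residual:
            dd2 = dd2 + dscaled
        grads["se_w1"] = np.zeros_like(params["se_w1"])
        grads["se_w2"] = np.zeros_like(params["se_w2"])
    else:
        dd2 = dscaled
        grads["se_w1"] = np.zeros_like(params["se_w1"])
        grads["se_w2"] = np.zeros_like(params["se_w2"])

    da2 = dd2 if cache["mask2"] is None else dd2 * cache["mask2"]
    da2_pre = da2 * (cache["conv2"] > 0)
    d1 = cache["dropout1"]
    grads["conv2_w"] = np.einsum("npf,npc->fc", da2_pre, d1)
    grads["conv2_b"] = da2_pre.sum(axis=(0, 1))
    dd1 = da2_pre @ params["conv2_w"]

    da1 = dd1 if cache["mask1"] is None else dd1 * cache["mask1"]
    da1_pre = da1 * (cache["conv1"] > 0)
    grads["conv1_w"] = np.einsum("npf,npc->fc", da1_pre, cache["x"])
    grads["conv1_b"] = da1_pre.sum(axis=(0, 1))
    return grads


def loss_and_grads(
    params: dict,
    config: ECNNConfig,
    x: np.ndarray,
    y: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy loss and analytic gradients for one batch."""
    logits, cache = forward(x, params, config, training=training, rng=rng)
    loss, dlogits = softmax_cross_entropy(logits, np.asarray(y, dtype=int))
    return loss, _backward(params, config, cache, dlogits)


# ---------------------------------------------------------------------------
# training


class EarlyStopper:
    """Halt when validation loss fails to improve for `patience` epochs.

    Keeps a snapshot of the parameters at the best validation loss seen so
    far; training resumes from / returns exactly those parameters.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch: int | None = None
        self.best_snapshot = None
        self.bad_epochs = 0

    def update(self, epoch: int, val_loss: float, snapshot) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.best_snapshot = copy.deepcopy(snapshot)
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


class _Adam:
    def __init__(self, params: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_early_stop(
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: ECNNConfig,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Adam minimization of cross-entropy with early stopping.

    Shuffles and minibatches the training set each epoch, evaluates the
    validation loss in eval mode, and stops once it has not improved for
    ``config.patience`` consecutive epochs (or at ``max_epochs``). Returns
    the parameters of the best-validation-loss epoch and a per-epoch history
    of (epoch, train_loss, val_loss, stopped_flag). Fully reproducible from
    ``config.seed``.
    """
    train_x, val_x = np.asarray(train_x, float), np.asarray(val_x, float)
    train_y, val_y = np.asarray(train_y, int), np.asarray(val_y, int)
    if train_x.shape[0] == 0 or val_x.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    params = init_params(train_x.shape[1], config, rng)
    opt = _Adam(params, config.learning_rate)
    stopper = EarlyStopper(config.patience)
    history: list[dict] = []

    n = train_x.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = loss_and_grads(params, config, train_x[idx],
                                         train_y[idx], training=True, rng=rng)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        val_logits, _ = forward(val_x, params, config, training=False)
        val_loss, _ = softmax_cross_entropy(val_logits, val_y)
        stop = stopper.update(epoch, val_loss, params)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                        "val_loss": val_loss, "stopped_flag": stop})
        if stop:
            break
    return stopper.best_snapshot, history


def extract_features(params: dict, config: ECNNConfig,
                     x: np.ndarray) -> np.ndarray:
    """Deterministic eval-mode representation handed to the SVM head.

    Returns the penultimate FC activations (default) or the logits,
    depending on ``config.extract_layer``.
    """
    if params is None:
        raise ValueError("model is not fitted")
    _, cache = forward(x, params, config, training=False)
    return cache["fc1"] if config.extract_layer == "penultimate" else cache["logits"]


# ---------------------------------------------------------------------------
# checkpointing


@dataclass
class ECNNModel:
    """A fitted network: config, parameters, and training history."""

    config: ECNNConfig
    params: dict[str, np.ndarray] | None = None
    history: list[dict] = field(default_factory=list)

    SCHEMA = 1

    def fit(self, train_x, train_y, val_x, val_y) -> "ECNNModel":
        self.params, self.history = train_early_stop(
            train_x, train_y, val_x, val_y, self.config)
        return self

    @property
    def best_val_loss(self) -> float:
        if not self.history:
            raise ValueError("model is not fitted")
        return min(h["val_loss"] for h in self.history)

    def extract(self, x: np.ndarray) -> np.ndarray:
        return extract_features(self.params, self.config, x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        logits, _ = forward(x, self.params, self.config, training=False)
        return logits.argmax(axis=1)

    def save(self, path: str | Path) -> None:
        if self.params is None:
            raise ValueError("cannot checkpoint an unfitted model")
        blob = {
            "schema_version": self.SCHEMA,
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "history": self.history,
        }
        Path(path).write_text(json.dumps(blob, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ECNNModel":
        blob = json.loads(Path(path).read_text())
        if blob.get("schema_version") != cls.SCHEMA:
            raise ValueError("unsupported checkpoint schema")
        model = cls(ECNNConfig(**blob["config"]))
        model.params = {k: np.asarray(v, dtype=float)
                        for k, v in blob["params"].items()}
        model.history = blob["history"]
        return model
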