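"""Compact convolutional identifier for spectro-temporal gait images.

One model is trained per (sensor, modality) source.  The network maps a
fixed-size TF image to an M-class posterior over subjects:

    CONV3x3x32(pad 1) - ReLU - POOL2x2
    CONV3x3x32(pad 1) - ReLU - POOL2x2
    CONV3x3x64(pad 1) - ReLU - POOL2x2
    FC 64 - ReLU - FC M - softmax

Convolutions preserve spatial size via padding; each pooling stage halves it
(120 -> 60 -> 30 -> 15), so the input side length must be divisible by 8.
Training is plain mini-batch SGD with momentum on the softmax cross-entropy
loss, run for a fixed number of epochs; there is no augmentation, dropout or
weight decay.  All parameter initialization and batch shuffling flow from the
config seed, so runs are bit-reproducible.

The implementation is pure numpy (im2col convolutions, index-routed pooling,
explicit backprop), which keeps every layer's arithmetic transparent enough
to check against brute-force loop oracles and finite-difference gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from numpy.lib.stride_tricks import sliding_window_view


# ---------------------------------------------------------------------------
# Layer primitives.  Tensors are (batch, channels, height, width).
# ---------------------------------------------------------------------------

def conv_forward(x: np.ndarray, w: np.ndarray, bias: Optional[np.ndarray] = None,
                 stride: int = 1, padding: int = 0) -> np.ndarray:
    """Cross-correlation of ``x`` (B,C,H,W) with filters ``w`` (K,C,kh,kw)."""
    x = np.asarray(x)
    w = np.asarray(w)
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv_forward expects 4D input and filter tensors")
    if x.shape[1] != w.shape[1]:
        raise ValueError(f"channel mismatch: input {x.shape[1]}, filter {w.shape[1]}")
    K, C, kh, kw = w.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    B, _, H, W = x.shape
    if kh > H or kw > W:
        raise ValueError("filter larger than (padded) input")
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # windows: (B, C, OH, OW, kh, kw)
    out = np.einsum("bcijhw,kchw->bkij", windows, w, optimize=True)
    if bias is not None:
        out += np.asarray(bias).reshape(1, -1, 1, 1)
    return out


def pool_forward(x: np.ndarray, window: Tuple[int, int], stride: int,
                 mode: str = "max") -> np.ndarray:
    """Per-window max (or min) pooling per channel."""
    x = np.asarray(x)
    hp, wp = window
    B, C, H, W = x.shape
    if hp > H or wp > W:
        raise ValueError("pooling window larger than input")
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    windows = sliding_window_view(x, (hp, wp), axis=(2, 3))[:, :, ::stride, ::stride]
    op = np.max if mode == "max" else np.min
    return op(windows, axis=(-2, -1))


def relu_forward(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


def log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# Trainable layers with backprop
# ---------------------------------------------------------------------------

class Layer:
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3-style same-convolution with stride 1 (general forward, stride-1 backward)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: int, rng: np.random.Generator, dtype=np.float32):
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # fan-in (He) scaling for ReLU stacks
        self.w = rng.normal(0.0, scale,
                            size=(out_channels, in_channels, kernel, kernel)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.padding = padding
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return conv_forward(x, self.w, self.b, stride=1, padding=self.padding)

    def backward(self, grad):
        x, p = self._x, self.padding
        K, C, kh, kw = self.w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))
        self.grads[0][...] = np.einsum("bcijhw,bkij->kchw", windows, grad,
                                       optimize=True)
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        # dx: full correlation of grad with the spatially-flipped, transposed kernel
        q = kh - 1 - p
        gp = np.pad(grad, ((0, 0), (0, 0), (q, q), (q, q)))
        w_t = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, K, kh, kw)
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        return np.einsum("bkijhw,ckhw->bcij", gwin, w_t, optimize=True)


class ReLULayer(Layer):
    def __init__(self):
        self.params, self.grads = [], []
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return relu_forward(x)

    def backward(self, grad):
        return grad * self._mask


class Pool2D(Layer):
    """Non-overlapping 2x2 max/min pooling with index-routed backprop.

    Gradient is routed to the first extremal element of each window (row-major),
    so backprop is deterministic even with ties.
    """

    def __init__(self, size: int = 2, mode: str = "max"):
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self.size, self.mode = size, mode
        self.params, self.grads = [], []
        self._idx = None
        self._shape = None

    def forward(self, x, train=False):
        s = self.size
        B, C, H, W = x.shape
        if H % s or W % s:
            raise ValueError("input spatial size must be divisible by the pool size")
        xr = x.reshape(B, C, H // s, s, W // s, s).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // s, W // s, s * s)
        pick = np.argmax(xr, axis=-1) if self.mode == "max" else np.argmin(xr, axis=-1)
        out = np.take_along_axis(xr, pick[..., None], axis=-1)[..., 0]
        if train:
            self._idx = pick
            self._shape = (B, C, H, W)
        return out

    def backward(self, grad):
        s = self.size
        B, C, H, W = self._shape
        flat = np.zeros((B, C, H // s, W // s, s * s), dtype=grad.dtype)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(B, C, H // s, W // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(B, C, H, W)


class Flatten(Layer):
    def __init__(self):
        self.params, self.grads = [], []
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class DcnnConfig:
    """Training hyper-parameters of one per-source identifier.

    The defaults are the fixed operating point of the method: learning rate
    0.001, momentum 0.9, feature maps 32/64, 64 fully-connected units, batch
    size 40 and exactly 19 epochs (training is terminated there rather than
    early-stopped).
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    feature_maps: Tuple[int, int, int] = (32, 32, 64)
    fc_units: int = 64
    batch_size: int = 40
    epochs: int = 19
    input_channels: int = 3
    num_classes: int = 10
    image_size: int = 120
    pool_mode: str = "max"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.image_size % 8:
            raise ValueError("image size must survive three 2x2 pooling stages")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")


class Model:
    """An ordered layer stack with softmax cross-entropy training."""

    def __init__(self, layers: Sequence[Layer], cfg: DcnnConfig,
                 source_id: Optional[Tuple[int, str]] = None):
        self.layers = list(layers)
        self.cfg = cfg
        self.source_id = source_id
        self.history: List[Dict] = []

    # -- inference ---------------------------------------------------------

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        dtype = np.dtype(self.cfg.dtype)
        out = np.asarray(x, dtype=dtype)
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    def predict_scores(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Log-softmax scores (the S_{i,j} consumed by fusion) and posteriors."""
        x = np.asarray(x)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if x.shape[1] != self.cfg.input_channels:
            raise ValueError(f"expected {self.cfg.input_channels} channels, "
                             f"got {x.shape[1]}")
        log_p = log_softmax(self.logits(x).astype(np.float64))
        post = np.exp(log_p)
        if squeeze:
            return log_p[0], post[0]
        return log_p, post

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class labels in 1..M; argmax ties break toward the lowest label."""
        log_p, _ = self.predict_scores(x)
        return np.argmax(log_p, axis=-1) + 1

    # -- training ----------------------------------------------------------

    def _loss_and_grad(self, x, y0):
        z = self.logits(x, train=True)
        log_p = log_softmax(z.astype(np.float64))
        B = x.shape[0]
        loss = -log_p[np.arange(B), y0].mean()
        grad = np.exp(log_p)
        grad[np.arange(B), y0] -= 1.0
        grad = (grad / B).astype(z.dtype)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, log_p

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)


def build_model(cfg: DcnnConfig,
                source_id: Optional[Tuple[int, str]] = None) -> Model:
    """Assemble the (untrained) layer stack with seeded initialization."""
    rng = np.random.default_rng(cfg.seed)
    dtype = np.dtype(cfg.dtype)
    f1, f2, f3 = cfg.feature_maps
    side = cfg.image_size // 8
    layers = [
        Conv2D(cfg.input_channels, f1, 3, 1, rng, dtype), ReLULayer(),
        Pool2D(2, cfg.pool_mode),
        Conv2D(f1, f2, 3, 1, rng, dtype), ReLULayer(), Pool2D(2, cfg.pool_mode),
        Conv2D(f2, f3, 3, 1, rng, dtype), ReLULayer(), Pool2D(2, cfg.pool_mode),
        Flatten(),
        Dense(side * side * f3, cfg.fc_units, rng, dtype), ReLULayer(),
        Dense(cfg.fc_units, cfg.num_classes, rng, dtype),
    ]
    return Model(layers, cfg, source_id=source_id)


def train_model(model: Model, images: np.ndarray, labels: np.ndarray,
                cfg: Optional[DcnnConfig] = None,
                val_images: Optional[np.ndarray] = None,
                val_labels: Optional[np.ndarray] = None) -> Model:
    """Mini-batch SGD with momentum for exactly ``cfg.epochs`` epochs.

    ``labels`` are subject ids in 1..M.  Per-epoch mean loss and training
    accuracy (and validation accuracy, when a validation set is given) are
    appended to ``model.history``.  Deterministic given the config seed.
    """
    cfg = cfg or model.cfg
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.ndim != 4:
        raise ValueError("images must be (B, C, H, W)")
    if labels.min() < 1 or labels.max() > cfg.num_classes:
        raise ValueError("labels must lie in 1..num_classes")
    if len(images) < 1:
        raise ValueError("need at least one training image")
    y0 = labels - 1
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xBA7C)))
    velocity = [np.zeros_like(p) for p, _ in model.parameters()]
    n = len(images)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            loss, log_p = model._loss_and_grad(images[idx], y0[idx])
            losses.append(loss * len(idx))
            correct += int((np.argmax(log_p, axis=1) == y0[idx]).sum())
            for v, (p, g) in zip(velocity, model.parameters()):
                v *= cfg.momentum
                v -= cfg.learning_rate * g
                p += v
        record = {"epoch": epoch + 1,
                  "loss": float(np.sum(losses) / n),
                  "train_acc": 100.0 * correct / n}
        if val_images is not None and len(val_images):
            record["val_acc"] = float(
                100.0 * np.mean(model.predict(val_images) == val_labels))
        model.history.append(record)
    return model


# ---------------------------------------------------------------------------
# Serialization: binary parameter container + JSON sidecar
# ---------------------------------------------------------------------------

def _base(path: str) -> str:
    path = str(path)
    return path[:-4] if path.endswith(".npz") else path


def save_model(model: Model, path: str) -> None:
    """Write parameters to ``<path>.npz`` and config/history to ``<path>.json``."""
    arrays = {}
    for i, (p, _) in enumerate(model.parameters()):
        arrays[f"p{i}"] = p
    np.savez(_base(path) + ".npz", **arrays)
    sidecar = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in vars(model.cfg).items()},
               "source_id": list(model.source_id) if model.source_id else None,
               "history": model.history}
    with open(_base(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path: str) -> Model:
    with open(_base(path) + ".json") as fh:
        sidecar = json.load(fh)
    c = sidecar["config"]
    c["feature_maps"] = tuple(c["feature_maps"])
    cfg = DcnnConfig(**c)
    src = tuple(sidecar["source_id"]) if sidecar["source_id"] else None
    model = build_model(cfg, source_id=src)
    data = np.load(_base(path) + ".npz")
    for i, (p, _) in enumerate(model.parameters()):
        p[...] = data[f"p{i}"]
    model.history = sidecar["history"]
    return model
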