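"""Convolutional feature extractor with hand-written backpropagation.

A small stack of convolution, subsampling (non-overlapping 2 x 2
pooling), and dense layers maps a fixed-size protein matrix to a
2-class score, and the activations of the penultimate dense layer are
taken as the learned feature representation Gamma fed to the
downstream classifier.

Layer semantics
    conv        valid cross-correlation + bias + activation g
    subsample   2 x 2 non-overlapping pooling (mean by default, max by
                config); odd trailing rows/columns are dropped
    dense       affine + activation g (the final dense layer is linear;
                its softmax lives in the loss / predicted
                probabilities)

The training objective is cross-entropy H(W, b) of the softmax class
probabilities plus an L2 weight penalty (theta/2) * sum(W^2) over all
kernels and dense weight matrices (biases are not penalized).
Optimization is full-batch gradient descent with a fixed learning rate
epsilon; initialization is seeded uniform(-0.1, 0.1) weights and zero
biases, so training is deterministic given the seed and data order.

Everything is plain numpy; gradients are analytic and are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DivergenceError, ShapeError

__all__ = [
    "CNNConfig",
    "CNNModel",
    "build_cnn",
    "cnn_forward",
    "cnn_loss",
    "cnn_train",
    "cnn_extract",
    "cnn_extract_batch",
    "save_checkpoint",
    "load_checkpoint",
]

# --- activations ----------------------------------------------------------

def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z, a):
    return (z > 0).astype(z.dtype)


def _identity(z):
    return z


def _identity_grad(z, a):
    return np.ones_like(z)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _sigmoid_grad(z, a):
    return a * (1.0 - a)


def _tanh(z):
    return np.tanh(z)


def _tanh_grad(z, a):
    return 1.0 - a * a


ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "identity": (_identity, _identity_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "tanh": (_tanh, _tanh_grad),
}


@dataclass
class CNNConfig:
    """Architecture and training hyper-parameters.

    ``layers`` is an ordered list of specs:
    ``("conv", out_channels, kernel_size)``, ``("subsample", width)``,
    ``("dense", width)``.  The last layer must be ``("dense", 2)`` (the
    binary class head); the dense layer before it is the feature layer.
    ``theta`` is the L2 penalty strength, ``epsilon`` the learning
    rate; both default small because the planted-signal problems this
    package trains on are easy and over-regularization only slows
    convergence.
    """

    layers: list[tuple] = field(
        default_factory=lambda: [
            ("conv", 8, 3),
            ("subsample", 2),
            ("conv", 16, 3),
            ("subsample", 2),
            ("dense", 128),
            ("dense", 2),
        ]
    )
    input_shape: tuple[int, int, int] = (1, 20, 20)  # channels, H, W
    theta: float = 1e-4
    epsilon: float = 0.05
    epochs: int = 15
    seed: int = 0
    activation: str = "relu"
    pooling: str = "mean"

    def validate(self) -> None:
        kinds = [spec[0] for spec in self.layers]
        if "conv" not in kinds or "dense" not in kinds:
            raise ShapeError("architecture needs at least one conv and one dense layer")
        if self.layers[-1] != ("dense", 2):
            raise ShapeError("last layer must be ('dense', 2) — the binary class head")
        if self.activation not in ACTIVATIONS:
            raise ShapeError(f"unknown activation {self.activation!r}")
        if self.pooling not in ("mean", "max"):
            raise ShapeError(f"unknown pooling {self.pooling!r}")
        if self.theta < 0 or self.epsilon < 0:
            raise ShapeError("theta and epsilon must be non-negative")


# --- layers ---------------------------------------------------------------


class _Conv:
    """Valid cross-correlation with per-output-channel bias."""

    has_weights = True

    def __init__(self, w: np.ndarray, b: np.ndarray, act: str):
        self.w = w  # (C_out, C_in, k, k)
        self.b = b  # (C_out,)
        self.act = act

    def out_shape(self, in_shape):
        c, h, w = in_shape
        co, ci, k, _ = self.w.shape
        if ci != c:
            raise ShapeError(f"conv expects {ci} input channels, got {c}")
        if h < k or w < k:
            raise ShapeError(f"input {h}x{w} smaller than kernel {k}")
        return (co, h - k + 1, w - k + 1)

    def forward(self, x):
        k = self.w.shape[-1]
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        z = np.einsum("bchwij,ocij->bohw", windows, self.w, optimize=True)
        z += self.b[None, :, None, None]
        g, _ = ACTIVATIONS[self.act]
        a = g(z)
        self._cache = (windows, z, a)
        return a

    def backward(self, dout):
        windows, z, a = self._cache
        _, dg = ACTIVATIONS[self.act]
        dz = dout * dg(z, a)
        self.dw = np.einsum("bchwij,bohw->ocij", windows, dz, optimize=True)
        self.db = dz.sum(axis=(0, 2, 3))
        b, co, ho, wo = dz.shape
        k = self.w.shape[-1]
        dx = np.zeros((b, self.w.shape[1], ho + k - 1, wo + k - 1))
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + ho, j : j + wo] += np.einsum(
                    "bohw,oc->bchw", dz, self.w[:, :, i, j], optimize=True
                )
        return dx


class _Pool:
    """Non-overlapping p x p mean or max pooling; trailing remainder dropped."""

    has_weights = False

    def __init__(self, p: int, mode: str):
        self.p = p
        self.mode = mode

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if h < self.p or w < self.p:
            raise ShapeError(f"map {h}x{w} smaller than pooling window {self.p}")
        return (c, h // self.p, w // self.p)

    def forward(self, x):
        p = self.p
        b, c, h, w = x.shape
        hc, wc = (h // p) * p, (w // p) * p
        tiles = x[:, :, :hc, :wc].reshape(b, c, hc // p, p, wc // p, p)
        if self.mode == "mean":
            out = tiles.mean(axis=(3, 5))
            self._cache = (x.shape, None)
        else:
            flat = tiles.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, hc // p, wc // p, p * p)
            idx = flat.argmax(axis=-1)
            out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
            self._cache = (x.shape, idx)
        return out

    def backward(self, dout):
        p = self.p
        shape, idx = self._cache
        b, c, h, w = shape
        hc, wc = (h // p) * p, (w // p) * p
        dx = np.zeros(shape)
        if self.mode == "mean":
            up = np.repeat(np.repeat(dout, p, axis=2), p, axis=3) / (p * p)
            dx[:, :, :hc, :wc] = up
        else:
            dtiles = np.zeros((b, c, hc // p, wc // p, p * p))
            np.put_along_axis(dtiles, idx[..., None], dout[..., None], axis=-1)
            dx[:, :, :hc, :wc] = (
                dtiles.reshape(b, c, hc // p, wc // p, p, p)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(b, c, hc, wc)
            )
        return dx


class _Dense:
    """Affine map on the flattened input, optional activation."""

    has_weights = True

    def __init__(self, w: np.ndarray, b: np.ndarray, act: str):
        self.w = w  # (n_in, n_out)
        self.b = b
        self.act = act  # "identity" for the class head

    def out_shape(self, in_shape):
        n_in = int(np.prod(in_shape))
        if n_in != self.w.shape[0]:
            raise ShapeError(f"dense expects {self.w.shape[0]} inputs, got {n_in}")
        return (self.w.shape[1],)

    def forward(self, x):
        xf = x.reshape(x.shape[0], -1)
        z = xf @ self.w + self.b
        g, _ = ACTIVATIONS[self.act]
        a = g(z)
        self._cache = (x.shape, xf, z, a)
        return a

    def backward(self, dout):
        in_shape, xf, z, a = self._cache
        _, dg = ACTIVATIONS[self.act]
        dz = dout * dg(z, a)
        self.dw = xf.T @ dz
        self.db = dz.sum(axis=0)
        return (dz @ self.w.T).reshape(in_shape)


@dataclass
class CNNModel:
    """A built network: layer objects with consistent shapes + config."""

    layers: list
    config: CNNConfig

    @property
    def weights(self) -> list[np.ndarray]:
        return [lay.w for lay in self.layers if lay.has_weights]

    @property
    def biases(self) -> list[np.ndarray]:
        return [lay.b for lay in self.layers if lay.has_weights]

    @property
    def feature_width(self) -> int:
        dense = [lay for lay in self.layers if isinstance(lay, _Dense)]
        return dense[-2].w.shape[1]


def build_cnn(config: CNNConfig | None = None) -> CNNModel:
    """Instantiate a network with seeded uniform(-0.1, 0.1) weights."""
    config = config or CNNConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.input_shape)
    layers: list = []
    n_dense_remaining = sum(1 for s in config.layers if s[0] == "dense")
    for spec in config.layers:
        kind = spec[0]
        if kind == "conv":
            _, c_out, k = spec
            w = rng.uniform(-0.1, 0.1, size=(c_out, shape[0], k, k))
            lay = _Conv(w, np.zeros(c_out), config.activation)
        elif kind == "subsample":
            lay = _Pool(spec[1], config.pooling)
        elif kind == "dense":
            n_in = int(np.prod(shape))
            _, width = spec
            w = rng.uniform(-0.1, 0.1, size=(n_in, width))
            n_dense_remaining -= 1
            act = "identity" if n_dense_remaining == 0 else config.activation
            lay = _Dense(w, np.zeros(width), act)
        else:
            raise ShapeError(f"unknown layer kind {kind!r}")
        shape = lay.out_shape(shape)
        layers.append(lay)
    return CNNModel(layers=layers, config=config)


def _as_batch(m: CNNModel, x: np.ndarray) -> np.ndarray:
    """Coerce (H,W), (C,H,W) or (B,C,H,W) input to a batch."""
    x = np.asarray(x, dtype=float)
    c, h, w = m.config.input_shape
    if x.shape == (h, w):
        x = x[None, None]
    elif x.shape == (c, h, w):
        x = x[None]
    elif x.ndim != 4 or x.shape[1:] != (c, h, w):
        raise ShapeError(f"input shape {x.shape} incompatible with {(c, h, w)}")
    return x


def _forward_batch(m: CNNModel, x: np.ndarray) -> list[np.ndarray]:
    trace = []
    out = x
    for lay in m.layers:
        out = lay.forward(out)
        trace.append(out)
    return trace


def cnn_forward(m: CNNModel, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Run one input through the network.

    Returns the final 2-vector of (pre-softmax) class scores and the
    trace of all intermediate maps, one per layer.
    """
    batch = _as_batch(m, x)
    trace = _forward_batch(m, batch)
    if batch.shape[0] == 1 and np.asarray(x).ndim < 4:
        return trace[-1][0], [t[0] for t in trace]
    return trace[-1], trace


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _penalty(m: CNNModel) -> float:
    return 0.5 * m.config.theta * sum(float((w ** 2).sum()) for w in m.weights)


def cnn_loss(m: CNNModel, batch: tuple[np.ndarray, np.ndarray]) -> float:
    """Mean cross-entropy over the batch + (theta/2) * sum of squared weights."""
    x, y = batch
    x = _as_batch(m, x)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ShapeError("empty batch")
    logits = _forward_batch(m, x)[-1]
    p = _softmax(logits)
    data_term = -float(np.mean(np.log(p[np.arange(len(y)), y] + 1e-300)))
    return data_term + _penalty(m)


def cnn_train(
    m: CNNModel,
    data: tuple[np.ndarray, np.ndarray],
    cfg: CNNConfig | None = None,
) -> CNNModel:
    """Full-batch gradient descent on the regularized cross-entropy.

    Every epoch: forward the whole training set, backpropagate, and
    update each weight ``W <- W - epsilon * (dH/dW + theta * W)`` and
    bias ``b <- b - epsilon * dH/db``.  Deterministic given the seeded
    initialization and data order.  Raises :class:`DivergenceError`
    naming the epoch if the loss goes non-finite.
    """
    cfg = cfg or m.config
    x, y = data
    x = _as_batch(m, x)
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ShapeError("empty training set")
    n = len(y)
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y] = 1.0

    for epoch in range(cfg.epochs):
        trace = _forward_batch(m, x)
        logits = trace[-1]
        p = _softmax(logits)
        loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-300))) + _penalty(m)
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        grad = (p - onehot) / n
        for lay in reversed(m.layers):
            grad = lay.backward(grad)
        for lay in m.layers:
            if lay.has_weights:
                lay.w -= cfg.epsilon * (lay.dw + cfg.theta * lay.w)
                lay.b -= cfg.epsilon * lay.db
    return m


def cnn_extract(m: CNNModel, x: np.ndarray) -> np.ndarray:
    """Feature vector Gamma: activations of the penultimate dense layer."""
    return cnn_extract_batch(m, _as_batch(m, x))[0] if np.asarray(x).ndim < 4 \
        else cnn_extract_batch(m, x)


def cnn_extract_batch(m: CNNModel, x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`cnn_extract` over a batch, (B, feature_width)."""
    x = _as_batch(m, x)
    dense_positions = [i for i, lay in enumerate(m.layers) if isinstance(lay, _Dense)]
    penultimate = dense_positions[-2]
    out = x
    for lay in m.layers[: penultimate + 1]:
        out = lay.forward(out)
    return out


# --- checkpoints ----------------------------------------------------------


def save_checkpoint(m: CNNModel, path: str | Path) -> None:
    """Write config (JSON) + parameter arrays; loads back bit-exactly."""
    cfg = m.config
    header = {
        "layers": [list(s) for s in cfg.layers],
        "input_shape": list(cfg.input_shape),
        "theta": cfg.theta,
        "epsilon": cfg.epsilon,
        "epochs": cfg.epochs,
        "seed": cfg.seed,
        "activation": cfg.activation,
        "pooling": cfg.pooling,
    }
    arrays = {}
    for i, lay in enumerate(m.layers):
        if lay.has_weights:
            arrays[f"w{i}"] = lay.w
            arrays[f"b{i}"] = lay.b
    np.savez(path, config=json.dumps(header), **arrays)


def load_checkpoint(path: str | Path) -> CNNModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["config"]))
        cfg = CNNConfig(
            layers=[tuple(s) for s in header["layers"]],
            input_shape=tuple(header["input_shape"]),
            theta=header["theta"],
            epsilon=header["epsilon"],
            epochs=header["epochs"],
            seed=header["seed"],
            activation=header["activation"],
            pooling=header["pooling"],
        )
        m = build_cnn(cfg)
        for i, lay in enumerate(m.layers):
            if lay.has_weights:
                lay.w = data[f"w{i}"].copy()
                lay.b = data[f"b{i}"].copy()
    return m
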