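"""Multivariate time-series classifiers in pure numpy.

Four architectures for classifying neurons from windows of multichannel time
series (spike counts plus behavioral covariates), with manual backpropagation
and an RMSprop mini-batch trainer:

* **MLP** — five fully connected layers, hidden widths 10/7/4, ReLU;
* **CNN** — three 1-D convolutions (10/7/4 filters, kernel 3, ReLU), max-pool
  after the second, global average pooling, dense head;
* **MCDCNN** — two 1-D convolutions applied to each input channel
  independently (filter/kernel presets (4,3), (3,2), (2,1)), batch
  normalization + ReLU, channel concatenation, dense 128 + ReLU, dropout 0.5;
* **LSTM** — two recurrent layers of 6 and 4 units.

Inputs are arrays of shape (N, M, T): N samples, M channels, T time bins.
Each channel is z-scored with training-split statistics before entering the
network.  All randomness (weight init, batch order, dropout masks) is driven
by explicit seeds, so training is bit-reproducible on a fixed machine
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "TrainedClassifier",
    "MCDCNN_PRESETS",
    "build_model",
    "build_mlp",
    "build_cnn",
    "build_mcdcnn",
    "build_lstm",
    "train_classifier",
    "evaluate",
    "ChannelScaler",
]

DTYPE = np.float32

#: MCDCNN (filters, kernel) presets: full-size, simulation / 4-class, and
#: 5-class variants
MCDCNN_PRESETS = ((4, 3), (3, 2), (2, 1))


# ---------------------------------------------------------------------------
# layers

class Layer:
    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Conv1D(Layer):
    """Valid 1-D convolution on (N, C, L) -> (N, F, L - k + 1)."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng):
        fan_in = in_channels * kernel
        self.W = _glorot(rng, (filters, in_channels, kernel), fan_in, filters)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        if x.shape[2] < self.kernel:
            raise ValueError(
                f"input length {x.shape[2]} shorter than kernel {self.kernel}"
            )
        win = sliding_window_view(x, self.kernel, axis=2)  # (N, C, Lout, k)
        self._win = win
        self._in_shape = x.shape
        out = np.einsum("nclk,fck->nfl", win, self.W, optimize=True)
        return out + self.b[None, :, None]

    def backward(self, dout):
        self.dW[...] = np.einsum("nclk,nfl->fck", self._win, dout, optimize=True)
        self.db[...] = dout.sum(axis=(0, 2))
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        L_out = dout.shape[2]
        for j in range(self.kernel):
            dx[:, :, j : j + L_out] += np.einsum(
                "nfl,fc->ncl", dout, self.W[:, :, j], optimize=True
            )
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; a trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train):
        n, c, length = x.shape
        lo = length // self.pool
        self._in_shape = x.shape
        xt = x[:, :, : lo * self.pool].reshape(n, c, lo, self.pool)
        self._arg = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, dout):
        n, c, lo = dout.shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dxt = dx[:, :, : lo * self.pool].reshape(n, c, lo, self.pool)
        np.put_along_axis(dxt, self._arg[..., None], dout[..., None], axis=3)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x, train):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (N, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=DTYPE)
        self.run_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = (
                self.momentum * self.run_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.run_var = (
                self.momentum * self.run_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        self._train = train
        self._m = x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dout):
        self.dgamma[...] = (dout * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        if not self._train:
            return dxhat / self._std[None, :, None]
        m = self._m
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True) / m
        )
        return term / self._std[None, :, None]


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single LSTM layer over (N, C, L).

    Gates use logistic activations; the cell candidate and cell output use
    tanh (the standard formulation).  ``return_sequences`` yields (N, H, L),
    otherwise the final hidden state (N, H).
    """

    def __init__(self, n_in: int, units: int, rng, return_sequences: bool):
        h = units
        self.Wx = _glorot(rng, (n_in, 4 * h), n_in, h)
        self.Wh = _glorot(rng, (h, 4 * h), h, h)
        self.b = np.zeros(4 * h, dtype=DTYPE)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.units = h
        self.return_sequences = return_sequences

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x, train):
        n, c, length = x.shape
        h = self.units
        self._x = x
        hs = np.zeros((length, n, h), dtype=DTYPE)
        cs = np.zeros((length, n, h), dtype=DTYPE)
        cache = []
        h_prev = np.zeros((n, h), dtype=DTYPE)
        c_prev = np.zeros((n, h), dtype=DTYPE)
        for t in range(length):
            xt = x[:, :, t]
            z = xt @ self.Wx + h_prev @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            cache.append((xt, h_prev, c_prev, i, f, g, o, tc))
            hs[t], cs[t] = h_t, c_t
            h_prev, c_prev = h_t, c_t
        self._cache = cache
        if self.return_sequences:
            return hs.transpose(1, 2, 0)  # (N, H, L)
        return hs[-1]

    def backward(self, dout):
        n, c, length = self._x.shape
        h = self.units
        if self.return_sequences:
            dh_seq = dout.transpose(2, 0, 1)  # (L, N, H)
        else:
            dh_seq = np.zeros((length, n, h), dtype=dout.dtype)
            dh_seq[-1] = dout
        self.dWx[...] = 0
        self.dWh[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((n, h), dtype=dout.dtype)
        dc_next = np.zeros((n, h), dtype=dout.dtype)
        for t in range(length - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dh_seq[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.dWx += xt.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, :, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx


# ---------------------------------------------------------------------------
# models

class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class MCDCNNNet:
    """Per-channel convolutional branches feeding a shared dense classifier."""

    def __init__(self, branches: list, trunk: Sequential):
        self.branches = branches
        self.trunk = trunk

    def forward(self, x, train=False):
        outs = []
        self._split = []
        for c, branch in enumerate(self.branches):
            o = branch.forward(x[:, c : c + 1, :], train)
            self._split.append(o.shape[1])
            outs.append(o)
        return self.trunk.forward(np.concatenate(outs, axis=1), train)

    def backward(self, dout):
        dcat = self.trunk.backward(dout)
        start = 0
        for c, branch in enumerate(self.branches):
            width = self._split[c]
            branch.backward(dcat[:, start : start + width])
            start += width
        return None

    def params(self):
        out = [p for b in self.branches for p in b.params()]
        return out + self.trunk.params()

    def grads(self):
        out = [g for b in self.branches for g in b.grads()]
        return out + self.trunk.grads()

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


# ---------------------------------------------------------------------------
# specs and builders

@dataclass
class ClassifierSpec:
    """Architecture and input-space description of one classifier."""

    arch: str  # mlp | cnn | mcdcnn | lstm
    n_channels: int
    window_len: int
    n_classes: int
    arch_params: dict = field(default_factory=dict)
    final_activation: str = "softmax"  # or "sigmoid" (binary only)

    def __post_init__(self) -> None:
        if self.arch not in ("mlp", "cnn", "mcdcnn", "lstm"):
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.final_activation not in ("softmax", "sigmoid"):
            raise ValueError("final_activation must be softmax or sigmoid")
        if self.final_activation == "sigmoid" and self.n_classes != 2:
            raise ValueError("sigmoid head only applies to binary problems")
        if self.n_channels < 1 or self.window_len < 1:
            raise ValueError("invalid input dimensions")


def _head_units(spec: ClassifierSpec) -> int:
    return 1 if spec.final_activation == "sigmoid" else spec.n_classes


def build_mlp(spec: ClassifierSpec, seed: int = 0) -> Sequential:
    """Five fully connected layers: input, hidden 10/7/4 (ReLU), class head."""
    rng = np.random.default_rng(seed)
    n_in = spec.n_channels * spec.window_len
    return Sequential(
        [
            Flatten(),
            Dense(n_in, 10, rng),
            ReLU(),
            Dense(10, 7, rng),
            ReLU(),
            Dense(7, 4, rng),
            ReLU(),
            Dense(4, _head_units(spec), rng),
        ]
    )


def build_cnn(spec: ClassifierSpec, seed: int = 0) -> Sequential:
    """Three 1-D convolutions (10, 7, 4 filters, kernel 3), max pool, GAP, head."""
    rng = np.random.default_rng(seed)
    # length bookkeeping: two valid k=3 convs, pool 2, one more k=3 conv
    length = spec.window_len - 2 - 2
    length = length // 2
    if length - 2 < 1:
        raise ValueError("window too short for the stacked convolutions")
    return Sequential(
        [
            Conv1D(spec.n_channels, 10, 3, rng),
            ReLU(),
            Conv1D(10, 7, 3, rng),
            ReLU(),
            MaxPool1D(2),
            Conv1D(7, 4, 3, rng),
            ReLU(),
            GlobalAvgPool1D(),
            Dense(4, _head_units(spec), rng),
        ]
    )


def build_mcdcnn(spec: ClassifierSpec, seed: int = 0) -> MCDCNNNet:
    """Per-channel conv-conv-batchnorm-ReLU branches, dense 128, dropout 0.5.

    ``arch_params`` accepts ``filters``/``kernel`` limited to the presets
    (4, 3), (3, 2) and (2, 1) unless ``allow_any_preset=True``.
    """
    filters = spec.arch_params.get("filters", 4)
    kernel = spec.arch_params.get("kernel", 3)
    if (filters, kernel) not in MCDCNN_PRESETS and not spec.arch_params.get(
        "allow_any_preset", False
    ):
        raise ValueError(
            f"(filters={filters}, kernel={kernel}) is not one of the presets "
            f"{MCDCNN_PRESETS}; pass allow_any_preset=True to override"
        )
    out_len = spec.window_len - 2 * (kernel - 1)
    if out_len < 1:
        raise ValueError("window too short for the two convolutions")
    rng = np.random.default_rng(seed)
    branches = [
        Sequential(
            [
                Conv1D(1, filters, kernel, rng),
                Conv1D(filters, filters, kernel, rng),
                BatchNorm1D(filters),
                ReLU(),
                Flatten(),
            ]
        )
        for _ in range(spec.n_channels)
    ]
    concat = spec.n_channels * filters * out_len
    trunk = Sequential(
        [
            Dense(concat, 128, rng),
            ReLU(),
            Dropout(0.5, np.random.default_rng(rng.integers(2**31))),
            Dense(128, _head_units(spec), rng),
        ]
    )
    return MCDCNNNet(branches, trunk)


def build_lstm(spec: ClassifierSpec, seed: int = 0) -> Sequential:
    """Two recurrent layers (6 then 4 units) and a classification head."""
    rng = np.random.default_rng(seed)
    return Sequential(
        [
            LSTM(spec.n_channels, 6, rng, return_sequences=True),
            LSTM(6, 4, rng, return_sequences=False),
            Dense(4, _head_units(spec), rng),
        ]
    )


_BUILDERS = {
    "mlp": build_mlp,
    "cnn": build_cnn,
    "mcdcnn": build_mcdcnn,
    "lstm": build_lstm,
}


def build_model(spec: ClassifierSpec, seed: int = 0):
    return _BUILDERS[spec.arch](spec, seed)


# ---------------------------------------------------------------------------
# loss, optimizer, training

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grad(logits: np.ndarray, Y: np.ndarray, activation: str):
    """Cross-entropy loss, class probabilities and gradient wrt logits."""
    n = logits.shape[0]
    eps = 1e-12
    if activation == "softmax":
        probs = _softmax(logits.astype(np.float64))
        loss = -np.mean(np.sum(Y * np.log(probs + eps), axis=1))
        grad = ((probs - Y) / n).astype(DTYPE)
        return loss, probs, grad
    p = _sigmoid(logits[:, 0].astype(np.float64))
    y = Y[:, 1]
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    grad = ((p - y) / n)[:, None].astype(DTYPE)
    probs = np.stack([1 - p, p], axis=1)
    return loss, probs, grad


class RMSprop:
    """RMSprop parameter update (learning rate 0.001, rho 0.9 by default)."""

    def __init__(self, params: list, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self, grads: list) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * np.square(g, dtype=np.float64)
            p -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(p.dtype)


@dataclass
class TrainConfig:
    """Mini-batch training protocol: batch 128, 90 epochs, RMSprop, CE loss."""

    batch_size: int = 128
    epochs: int = 90
    learning_rate: float = 0.001
    rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


class ChannelScaler:
    """Per-channel z-scoring with statistics frozen from the training split."""

    def __init__(self):
        self.mean: Optional[np.ndarray] = None
        self.std: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "ChannelScaler":
        self.mean = X.mean(axis=(0, 2))
        std = X.std(axis=(0, 2))
        self.std = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("scaler not fitted")
        out = (X - self.mean[None, :, None]) / self.std[None, :, None]
        return out.astype(DTYPE)


@dataclass
class TrainedClassifier:
    """A trained model with its input scaler and per-epoch history."""

    spec: ClassifierSpec
    model: object
    scaler: ChannelScaler
    history: dict
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.model.forward(self.scaler.transform(X), train=False)
        if self.spec.final_activation == "sigmoid":
            p = _sigmoid(logits[:, 0].astype(np.float64))
            return np.stack([1 - p, p], axis=1)
        return _softmax(logits.astype(np.float64))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def save(self, path) -> None:
        spec = {
            "arch": self.spec.arch,
            "n_channels": self.spec.n_channels,
            "window_len": self.spec.window_len,
            "n_classes": self.spec.n_classes,
            "arch_params": self.spec.arch_params,
            "final_activation": self.spec.final_activation,
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.model.params())}
        np.savez(
            path,
            spec=json.dumps(spec),
            seed=self.seed,
            scaler_mean=self.scaler.mean,
            scaler_std=self.scaler.std,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with np.load(path, allow_pickle=False) as f:
            spec = ClassifierSpec(**json.loads(str(f["spec"])))
            seed = int(f["seed"])
            model = build_model(spec, seed)
            for i, p in enumerate(model.params()):
                p[...] = f[f"p{i}"]
            scaler = ChannelScaler()
            scaler.mean = f["scaler_mean"]
            scaler.std = f["scaler_std"]
        return cls(spec=spec, model=model, scaler=scaler, history={}, seed=seed)


def train_classifier(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: Optional[np.ndarray] = None,
    Y_val: Optional[np.ndarray] = None,
    cfg: Optional[TrainConfig] = None,
) -> TrainedClassifier:
    """Train a classifier with seeded mini-batch RMSprop.

    ``X_*`` are (N, M, T) channel windows, ``Y_*`` one-hot labels.  Records
    per-epoch training (and validation, if given) loss and accuracy.  A
    non-finite loss aborts with a diagnostic suggesting a smaller learning
    rate.
    """
    cfg = cfg or TrainConfig()
    if len(X_train) == 0:
        raise ValueError("empty training set")
    if X_train.shape[1] != spec.n_channels or X_train.shape[2] != spec.window_len:
        raise ValueError(
            f"training data shape {X_train.shape[1:]} does not match spec "
            f"({spec.n_channels}, {spec.window_len})"
        )
    scaler = ChannelScaler().fit(X_train)
    Xtr = scaler.transform(X_train)
    Ytr = Y_train.astype(np.float64)
    model = build_model(spec, cfg.seed)
    opt = RMSprop(model.params(), lr=cfg.learning_rate, rho=cfg.rho)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(Xtr)
    history: dict = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            logits = model.forward(xb, train=True)
            loss, probs, grad = _loss_and_grad(logits, yb, spec.final_activation)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "non-finite training loss; try a smaller learning rate"
                )
            model.backward(grad)
            opt.step(model.grads())
            ep_loss += loss * len(idx)
            ep_correct += int((probs.argmax(1) == yb.argmax(1)).sum())
        history["train_loss"].append(ep_loss / n)
        history["train_acc"].append(ep_correct / n)
        if X_val is not None and len(X_val):
            logits = model.forward(scaler.transform(X_val), train=False)
            vloss, vprobs, _ = _loss_and_grad(
                logits, Y_val.astype(np.float64), spec.final_activation
            )
            history["val_loss"].append(vloss)
            history["val_acc"].append(float((vprobs.argmax(1) == Y_val.argmax(1)).mean()))
    return TrainedClassifier(
        spec=spec, model=model, scaler=scaler, history=history, seed=cfg.seed
    )


def evaluate(
    clf: TrainedClassifier, X_test: np.ndarray, Y_test: np.ndarray
) -> tuple[float, np.ndarray]:
    """Accuracy and confusion counts (rows true, columns predicted)."""
    if len(X_test) == 0:
        raise ValueError("empty test set")
    if X_test.shape[1] != clf.spec.n_channels:
        raise ValueError("channel count mismatch between test data and classifier")
    pred = clf.predict(X_test)
    true = Y_test.argmax(axis=1)
    k = Y_test.shape[1]
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (true, pred), 1)
    acc = float(np.trace(conf) / conf.sum())
    return acc, conf
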