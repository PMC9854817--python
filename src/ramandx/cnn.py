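"""One-dimensional convolutional network for Raman spectral classification.

The architecture is fixed and small: two unpadded (valid) kernel-3
convolutions with 8 then 16 channels and tanh activations, one batch
normalization layer between the convolutional layers, a width-3 stride-3
max-pool, a flatten, and a dense softmax output over the diagnostic classes.
On a 1698-point spectrum the flatten therefore produces
(((1698-2)-2)//3) * 16 = 9024 features feeding the 3-node output layer.
Training minimises categorical cross-entropy with Adam (default batch 16,
100 epochs, learning rate 1e-3).

Forward and backward passes are implemented directly in numpy: the network
has ~30k parameters and spectra are short, so batched einsum contractions on
one CPU train it in seconds while keeping runs bit-reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "CNNSpec",
    "TrainingHistory",
    "CNNClassifier",
    "flattened_size",
    "build_cnn",
    "train_cnn",
]


@dataclass
class CNNSpec:
    """Architecture and training hyperparameters of the 1D CNN."""

    input_len: int = 1698
    conv_channels: tuple[int, ...] = (8, 16)
    kernel_len: int = 3
    pool_len: int = 3
    hidden_activation: str = "tanh"
    n_classes: int = 3
    batch_size: int = 16
    epochs: int = 100
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"

    def __post_init__(self) -> None:
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        if self.input_len < self.kernel_len:
            raise ConfigError("input shorter than the convolution kernel")
        if any(c < 1 for c in self.conv_channels) or not self.conv_channels:
            raise ConfigError(f"invalid conv_channels {self.conv_channels}")
        if self.kernel_len < 1 or self.pool_len < 1:
            raise ConfigError("kernel_len and pool_len must be >= 1")
        if self.n_classes < 2:
            raise ConfigError(f"need at least 2 classes, got {self.n_classes}")
        if self.hidden_activation != "tanh":
            raise ConfigError(f"unsupported activation {self.hidden_activation!r}")
        if self.optimizer.lower() != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ConfigError(f"unsupported loss {self.loss!r}")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ConfigError("learning_rate > 0, batch_size >= 1, epochs >= 0 required")
        flattened_size(self)  # raises if any intermediate length collapses


def flattened_size(spec: CNNSpec) -> int:
    """Feature count entering the dense layer, by shape arithmetic.

    Each valid convolution shortens the signal by kernel_len - 1; the single
    stride-``pool_len`` max-pool floors the remaining length; the final
    channel count multiplies it.
    """
    length = spec.input_len
    for _ in spec.conv_channels:
        length -= spec.kernel_len - 1
        if length <= 0:
            raise ConfigError("convolution stack collapses the signal to nothing")
    length //= spec.pool_len
    if length <= 0:
        raise ConfigError("pooling collapses the signal to nothing")
    return length * spec.conv_channels[-1]


@dataclass
class TrainingHistory:
    """Per-epoch metrics in the Keras History style."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


_DTYPE = np.float32  # training precision; halves memory traffic vs float64


class _Conv1D:
    """Valid (unpadded) 1-D convolution, stride 1.  x: (B, Cin, L) -> (B, Cout, L-K+1).

    Implemented as im2col + matmul so the inner products run through BLAS.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int) -> None:
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.W = _glorot_uniform(rng, (c_out, c_in, k), fan_in=c_in * k, fan_out=c_out * k).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # (B, Cin, Lout, K) -> (B, Lout, Cin*K) contiguous patch matrix
        windows = sliding_window_view(x, self.k, axis=2)
        b, _, lout, _ = windows.shape
        self._cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
            b, lout, self.c_in * self.k
        )
        self._in_len = x.shape[2]
        wmat = self.W.reshape(self.c_out, self.c_in * self.k)
        out = self._cols @ wmat.T + self.b
        return out.transpose(0, 2, 1)  # (B, Cout, Lout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, lout = dout.shape
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(b * lout, self.c_out)
        cols_flat = self._cols.reshape(b * lout, self.c_in * self.k)
        self.grads[0][...] = (dflat.T @ cols_flat).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(self.c_out, -1)).reshape(b, lout, self.c_in, self.k)
        dx = np.zeros((b, self.c_in, self._in_len), dtype=_DTYPE)
        for k in range(self.k):  # col2im scatter-add, K is tiny
            dx[:, :, k : k + lout] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dx


class _Tanh:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._out**2)


class _BatchNorm1D:
    """Per-channel normalization over (batch, position); Keras-style defaults."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        self.gamma = np.ones(channels, dtype=_DTYPE)
        self.beta = np.zeros(channels, dtype=_DTYPE)
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._n = x.shape[0] * x.shape[2]
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean[:, None]) * self._inv_std[:, None]
            return self.gamma[:, None] * self._xhat + self.beta[:, None]
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma[:, None] * (x - self.running_mean[:, None]) * inv[:, None] + self.beta[:, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = (dout * self._xhat).sum(axis=(0, 2))
        self.grads[1][...] = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[:, None]
        n = self._n
        term = dxhat - dxhat.mean(axis=(0, 2))[:, None] - self._xhat * (
            (dxhat * self._xhat).sum(axis=(0, 2)) / n
        )[:, None]
        return term * self._inv_std[:, None]


class _MaxPool1D:
    """Non-overlapping max-pool, stride == width, trailing remainder dropped."""

    params: list = []
    grads: list = []

    def __init__(self, width: int) -> None:
        self.width = width

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, c, length = x.shape
        lp = length // self.width
        blocks = x[:, :, : lp * self.width].reshape(b, c, lp, self.width)
        self._arg = blocks.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._arg[..., None], axis=3)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, lp = dout.shape
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dblocks = dx[:, :, : lp * self.width].reshape(b, c, lp, self.width)
        bi, ci, pi = np.ogrid[:b, :c, :lp]
        dblocks[bi, ci, pi, self._arg] = dout
        return dx


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int) -> None:
        self.W = _glorot_uniform(rng, (n_in, n_out), fan_in=n_in, fan_out=n_out).astype(_DTYPE)
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class CNNClassifier:
    """The assembled network; inputs are (N, L) preprocessed spectra."""

    def __init__(self, spec: CNNSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1D]))
        layers: list = []
        c_in = 1
        for i, c_out in enumerate(spec.conv_channels):
            layers.append(_Conv1D(rng, c_in, c_out, spec.kernel_len))
            layers.append(_Tanh())
            if i == 0 and len(spec.conv_channels) > 1:
                layers.append(_BatchNorm1D(c_out))
            c_in = c_out
        layers.append(_MaxPool1D(spec.pool_len))
        layers.append(_Flatten())
        n_flat = flattened_size(spec)
        layers.append(_Dense(rng, n_flat, spec.n_classes))
        self.layers = layers
        self.history = TrainingHistory()
        self.classes_: Optional[np.ndarray] = None

    # -- forward/backward ---------------------------------------------------

    def _forward_logits(self, x2d: np.ndarray, training: bool) -> np.ndarray:
        h = np.asarray(x2d, dtype=_DTYPE)[:, None, :]  # single input channel
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        out = [
            _softmax(self._forward_logits(x[i : i + batch_size], training=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def _train_batch(self, x: np.ndarray, y_onehot: np.ndarray, optimizer: _Adam) -> tuple[float, float]:
        probs = _softmax(self._forward_logits(x, training=True))
        eps = 1e-12
        loss = float(-(y_onehot * np.log(probs + eps)).sum() / x.shape[0])
        if not math.isfinite(loss):
            raise NumericalError("training diverged: non-finite cross-entropy loss")
        acc = float((probs.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
        dlogits = (probs - y_onehot) / x.shape[0]
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step(self.gradients())
        return loss, acc

    def evaluate(self, x: np.ndarray, y_codes: np.ndarray) -> tuple[float, float]:
        probs = self.predict_proba(x)
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(len(y_codes)), y_codes] + eps).mean())
        acc = float((probs.argmax(axis=1) == y_codes).mean())
        return loss, acc


def build_cnn(spec: CNNSpec | None = None, seed: int = 0) -> CNNClassifier:
    """Instantiate the network with seed-reproducible Glorot-uniform weights."""
    spec = spec or CNNSpec()
    model = CNNClassifier(spec, seed=seed)
    dense = model.layers[-1]
    assert dense.W.shape[0] == flattened_size(spec)
    return model


def _stratified_holdout(y: np.ndarray, frac: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = members[rng.permutation(members.size)]
        n_val = int(math.floor(frac * members.size))
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(val_idx, int))


def train_cnn(
    model: CNNClassifier,
    x: np.ndarray,
    y: np.ndarray,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> CNNClassifier:
    """Train with Adam on categorical cross-entropy, recording epoch curves.

    A stratified ``val_fraction`` of the data is held out for the validation
    curves (the model never trains on it).  Sample order is reshuffled every
    epoch from the run seed, so training is bit-reproducible.
    """
    x = np.ascontiguousarray(x, dtype=_DTYPE)
    y = np.asarray(y, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise DataError(f"incompatible shapes x{x.shape}, y{y.shape}")
    if np.unique(y).size < 2:
        raise DataError("training set must contain at least 2 classes")
    spec = model.spec
    if x.shape[1] != spec.input_len:
        raise DataError(f"spectra of length {x.shape[1]} but the network expects {spec.input_len}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E]))
    if val_fraction > 0:
        tr, va = _stratified_holdout(y, val_fraction, rng)
    else:
        tr, va = np.arange(x.shape[0]), np.array([], dtype=int)
    x_tr, y_tr, x_va, y_va = x[tr], y[tr], x[va], y[va]
    onehot = np.eye(spec.n_classes)[y_tr]

    optimizer = _Adam(model.parameters(), lr=spec.learning_rate)
    n = x_tr.shape[0]
    for _epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, spec.batch_size):
            sel = order[start : start + spec.batch_size]
            loss, acc = model._train_batch(x_tr[sel], onehot[sel], optimizer)
            losses.append(loss)
            accs.append(acc)
        model.history.train_loss.append(float(np.mean(losses)))
        model.history.train_accuracy.append(float(np.mean(accs)))
        if va.size:
            v_loss, v_acc = model.evaluate(x_va, y_va)
        else:
            v_loss, v_acc = float("nan"), float("nan")
        model.history.val_loss.append(v_loss)
        model.history.val_accuracy.append(v_acc)
    model.classes_ = np.arange(spec.n_classes)
    return model
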