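"""Small 1D convolutional network for six-class epoch classification.

Architecture (two convolutional modules with filters of decreasing
size, then flatten and a dense-softmax output):

    input (2 x w, per-channel standardized)
    -> conv1d(32 filters, kernel 7) -> ReLU -> maxpool(2)   [module A]
    -> conv1d(16 filters, kernel 5) -> ReLU -> maxpool(2)   [module B]
    -> flatten -> dense(6) -> softmax

Trained with mini-batch Adam on the cross-entropy loss. The network is
implemented directly on numpy (im2col-style convolutions via stride
tricks, explicit backward pass) and is exactly reproducible for a fixed
seed; the gradient computation is verified against finite differences
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CLASS_ORDER, EpochSet, ValidationError


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and optimization settings.

    Each module is ``(filter_count, kernel_length, pool_length)``;
    module B must not have more filters than module A (decreasing size).
    """

    module_a: tuple[int, int, int] = (32, 7, 2)
    module_b: tuple[int, int, int] = (16, 5, 2)
    dense_units: int = 6
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mod in (("module_a", self.module_a), ("module_b", self.module_b)):
            if len(mod) != 3 or any(int(v) < 1 for v in mod):
                raise ValidationError(f"{name} must be three positive ints, got {mod}")
        if self.module_b[0] > self.module_a[0]:
            raise ValidationError(
                f"module B filter count {self.module_b[0]} exceeds module A's "
                f"{self.module_a[0]}; modules must decrease in size"
            )
        if self.dense_units != len(CLASS_ORDER):
            raise ValidationError(
                f"output layer must have exactly {len(CLASS_ORDER)} units"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# layer primitives (batch, channels, length) layout


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid cross-correlation. x (B,C,L), W (F,C,K) -> (B,F,L-K+1)."""
    K = W.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)  # (B,C,Lo,K)
    out = np.einsum("bclk,fck->bfl", win, W, optimize=True) + b[None, :, None]
    return out, win


def _conv1d_backward(dout: np.ndarray, win: np.ndarray, W: np.ndarray):
    """Gradients of valid cross-correlation w.r.t. W, b and the input."""
    K = W.shape[2]
    dW = np.einsum("bfl,bclk->fck", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2))
    pad = np.pad(dout, ((0, 0), (0, 0), (K - 1, K - 1)))
    win2 = np.lib.stride_tricks.sliding_window_view(pad, K, axis=2)  # (B,F,L,K)
    dx = np.einsum("bflk,fck->bcl", win2, W[:, :, ::-1], optimize=True)
    return dW, db, dx


def _maxpool_forward(x: np.ndarray, p: int):
    """Non-overlapping max pooling along the last axis (tail truncated)."""
    B, F, L = x.shape
    Lp = L // p
    xr = x[:, :, : Lp * p].reshape(B, F, Lp, p)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return out, (arg, L)


def _maxpool_backward(dout: np.ndarray, cache, p: int) -> np.ndarray:
    arg, L = cache
    B, F, Lp = dout.shape
    dxr = np.zeros((B, F, Lp, p))
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
    dx = np.zeros((B, F, L))
    dx[:, :, : Lp * p] = dxr.reshape(B, F, Lp * p)
    return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Net:
    """Parameter container + forward/backward for the two-module CNN."""

    def __init__(self, config: CNNConfig, input_len: int, rng: np.random.Generator):
        f1, k1, p1 = config.module_a
        f2, k2, p2 = config.module_b
        l1 = input_len - k1 + 1
        if l1 < 1:
            raise ValidationError(
                f"epoch length {input_len} too short for kernel {k1}"
            )
        l1p = l1 // p1
        l2 = l1p - k2 + 1
        if l2 < 1:
            raise ValidationError(
                f"epoch length {input_len} too short for the two-module "
                f"architecture (module B sees {l1p} samples, kernel {k2})"
            )
        l2p = l2 // p2
        if l2p < 1:
            raise ValidationError(f"epoch length {input_len} pools away to nothing")
        self.config = config
        self.input_len = input_len
        self.flat_len = f2 * l2p
        # He initialization for the ReLU conv stack; small dense head.
        self.params = {
            "W1": rng.normal(0, np.sqrt(2.0 / (2 * k1)), size=(f1, 2, k1)),
            "b1": np.zeros(f1),
            "W2": rng.normal(0, np.sqrt(2.0 / (f1 * k2)), size=(f2, f1, k2)),
            "b2": np.zeros(f2),
            "W3": rng.normal(0, np.sqrt(1.0 / self.flat_len),
                             size=(config.dense_units, self.flat_len)),
            "b3": np.zeros(config.dense_units),
        }

    def forward(self, x: np.ndarray):
        p = self.params
        _, _, p1 = self.config.module_a
        _, _, p2 = self.config.module_b
        c1, win1 = _conv1d_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(c1, 0.0)
        m1, cache1 = _maxpool_forward(a1, p1)
        c2, win2 = _conv1d_forward(m1, p["W2"], p["b2"])
        a2 = np.maximum(c2, 0.0)
        m2, cache2 = _maxpool_forward(a2, p2)
        flat = m2.reshape(len(x), -1)
        logits = flat @ p["W3"].T + p["b3"]
        cache = (win1, c1, cache1, m1, win2, c2, cache2, m2, flat)
        return logits, cache

    def loss_and_grads(self, x: np.ndarray, y_idx: np.ndarray):
        p = self.params
        _, _, p1 = self.config.module_a
        _, _, p2 = self.config.module_b
        logits, (win1, c1, cache1, m1, win2, c2, cache2, m2, flat) = self.forward(x)
        probs = _softmax(logits)
        n = len(x)
        loss = float(-np.log(probs[np.arange(n), y_idx] + 1e-12).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        grads = {
            "W3": dlogits.T @ flat,
            "b3": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["W3"]
        dm2 = dflat.reshape(m2.shape)
        da2 = _maxpool_backward(dm2, cache2, p2)
        dc2 = da2 * (c2 > 0)
        grads["W2"], grads["b2"], dm1 = _conv1d_backward(dc2, win2, p["W2"])
        da1 = _maxpool_backward(dm1, cache1, p1)
        dc1 = da1 * (c1 > 0)
        grads["W1"], grads["b1"], _ = _conv1d_backward(dc1, win1, p["W1"])
        return loss, grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class CNNClassifier:
    """The two-module 1D CNN with the common fit/predict contract.

    Standardizes each channel with training-set statistics, trains with
    Adam on cross-entropy, and predicts the argmax class. ``loss_history``
    holds the mean training loss per epoch after ``fit``.
    """

    config: CNNConfig = field(default_factory=CNNConfig)
    _net: _Net | None = field(default=None, repr=False)
    _mean: np.ndarray | None = field(default=None, repr=False)
    _std: np.ndarray | None = field(default=None, repr=False)
    loss_history: list[float] = field(default_factory=list, repr=False)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        assert self._mean is not None and self._std is not None
        return (X - self._mean) / self._std

    def fit(self, X: np.ndarray | EpochSet, y: np.ndarray | None = None) -> "CNNClassifier":
        if isinstance(X, EpochSet):
            y = X.y
            X = X.X
        X = np.asarray(X, dtype=float)
        if y is None:
            raise ValidationError("labels required to fit")
        y = np.asarray(y, dtype=object)
        if len(set(y)) < 2:
            raise ValidationError("training set must contain at least 2 classes")
        if X.ndim != 3 or X.shape[1] != 2:
            raise ValidationError(f"X must have shape (n, 2, w); got {X.shape}")
        # per-channel standardization from the training set only
        self._mean = X.mean(axis=(0, 2), keepdims=True)
        self._std = X.std(axis=(0, 2), keepdims=True)
        self._std[self._std == 0] = 1.0
        Xs = self._standardize(X)
        y_idx = np.array([CLASS_ORDER.index(lab) for lab in y])
        rng = np.random.default_rng(self.config.seed)
        self._net = _Net(self.config, X.shape[2], rng)
        opt = _Adam(self._net.params, self.config.learning_rate)
        n = len(Xs)
        bs = min(self.config.batch_size, n)
        self.loss_history = []
        for _ in range(self.config.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                loss, grads = self._net.loss_and_grads(Xs[idx], y_idx[idx])
                opt.step(self._net.params, grads)
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
        return self

    def _check_shape(self, X: np.ndarray) -> np.ndarray:
        if self._net is None:
            raise ValidationError("CNNClassifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != self._net.input_len:
            raise ValidationError(
                f"expected epochs of shape (n, 2, {self._net.input_len}); "
                f"got {X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray | EpochSet) -> np.ndarray:
        arr = X.X if isinstance(X, EpochSet) else X
        arr = self._check_shape(arr)
        assert self._net is not None
        logits, _ = self._net.forward(self._standardize(arr))
        return _softmax(logits)

    def predict(self, X: np.ndarray | EpochSet) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([CLASS_ORDER[i] for i in probs.argmax(axis=1)], dtype=object)
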