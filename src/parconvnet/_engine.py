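"""Minimal numpy CNN engine (NHWC, float32).

Internal layer library used by :mod:`parconvnet.model_runtime`.  Each layer
object owns its parameters, gradients and SGD-momentum buffers and exposes
``forward(x, train)`` / ``backward(dy)``.  Convolutions use TensorFlow-style
"same" padding (``out = ceil(in / stride)``, asymmetric pad when the total is
odd) via im2col feeding a single BLAS GEMM, with a k*k-loop fallback when the
columns buffer would be too large (inference on very big inputs).

Performance note: on one CPU the network is memory-bandwidth bound, so every
layer keeps persistent scratch buffers (columns, activations, gradients) that
are reused across steps instead of reallocated.  Consequence: the array a
layer returns is overwritten by its next forward call — consumers that need
an activation to survive (feature taps) must copy it.

Determinism: all initialization and dropout randomness flows from explicit
``numpy.random.Generator`` objects; identical seeds give bitwise-identical
weights and updates.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32

_IM2COL_BYTE_CAP = 400 * 1024 * 1024  # above this, use the k*k loop path


class Layer:
    trainable = True

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def _buf(self, key: str, shape: tuple, dtype=F32) -> np.ndarray:
        """Persistent scratch array, reallocated only when the shape changes."""
        store = self.__dict__.setdefault("_bufs", {})
        arr = store.get(key)
        if arr is None or arr.shape != shape or arr.dtype != dtype:
            arr = np.empty(shape, dtype)
            store[key] = arr
        return arr

    def release(self) -> None:
        """Drop scratch buffers and caches (keeps weights and velocities).

        Scratch can reach gigabytes for training-sized batches; callers
        release it once a training run or batched prediction finishes.
        """
        self.__dict__.pop("_bufs", None)
        for attr in ("_cache", "_mask", "_x"):
            if hasattr(self, attr):
                setattr(self, attr, None)

    def _step_params(self, lr: float, momentum: float, pairs) -> None:
        if not self.trainable:
            return
        if not hasattr(self, "_vel"):
            self._vel = {k: np.zeros_like(p) for k, p, _ in pairs}
        for k, p, g in pairs:
            v = self._vel[k]
            v *= F32(momentum)
            v -= F32(lr) * g
            p += v

    def sgd_step(self, lr: float, momentum: float) -> None:
        pass


def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    """Return (out_size, pad_begin, pad_end) for SAME padding."""
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


class Conv2D(Layer):
    """2-D convolution, SAME padding, square kernel, NHWC."""

    def __init__(self, name: str, k: int, stride: int, cin: int, cout: int,
                 rng: np.random.Generator):
        self.name = name
        self.k, self.s, self.cin, self.cout = k, stride, cin, cout
        fan_in = k * k * cin
        # He-normal init for ReLU networks
        self.W = (rng.standard_normal((k, k, cin, cout)) *
                  np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"dW": self.dW, "db": self.db}

    def sgd_step(self, lr, momentum):
        self._step_params(lr, momentum,
                          [("W", self.W, self.dW), ("b", self.b, self.db)])

    def _pad_input(self, x, pt, pb, pl, pr):
        if pt == pb == pl == pr == 0:
            return x
        n, h, w, c = x.shape
        xp = self._buf("xp", (n, h + pt + pb, w + pl + pr, c))
        xp.fill(0)
        xp[:, pt:pt + h, pl:pl + w, :] = x
        return xp

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        k, s, cin, cout = self.k, self.s, self.cin, self.cout
        oh, pt, pb = _same_pad(h, k, s)
        ow, pl, pr = _same_pad(w, k, s)
        xp = self._pad_input(x, pt, pb, pl, pr)
        cols_bytes = n * oh * ow * k * k * cin * 4

        if cols_bytes <= _IM2COL_BYTE_CAP:
            if k == 1 and s == 1:
                cols = xp.reshape(-1, cin)  # 1x1 stride-1 conv is a plain matmul
            else:
                cols = self._buf("cols", (n * oh * ow, k * k * cin))
                view = cols.reshape(n, oh, ow, k, k, cin)
                for ki in range(k):
                    for kj in range(k):
                        view[:, :, :, ki, kj, :] = \
                            xp[:, ki:ki + s * oh:s, kj:kj + s * ow:s, :]
            y = self._buf("y", (n, oh, ow, cout))
            yf = y.reshape(-1, cout)
            np.matmul(cols, self.W.reshape(k * k * cin, cout), out=yf)
            yf += self.b
            if train:
                self._cache = ("gemm", cols, x.shape, (oh, ow), (pt, pl))
            return y

        # loop path: no columns buffer (large inference inputs)
        y = self._buf("y", (n, oh, ow, cout))
        y[:] = self.b
        flat = y.reshape(-1, cout)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, ki:ki + s * oh:s, kj:kj + s * ow:s, :]
                flat += patch.reshape(-1, cin) @ self.W[ki, kj].reshape(cin, cout)
        if train:
            self._cache = ("loop", xp, x.shape, (oh, ow), (pt, pl))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mode, stored, xshape, (oh, ow), (pt, pl) = self._cache
        n, h, w, cin = xshape
        k, s, cout = self.k, self.s, self.cout
        dyf = dy.reshape(-1, cout)
        self.db[:] = dyf.sum(axis=0)
        pad_h = max((oh - 1) * s + k - h, 0)
        pad_w = max((ow - 1) * s + k - w, 0)

        if mode == "gemm":
            cols = stored
            np.matmul(cols.T, dyf, out=self.dW.reshape(k * k * cin, cout))
            if k == 1 and s == 1:
                dxp = self._buf("dxp", (n, h, w, cin))
                np.matmul(dyf, self.W.reshape(cin, cout).T,
                          out=dxp.reshape(-1, cin))
            else:
                dcols = self._buf("dcols", (n * oh * ow, k * k * cin))
                np.matmul(dyf, self.W.reshape(k * k * cin, cout).T, out=dcols)
                dview = dcols.reshape(n, oh, ow, k, k, cin)
                dxp = self._buf("dxp", (n, h + pad_h, w + pad_w, cin))
                dxp.fill(0)
                for ki in range(k):
                    for kj in range(k):
                        dxp[:, ki:ki + s * oh:s, kj:kj + s * ow:s, :] += \
                            dview[:, :, :, ki, kj, :]
            self._cache = None
            return dxp[:, pt:pt + h, pl:pl + w, :]

        xp = stored
        dxp = self._buf("dxp", xp.shape)
        dxp.fill(0)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, ki:ki + s * oh:s, kj:kj + s * ow:s, :]
                self.dW[ki, kj] = (patch.reshape(-1, cin).T @ dyf)
                dxp[:, ki:ki + s * oh:s, kj:kj + s * ow:s, :] += (
                    dyf @ self.W[ki, kj].reshape(cin, cout).T
                ).reshape(n, oh, ow, cin)
        self._cache = None
        return dxp[:, pt:pt + h, pl:pl + w, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Training uses batch statistics and updates running statistics with
    momentum 0.9 (``running = 0.9*running + 0.1*batch``); inference uses the
    running statistics.
    """

    def __init__(self, name: str, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.name = name
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def sgd_step(self, lr, momentum):
        self._step_params(lr, momentum,
                          [("gamma", self.gamma, self.dgamma),
                           ("beta", self.beta, self.dbeta)])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = F32(self.momentum)
            self.running_mean *= m
            self.running_mean += (1 - m) * mean
            self.running_var *= m
            self.running_var += (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = self._buf("xhat", x.shape)
        np.subtract(x, mean, out=xhat)
        xhat *= inv
        y = self._buf("y", x.shape)
        np.multiply(xhat, self.gamma, out=y)
        y += self.beta
        if train:
            self._cache = (xhat, inv, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        axes = tuple(range(dy.ndim - 1))
        m = int(np.prod([shape[a] for a in axes]))
        self.dgamma[:] = (dy * xhat).sum(axis=axes)
        self.dbeta[:] = dy.sum(axis=axes)
        # dx = (gamma*inv/m) * (m*dy - dbeta - xhat*dgamma); xhat is consumed
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, F32(m), out=dx)
        dx -= self.dbeta
        xhat *= self.dgamma
        dx -= xhat
        dx *= self.gamma * inv * F32(1.0 / m)
        self._cache = None
        return dx


class ReLU(Layer):
    trainable = False

    def __init__(self, name: str = "relu"):
        self.name = name

    def forward(self, x, train=False):
        y = self._buf("y", x.shape)
        np.maximum(x, 0, out=y)
        if train:
            mask = self._buf("mask", x.shape, dtype=bool)
            np.greater(x, 0, out=mask)
            self._mask = mask
        return y

    def backward(self, dy):
        dx = self._buf("dx", dy.shape)
        np.multiply(dy, self._mask, out=dx)
        self._mask = None
        return dx


class GlobalAvgPool(Layer):
    trainable = False

    def __init__(self, name: str = "G1"):
        self.name = name

    def forward(self, x, train=False):
        self._hw = x.shape[1:3]
        return x.mean(axis=(1, 2), dtype=F32)

    def backward(self, dy):
        h, w = self._hw
        dx = self._buf("dx", (dy.shape[0], h, w, dy.shape[1]))
        dx[:] = dy[:, None, None, :]
        dx *= F32(1.0 / (h * w))
        return dx


class Dense(Layer):
    def __init__(self, name: str, din: int, dout: int, rng: np.random.Generator):
        self.name = name
        self.W = (rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)).astype(F32)
        self.b = np.zeros(dout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"dW": self.dW, "db": self.db}

    def sgd_step(self, lr, momentum):
        self._step_params(lr, momentum,
                          [("W", self.W, self.dW), ("b", self.b, self.db)])

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    trainable = False

    def __init__(self, name: str, p: float, rng: np.random.Generator):
        self.name = name
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = F32(1.0 - self.p)
        mask = (self.rng.random(x.shape, dtype=np.float32) >= self.p)
        self._mask = mask
        return x * mask / keep

    def backward(self, dy):
        if self._mask is None:
            return dy
        out = dy * self._mask / F32(1.0 - self.p)
        self._mask = None
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and the logit gradient (probs - onehot)/n."""
    n = probs.shape[0]
    eps = 1e-12
    loss = float(-(onehot * np.log(probs + eps)).sum() / n)
    return loss, ((probs - onehot) / n).astype(F32)
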