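"""Minimal CPU neural-network engine (numpy, float32).

Implements exactly the layers the fingerprinting classifier needs: stride-1
same-padded 2-D convolution (im2col), ReLU, 2x2 max-pooling, inverted
dropout, dense, and a softmax/cross-entropy head, with RMSprop / Adam / SGD
optimizers.  Deterministic given the seed: no threading-dependent reductions
beyond BLAS matmul.

Data layout is channels-last: (batch, height, width, channels).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

DTYPE = np.float32


class Layer:
    params: list[str] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_grads(self):
        for name in self.params:
            yield getattr(self, name), getattr(self, "d_" + name)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Patches of a same-padded input: (N*H*W, kh*kw*C)."""
    n, h, w, c = x.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (N, H, W, C, kh, kw) -> (N, H, W, kh, kw, C)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, kh * kw * c)
    return np.ascontiguousarray(cols)


class Conv2D(Layer):
    """Same-padded stride-1 convolution with odd kernels.

    The input gradient is computed as a convolution of the output gradient
    with the spatially flipped, channel-transposed kernel — no scatter-add.
    """

    params = ["W", "b"]

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigurationError(f"kernel {kernel} must have odd sides")
        self.kh, self.kw = kh, kw
        self.in_ch, self.out_ch = in_ch, out_ch
        scale = np.sqrt(2.0 / (kh * kw * in_ch))  # He init for ReLU nets
        self.W = (rng.standard_normal((kh * kw * in_ch, out_ch)) * scale).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)

    def forward(self, x, training):
        if x.shape[1] < self.kh or x.shape[2] < self.kw:
            raise ConfigurationError(
                f"kernel ({self.kh},{self.kw}) larger than input plane "
                f"{x.shape[1:3]}"
            )
        self._shape = x.shape
        self._cols = _im2col(x, self.kh, self.kw)
        n, h, w, _ = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, grad):
        n, h, w, _ = self._shape
        gflat = grad.reshape(n * h * w, self.out_ch)
        self.d_W = self._cols.T @ gflat
        self.d_b = gflat.sum(axis=0)
        # flip kernel spatially, swap in/out channels
        wk = self.W.reshape(self.kh, self.kw, self.in_ch, self.out_ch)
        wback = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
            self.kh * self.kw * self.out_ch, self.in_ch
        )
        cols = _im2col(grad, self.kh, self.kw)
        dx = (cols @ wback).reshape(n, h, w, self.in_ch)
        self._cols = None
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class MaxPool2D(Layer):
    """2x2 (or (ph, pw)) max pooling with floor semantics: trailing rows or
    columns that do not fill a window are dropped."""

    def __init__(self, pool: tuple[int, int] = (2, 2)):
        self.ph, self.pw = pool

    def forward(self, x, training):
        n, h, w, c = x.shape
        ho, wo = h // self.ph, w // self.pw
        self._in_shape = x.shape
        xc = x[:, : ho * self.ph, : wo * self.pw, :]
        blocks = xc.reshape(n, ho, self.ph, wo, self.pw, c)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, -1)
        self._argmax = blocks.argmax(axis=-1)
        return blocks.max(axis=-1)

    def backward(self, grad):
        n, h, w, c = self._in_shape
        ho, wo = h // self.ph, w // self.pw
        k = self.ph * self.pw
        onehot = np.zeros((n, ho, wo, c, k), dtype=grad.dtype)
        np.put_along_axis(onehot, self._argmax[..., None], grad[..., None], axis=-1)
        blocks = onehot.reshape(n, ho, wo, c, self.ph, self.pw)
        blocks = blocks.transpose(0, 1, 4, 2, 5, 3).reshape(
            n, ho * self.ph, wo * self.pw, c
        )
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : ho * self.ph, : wo * self.pw, :] = blocks
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError(f"dropout rate {rate} not in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    params = ["W", "b"]

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.d_W = self._x.T @ grad
        self.d_b = grad.sum(axis=0)
        dx = grad @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(DTYPE).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class RMSprop:
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache: dict[int, np.ndarray] = {}

    def update(self, param, grad):
        key = id(param)
        c = self.cache.get(key)
        if c is None:
            c = np.zeros_like(param)
            self.cache[key] = c
        c *= self.rho
        c += (1.0 - self.rho) * grad * grad
        param -= self.lr * grad / (np.sqrt(c) + self.eps)


class Adam:
    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.state: dict[int, list] = {}

    def update(self, param, grad):
        st = self.state.setdefault(
            id(param), [np.zeros_like(param), np.zeros_like(param), 0]
        )
        m, v, t = st
        t += 1
        st[2] = t
        m *= self.b1
        m += (1 - self.b1) * grad
        v *= self.b2
        v += (1 - self.b2) * grad * grad
        mh = m / (1 - self.b1 ** t)
        vh = v / (1 - self.b2 ** t)
        param -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def update(self, param, grad):
        param -= self.lr * grad


OPTIMIZERS = {"rmsprop": RMSprop, "adam": Adam, "sgd": SGD}


def make_optimizer(name: str, lr: float):
    try:
        return OPTIMIZERS[name.lower()](lr)
    except KeyError:
        raise ConfigurationError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}"
        ) from None


class Sequential:
    """Plain layer stack with a manual training loop."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False,
                upto: int | None = None) -> np.ndarray:
        out = x
        for layer in self.layers[:upto]:
            out = layer.forward(out, training)
        return out

    def forward_from(self, x: np.ndarray, start: int) -> np.ndarray:
        out = x
        for layer in self.layers[start:]:
            out = layer.forward(out, training=False)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def train_step(self, x, y, optimizer):
        logits = self.forward(x, training=True)
        loss, grad = softmax_xent_grad(logits, y)
        self.backward(grad)
        for layer in self.layers:
            for param, g in layer.param_grads():
                optimizer.update(param, g)
        return loss, logits

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(layer, p) for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params:
                current = getattr(layer, p)
                if weights[i].shape != current.shape:
                    raise ConfigurationError(
                        f"weight {i} shape {weights[i].shape} != {current.shape}"
                    )
                setattr(layer, p, weights[i].astype(DTYPE))
                i += 1
        if i != len(weights):
            raise ConfigurationError("weight count mismatch")
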