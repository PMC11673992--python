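"""Minimal NumPy neural-network engine for the autoencoder ensemble.

Implements exactly the pieces the architecture needs: stride-1 'same'
2-D convolution (im2col), 2x2 max-pooling with ceiling division, 2x2
nearest-neighbour up-sampling with crop-to-target, dense layers, the
ReLU / Leaky-ReLU / tanh / sigmoid activations, Adam, mean-squared
reconstruction loss and softmax cross-entropy.  Tensors are NHWC float32;
everything is deterministic given a seed (single-threaded BLAS assumed).

'same' padding follows the usual deep-learning convention for even
kernels: the extra pad sample goes at the end (pad_before = (k-1)//2,
pad_after = k//2).
"""

from __future__ import annotations

import numpy as np
from numba import njit

DTYPE = np.float32


@njit(fastmath=True, cache=True)
def _conv2d_fwd_co(xp, Wk, b, out):
    """out[n,y,x,co] = b[co] + sum_{i,j,ci} xp[n,y+i,x+j,ci] W[i,j,ci,co].

    Inner loop over the output channel (contiguous in W and out); best
    when c_out >= c_in.
    """
    n, h, w, cout = out.shape
    kh, kw, cin, _ = Wk.shape
    acc = np.empty(cout, dtype=DTYPE)
    for s in range(n):
        for y in range(h):
            for x in range(w):
                for co in range(cout):
                    acc[co] = b[co]
                for i in range(kh):
                    for j in range(kw):
                        for ci in range(cin):
                            v = xp[s, y + i, x + j, ci]
                            for co in range(cout):
                                acc[co] += v * Wk[i, j, ci, co]
                for co in range(cout):
                    out[s, y, x, co] = acc[co]


@njit(fastmath=True, cache=True)
def _conv2d_fwd_ci(xp, Wkt, b, out):
    """Same contraction with weights stored (kh,kw,cout,cin): the inner
    dot runs over the input channel (contiguous in xp); best when
    c_in > c_out."""
    n, h, w, cout = out.shape
    kh, kw, _, cin = Wkt.shape
    for s in range(n):
        for y in range(h):
            for x in range(w):
                for co in range(cout):
                    acc = b[co]
                    for i in range(kh):
                        for j in range(kw):
                            for ci in range(cin):
                                acc += xp[s, y + i, x + j, ci] * \
                                    Wkt[i, j, co, ci]
                    out[s, y, x, co] = acc


@njit(fastmath=True, cache=True)
def _conv2d_bwd_co(xp, Wk, dz, dxp, dW, db):
    """Gradients of the convolution, output-channel-inner layout."""
    n, h, w, cout = dz.shape
    kh, kw, cin, _ = Wk.shape
    for s in range(n):
        for y in range(h):
            for x in range(w):
                for co in range(cout):
                    db[co] += dz[s, y, x, co]
                for i in range(kh):
                    for j in range(kw):
                        for ci in range(cin):
                            v = xp[s, y + i, x + j, ci]
                            acc = DTYPE(0.0)
                            for co in range(cout):
                                g = dz[s, y, x, co]
                                dW[i, j, ci, co] += v * g
                                acc += g * Wk[i, j, ci, co]
                            dxp[s, y + i, x + j, ci] += acc


@njit(fastmath=True, cache=True)
def _conv2d_bwd_ci(xp, Wkt, dz, dxp, dWt, db):
    """Gradients with weights stored (kh,kw,cout,cin): inner loops run
    over the input channel, contiguous in xp/dxp."""
    n, h, w, cout = dz.shape
    kh, kw, _, cin = Wkt.shape
    for s in range(n):
        for y in range(h):
            for x in range(w):
                for co in range(cout):
                    g = dz[s, y, x, co]
                    db[co] += g
                    for i in range(kh):
                        for j in range(kw):
                            for ci in range(cin):
                                dWt[i, j, co, ci] += \
                                    xp[s, y + i, x + j, ci] * g
                                dxp[s, y + i, x + j, ci] += \
                                    g * Wkt[i, j, co, ci]


# ---------------------------------------------------------------------------
# Activations

def apply_activation(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0)
    if kind == "leaky_relu":
        return np.where(x > 0, x, DTYPE(0.01) * x)
    if kind == "tanh":
        return np.tanh(x)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if kind == "linear":
        return x
    raise ValueError(f"unknown activation {kind!r}")


def activation_grad(y: np.ndarray, x: np.ndarray, kind: str) -> np.ndarray:
    """d(activation)/dx expressed from input x and output y."""
    if kind == "relu":
        return (x > 0).astype(y.dtype)
    if kind == "leaky_relu":
        return np.where(x > 0, 1.0, 0.01).astype(y.dtype)
    if kind == "tanh":
        return 1.0 - y * y
    if kind == "sigmoid":
        return y * (1.0 - y)
    if kind == "linear":
        return np.ones_like(y)
    raise ValueError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# padding helper

def _same_pads(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


# ---------------------------------------------------------------------------
# Layers

class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_shape(self, in_shape: tuple) -> tuple:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution with activation.

    A stride-1 transpose convolution with 'same' padding is algebraically a
    plain convolution, so this layer also serves as the decoder's
    transpose-convolution blocks (up-sampling is a separate layer).
    """

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int,
                 activation: str, rng: np.random.Generator):
        super().__init__()
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        self.activation = activation
        fan_in = kh * kw * c_in
        # He initialisation (suits the rectified activations)
        w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params = {"W": w.astype(DTYPE),
                       "b": np.zeros(c_out, dtype=DTYPE)}
        self.grads = {}

    def _pad(self, x):
        pt, pb = _same_pads(self.kh)
        pl, pr = _same_pads(self.kw)
        return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))

    @property
    def _ci_inner(self) -> bool:
        return self.c_in > self.c_out

    def forward(self, x, train=True):
        n, h, w, _ = x.shape
        self._x_shape = x.shape
        xp = np.ascontiguousarray(self._pad(x), dtype=DTYPE)
        Wk = self.params["W"].reshape(self.kh, self.kw, self.c_in,
                                      self.c_out)
        z = np.empty((n, h, w, self.c_out), dtype=DTYPE)
        if self._ci_inner:
            Wkt = np.ascontiguousarray(Wk.transpose(0, 1, 3, 2))
            _conv2d_fwd_ci(xp, Wkt, self.params["b"], z)
        else:
            _conv2d_fwd_co(xp, np.ascontiguousarray(Wk),
                           self.params["b"], z)
        self._z = z
        if train:
            self._xp = xp
        self._y = apply_activation(self._z, self.activation)
        return self._y

    def backward(self, dy):
        dz = np.ascontiguousarray(
            dy * activation_grad(self._y, self._z, self.activation),
            dtype=DTYPE)
        n, h, w, _ = self._x_shape
        Wk = self.params["W"].reshape(self.kh, self.kw, self.c_in,
                                      self.c_out)
        db = np.zeros(self.c_out, dtype=DTYPE)
        dxp = np.zeros_like(self._xp)
        if self._ci_inner:
            Wkt = np.ascontiguousarray(Wk.transpose(0, 1, 3, 2))
            dWt = np.zeros_like(Wkt)
            _conv2d_bwd_ci(self._xp, Wkt, dz, dxp, dWt, db)
            dWk = dWt.transpose(0, 1, 3, 2)
        else:
            dWk = np.zeros_like(np.ascontiguousarray(Wk))
            _conv2d_bwd_co(self._xp, np.ascontiguousarray(Wk), dz, dxp,
                           dWk, db)
        self.grads["W"] = np.ascontiguousarray(dWk).reshape(
            self.params["W"].shape)
        self.grads["b"] = db
        del self._xp
        pt, _ = _same_pads(self.kh)
        pl, _ = _same_pads(self.kw)
        return dxp[:, pt:pt + h, pl:pl + w, :]

    def out_shape(self, in_shape):
        h, w, _ = in_shape
        return (h, w, self.c_out)


class MaxPool2D(Layer):
    """2x2, stride-2 max pooling with ceiling division ('same')."""

    def __init__(self):
        super().__init__()

    def forward(self, x, train=True):
        n, h, w, c = x.shape
        self._in_shape = x.shape
        h2, w2 = -(-h // 2), -(-w // 2)
        xp = np.full((n, h2 * 2, w2 * 2, c), -np.inf, dtype=x.dtype)
        xp[:, :h, :w, :] = x
        blocks = xp.reshape(n, h2, 2, w2, 2, c)
        flat = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]
        return y

    def backward(self, dy):
        n, h, w, c = self._in_shape
        h2, w2 = -(-h // 2), -(-w // 2)
        dflat = np.zeros((n, h2, w2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None],
                          axis=-1)
        dxp = dflat.reshape(n, h2, w2, c, 2, 2).transpose(
            0, 1, 4, 2, 5, 3).reshape(n, h2 * 2, w2 * 2, c)
        return dxp[:, :h, :w, :]

    def out_shape(self, in_shape):
        h, w, c = in_shape
        return (-(-h // 2), -(-w // 2), c)


class Upsample2D(Layer):
    """2x nearest-neighbour up-sampling, cropped to a target H x W."""

    def __init__(self, target_hw: tuple[int, int]):
        super().__init__()
        self.target_hw = target_hw

    def forward(self, x, train=True):
        self._in_shape = x.shape
        y = x.repeat(2, axis=1).repeat(2, axis=2)
        th, tw = self.target_hw
        return y[:, :th, :tw, :]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        th, tw = self.target_hw
        full = np.zeros((n, 2 * h, 2 * w, c), dtype=dy.dtype)
        full[:, :th, :tw, :] = dy
        return full.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))

    def out_shape(self, in_shape):
        return (*self.target_hw, in_shape[2])


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str,
                 rng: np.random.Generator):
        super().__init__()
        self.activation = activation
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params = {"W": w.astype(DTYPE),
                       "b": np.zeros(n_out, dtype=DTYPE)}
        self.grads = {}

    def forward(self, x, train=True):
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._y = apply_activation(self._z, self.activation)
        return self._y

    def backward(self, dy):
        dz = dy * activation_grad(self._y, self._z, self.activation)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T

    def out_shape(self, in_shape):
        return (self.params["W"].shape[1],)


# ---------------------------------------------------------------------------
# Optimiser / losses / network container

class Adam:
    """Adam with optional L2 weight decay (coupled, added to the
    gradient; biases excluded)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k].astype(p.dtype)
                if self.weight_decay and k == "W":
                    g = g + DTYPE(self.weight_decay) * p
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)


def mse_loss(y_pred: np.ndarray, y_true: np.ndarray
             ) -> tuple[float, np.ndarray]:
    diff = y_pred - y_true
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(y_pred.dtype)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, onehot: np.ndarray
                 ) -> tuple[float, np.ndarray]:
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.sum(onehot * np.log(p + 1e-12)) / n)
    grad = ((p - onehot) / n).astype(logits.dtype)
    return loss, grad


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def forward_until(self, x: np.ndarray, n_layers: int) -> np.ndarray:
        for l in self.layers[:n_layers]:
            x = l.forward(x, train=False)
        return x

    def param_vector(self) -> np.ndarray:
        parts = [p.ravel() for l in self.layers for p in l.params.values()]
        return np.concatenate(parts) if parts else np.zeros(0)
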