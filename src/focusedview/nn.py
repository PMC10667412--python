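"""Minimal numpy layer stack for small 3-D segmentation networks.

Implements exactly the pieces the U-Net variants need — 3-D convolution
(im2col + GEMM), instance normalization, ReLU, 2x2x2 max pooling, nearest
upsampling, channel concatenation, softmax, and DANet-style position /
channel attention — each as a layer object with ``forward`` and a manual
``backward``.  Arrays are channels-first, batched: ``(N, C, X, Y, Z)``.

Every layer's gradient is validated against central finite differences in
the test suite; the stack is deliberately small rather than general.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int, pad: int) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """Unfold (N,C,X,Y,Z) into rows of receptive fields: (N*X*Y*Z, C*k^3)."""
    n, c = x.shape[:2]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    v = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    sx, sy, sz = v.shape[2:5]
    col = v.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * sx * sy * sz, c * k**3)
    return np.ascontiguousarray(col), (n, sx, sy, sz)


def _conv_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Correlate (N,C,...) with weights (F,C,k,k,k), 'same' for pad=(k-1)//2."""
    f, c, k = w.shape[0], w.shape[1], w.shape[2]
    col, (n, sx, sy, sz) = _im2col(x, k, pad)
    out = col @ w.reshape(f, c * k**3).T
    return out.reshape(n, sx, sy, sz, f).transpose(0, 4, 1, 2, 3)


class Layer:
    """Base: parameters and gradients are flat name->array dicts."""

    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}


class Conv3d(Layer):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (cin * k**3))  # He init for ReLU nets
        self.W = rng.normal(0.0, scale, (cout, cin, k, k, k)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k, self.pad = k, (k - 1) // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        f, c, k = self.W.shape[0], self.W.shape[1], self.k
        col, (n, sx, sy, sz) = _im2col(x, k, self.pad)
        out = col @ self.W.reshape(f, c * k**3).T + self.b
        if train:
            self._col = col
        return out.reshape(n, sx, sy, sz, f).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f = self.W.shape[0]
        dm = dout.transpose(0, 2, 3, 4, 1).reshape(-1, f)
        self.dW = (self._col.T @ dm).T.reshape(self.W.shape)
        self.db = dm.sum(axis=0)
        self._col = None
        # input gradient = full correlation with flipped, channel-swapped W
        wb = np.ascontiguousarray(
            self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        return _conv_raw(dout, wb, self.pad)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class InstanceNorm(Layer):
    """Per-sample, per-channel standardization over spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        g = self.gamma.reshape(1, -1, 1, 1, 1)
        return g * xhat + self.beta.reshape(1, -1, 1, 1, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ax = (2, 3, 4)
        xhat, inv = self._xhat, self._inv
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.dbeta = dout.sum(axis=(0, 2, 3, 4))
        dxh = dout * self.gamma.reshape(1, -1, 1, 1, 1)
        m = dxh.mean(axis=ax, keepdims=True)
        mx = (dxh * xhat).mean(axis=ax, keepdims=True)
        self._xhat = self._inv = None
        return inv * (dxh - m - xhat * mx)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


class MaxPool2(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, sx, sy, sz = x.shape
        b = x.reshape(n, c, sx // 2, 2, sy // 2, 2, sz // 2, 2)
        b = b.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, sx // 2, sy // 2, sz // 2, 8
        )
        idx = b.argmax(axis=-1)
        if train:
            self._onehot = (
                idx[..., None] == np.arange(8)
            )
            self._shape = x.shape
        return np.take_along_axis(b, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, sx, sy, sz = self._shape
        db = dout[..., None] * self._onehot
        db = db.reshape(n, c, sx // 2, sy // 2, sz // 2, 2, 2, 2)
        db = db.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, sx, sy, sz)
        self._onehot = None
        return np.ascontiguousarray(db)


class Upsample2(Layer):
    """Nearest-neighbour doubling of each spatial axis."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, sx, sy, sz = dout.shape
        b = dout.reshape(n, c, sx // 2, 2, sy // 2, 2, sz // 2, 2)
        return b.sum(axis=(3, 5, 7))


def _rowsoftmax(e: np.ndarray) -> np.ndarray:
    e = e - e.max(axis=-1, keepdims=True)
    np.exp(e, out=e)
    e /= e.sum(axis=-1, keepdims=True)
    return e


def _softmax_back(a: np.ndarray, da: np.ndarray) -> np.ndarray:
    return a * (da - (da * a).sum(axis=-1, keepdims=True))


class PositionAttention(Layer):
    """Spatial self-attention over the flattened bottleneck voxels.

    Query/key use ``c // 4`` channels; the residual gain ``gamma`` starts
    at 0 so the block is the identity at initialization.
    """

    def __init__(self, c: int, rng: np.random.Generator, dtype=np.float32):
        cq = max(1, c // 4)
        s = np.sqrt(1.0 / c)
        self.Wq = rng.normal(0, s, (cq, c)).astype(dtype)
        self.Wk = rng.normal(0, s, (cq, c)).astype(dtype)
        self.Wv = rng.normal(0, s, (c, c)).astype(dtype)
        self.gamma = np.zeros(1, dtype=dtype)
        for n in ("Wq", "Wk", "Wv", "gamma"):
            setattr(self, "d" + n, np.zeros_like(getattr(self, n)))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c = x.shape[:2]
        xf = x.reshape(n, c, -1)
        q = self.Wq @ xf
        k = self.Wk @ xf
        v = self.Wv @ xf
        e = np.einsum("ncp,ncq->npq", q, k)
        a = _rowsoftmax(e)
        o = np.einsum("ncq,npq->ncp", v, a)
        if train:
            self._cache = (xf, q, k, v, a, o)
        return x + self.gamma * o.reshape(x.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xf, q, k, v, a, o = self._cache
        self._cache = None
        n, c = dout.shape[:2]
        dof = dout.reshape(n, c, -1)
        self.dgamma = np.array([(dof * o).sum()], dtype=self.gamma.dtype)
        do = self.gamma * dof
        dv = np.einsum("ncp,npq->ncq", do, a)
        da = np.einsum("ncq,ncp->npq", v, do)
        de = _softmax_back(a, da)
        dq = np.einsum("ncq,npq->ncp", k, de)
        dk = np.einsum("ncp,npq->ncq", q, de)
        self.dWq = np.einsum("ncp,nkp->ck", dq, xf).astype(self.Wq.dtype)
        self.dWk = np.einsum("ncp,nkp->ck", dk, xf).astype(self.Wk.dtype)
        self.dWv = np.einsum("ncp,nkp->ck", dv, xf).astype(self.Wv.dtype)
        dxf = (
            np.einsum("ck,ncp->nkp", self.Wq, dq)
            + np.einsum("ck,ncp->nkp", self.Wk, dk)
            + np.einsum("ck,ncp->nkp", self.Wv, dv)
        )
        return dout + dxf.reshape(dout.shape)

    def params(self):
        return {"Wq": self.Wq, "Wk": self.Wk, "Wv": self.Wv, "gamma": self.gamma}

    def grads(self):
        return {"Wq": self.dWq, "Wk": self.dWk, "Wv": self.dWv, "gamma": self.dgamma}


class ChannelAttention(Layer):
    """Channel self-attention: affinity over channels of the bottleneck."""

    def __init__(self, c: int, dtype=np.float32):
        self.gamma = np.zeros(1, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c = x.shape[:2]
        xf = x.reshape(n, c, -1)
        e = np.einsum("ncp,nkp->nck", xf, xf)
        a = _rowsoftmax(e)
        o = np.einsum("nck,nkp->ncp", a, xf)
        if train:
            self._cache = (xf, a, o)
        return x + self.gamma * o.reshape(x.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xf, a, o = self._cache
        self._cache = None
        n, c = dout.shape[:2]
        dof = dout.reshape(n, c, -1)
        self.dgamma = np.array([(dof * o).sum()], dtype=self.gamma.dtype)
        do = self.gamma * dof
        dxf = np.einsum("nck,ncp->nkp", a, do)  # through V path
        da = np.einsum("ncp,nkp->nck", do, xf)
        de = _softmax_back(a, da)
        dxf += np.einsum("nck,nkp->ncp", de + de.transpose(0, 2, 1), xf)
        return dout + dxf.reshape(dout.shape)

    def params(self):
        return {"gamma": self.gamma}

    def grads(self):
        return {"gamma": self.dgamma}


class SoftmaxC(Layer):
    """Softmax over the channel axis of (N,C,X,Y,Z)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=1, keepdims=True)
        if train:
            self._p = z
        return z

    def backward(self, dp: np.ndarray) -> np.ndarray:
        p = self._p
        self._p = None
        return p * (dp - (dp * p).sum(axis=1, keepdims=True))


class Optimizer:
    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 l2: float = 0.0):
        self.params = params
        self.lr = lr
        self.l2 = l2
        self.state: Dict[str, Dict[str, np.ndarray]] = {
            k: {} for k in params
        }
        self.t = 0

    def _reg(self, name: str, p: np.ndarray, g: np.ndarray) -> np.ndarray:
        # L2 only on weight tensors, not biases / norm gains
        if self.l2 and p.ndim > 1:
            return g + self.l2 * p
        return g

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr, l2=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr, l2)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = self._reg(k, p, grads[k])
            st = self.state[k]
            st.setdefault("m", np.zeros_like(p))
            st.setdefault("v", np.zeros_like(p))
            st["m"] = b1 * st["m"] + (1 - b1) * g
            st["v"] = b2 * st["v"] + (1 - b2) * g * g
            mhat = st["m"] / (1 - b1**self.t)
            vhat = st["v"] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(Optimizer):
    def __init__(self, params, lr, l2=0.0, rho=0.9, eps=1e-7):
        super().__init__(params, lr, l2)
        self.rho, self.eps = rho, eps

    def step(self, grads):
        for k, p in self.params.items():
            g = self._reg(k, p, grads[k])
            st = self.state[k]
            st.setdefault("v", np.zeros_like(p))
            st["v"] = self.rho * st["v"] + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(st["v"]) + self.eps)


def make_optimizer(name: str, params: Dict[str, np.ndarray], lr: float,
                   l2: float = 0.0) -> Optimizer:
    if name == "adam":
        return Adam(params, lr, l2)
    if name == "rmsprop":
        return RMSProp(params, lr, l2)
    raise ValueError(f"unknown optimizer {name!r}; expected 'adam' or 'rmsprop'")
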