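"""Minimal 3D neural-network layers with explicit backprop.

All layers operate on arrays of shape ``(N, C, D, H, W)`` (batch, channels,
three spatial axes) and cache whatever the backward pass needs on ``self``.
The stack is intentionally small: it covers exactly the blocks required by an
SFCN-style volumetric encoder (3x3x3 / 1x1x1 convolution, batch norm, 2x2x2
max/average pooling with floor semantics, ReLU, dropout, flatten) plus dense
heads, and an Adam optimizer whose state is keyed by parameter name so that
disjoint parameter groups can be updated by independent optimizers.

Design constraints honoured here:

* Pooling along an axis whose extent is < 2 is the identity, so arbitrarily
  small desk-scale volumes flow through the full block stack without any
  spatial extent ever reaching zero.
* Batch-norm running statistics are *staged* during a training forward pass
  and only written by :meth:`Sequential.commit_bn`; a zero-learning-rate
  update therefore leaves every byte of the model untouched.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "MaxPool3d",
    "AvgPool3d",
    "ReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
]


def _extract_patches(x: np.ndarray, k: int) -> np.ndarray:
    """im2col for stride-1 kxkxk windows: (N,C,D,H,W) -> (N, P, C*k^3)."""
    n, c, d, h, w = x.shape
    sn, sc, sd, sh, sw = x.strides
    od, oh, ow = d - k + 1, h - k + 1, w - k + 1
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, od, oh, ow, c, k, k, k),
        strides=(sn, sd, sh, sw, sc, sd, sh, sw),
        writeable=False,
    )
    return view.reshape(n, od * oh * ow, c * k * k * k)


class Layer:
    """Base class: stateless forward/backward contract."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def buffers(self) -> dict:
        return {}


class Conv3d(Layer):
    """Stride-1 3D convolution; 'same' padding for k=3, none for k=1."""

    def __init__(self, in_ch, out_ch, kernel, rng, dtype=np.float32,
                 needs_input_grad=True):
        if kernel not in (1, 3):
            raise ValueError("only 1x1x1 and 3x3x3 kernels are supported")
        self.k = kernel
        self.needs_input_grad = needs_input_grad
        self.pad = (kernel - 1) // 2
        fan_in = in_ch * kernel ** 3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, in_ch, kernel, kernel, kernel)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._in_shape = x.shape
        cols = _extract_patches(xp, k)
        self._cols = cols
        n = x.shape[0]
        out_ch = self.W.shape[0]
        wmat = self.W.reshape(out_ch, -1)
        out = cols @ wmat.T + self.b
        d, h, w = x.shape[2:]
        return out.reshape(n, d, h, w, out_ch).transpose(0, 4, 1, 2, 3)

    def backward(self, dout):
        k = self.k
        n, out_ch, d, h, w = dout.shape
        dmat = dout.transpose(0, 2, 3, 4, 1).reshape(n, d * h * w, out_ch)
        self.dW = np.einsum("npo,npc->oc", dmat, self._cols).reshape(self.W.shape)
        self.db = dmat.sum(axis=(0, 1))
        if not self.needs_input_grad:  # first layer: nothing consumes dx
            return None
        wmat = self.W.reshape(out_ch, -1)
        if k == 1:
            dx = dmat @ wmat
        else:
            # full correlation of dout with the spatially flipped kernel
            q = k - 1 - self.pad  # 'same' padding: q == pad == 1
            dpad = np.pad(dout, ((0, 0), (0, 0), (q, q), (q, q), (q, q)))
            dcols = _extract_patches(dpad, k)
            wrot = np.flip(self.W, (2, 3, 4)).transpose(1, 0, 2, 3, 4)
            dx = dcols @ wrot.reshape(wrot.shape[0], -1).T
        in_ch = self.W.shape[1]
        return dx.reshape(n, d, h, w, in_ch).transpose(0, 4, 1, 2, 3)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm3d(Layer):
    """Per-channel batch norm over (N, D, H, W).

    Training forwards stage the running-statistic update; it is applied only
    when the owning :class:`Sequential` commits (i.e. when the surrounding
    optimizer step actually modifies the model).
    """

    def __init__(self, n_ch, dtype=np.float32, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(n_ch, dtype=dtype)
        self.beta = np.zeros(n_ch, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._staged = None
        # "batch": classic training BN. "running": training forwards
        # normalise by the running statistics (treated as constants in the
        # backward pass) while still staging batch statistics for tracking —
        # keeps training and inference representations aligned without
        # letting the representation collapse unnoticed.
        self.policy = "batch"

    @staticmethod
    def _bc(v):
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x, train=False):
        if train:
            self._staged = (x.mean(axis=(0, 2, 3, 4)),
                            x.var(axis=(0, 2, 3, 4)))
            if self.policy == "running":
                mu, var = self.running_mean, self.running_var
                self._train = False  # stats are constants in backward
            else:
                mu, var = self._staged
                self._train = True
        else:
            mu, var = self.running_mean, self.running_var
            self._train = False
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bc(mu)) * self._bc(ivstd)
        self._xhat, self._ivstd = xhat, ivstd
        return self._bc(self.gamma) * xhat + self._bc(self.beta)

    def backward(self, dout):
        xhat, ivstd = self._xhat, self._ivstd
        axes = (0, 2, 3, 4)
        self.dgamma = (dout * xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self._bc(self.gamma)
        if not self._train:
            return dxhat * self._bc(ivstd)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        t1 = m * dxhat
        t2 = dxhat.sum(axis=axes)
        t3 = xhat * (dxhat * xhat).sum(axis=axes).reshape(1, -1, 1, 1, 1)
        return (self._bc(ivstd) / m) * (t1 - t2.reshape(1, -1, 1, 1, 1) - t3)

    def commit(self):
        if self._staged is not None:
            mu, var = self._staged
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
            self._staged = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class _Pool3d(Layer):
    """Shared machinery for factor-2 floor pooling; extent-1 axes pass through."""

    def __init__(self, kernel=2):
        if kernel != 2:
            raise ValueError("only kernel 2 pooling is implemented")
        self.kernel = kernel

    def forward(self, x, train=False):
        self._steps = []
        for axis in (2, 3, 4):
            x = self._pool_axis(x, axis)
        return x

    def backward(self, dout):
        for step in reversed(self._steps):
            dout = self._unpool_axis(dout, step)
        return dout

    def _pool_axis(self, x, axis):
        e = x.shape[axis]
        if e < 2:
            self._steps.append(("skip", axis, None))
            return x
        half = e // 2
        xc = np.moveaxis(x, axis, -1)[..., : 2 * half]
        view = xc.reshape(xc.shape[:-1] + (half, 2))
        out, extra = self._reduce(view)
        self._steps.append(("pool", axis, (e, half, view.shape, extra)))
        return np.moveaxis(out, -1, axis)

    def _unpool_axis(self, dout, step):
        kind, axis, info = step
        if kind == "skip":
            return dout
        e, half, vshape, extra = info
        dmoved = np.moveaxis(dout, axis, -1)
        dview = self._spread(dmoved, vshape, extra)
        dflat = dview.reshape(vshape[:-2] + (2 * half,))
        if 2 * half < e:
            pad = [(0, 0)] * dflat.ndim
            pad[-1] = (0, e - 2 * half)
            dflat = np.pad(dflat, pad)
        return np.moveaxis(dflat, -1, axis)


class MaxPool3d(_Pool3d):
    def _reduce(self, view):
        idx = view.argmax(axis=-1)
        out = np.take_along_axis(view, idx[..., None], axis=-1)[..., 0]
        return out, idx

    def _spread(self, dmoved, vshape, idx):
        dview = np.zeros(vshape, dtype=dmoved.dtype)
        np.put_along_axis(dview, idx[..., None], dmoved[..., None], axis=-1)
        return dview


class AvgPool3d(_Pool3d):
    def _reduce(self, view):
        return view.mean(axis=-1), None

    def _spread(self, dmoved, vshape, _extra):
        return np.repeat(dmoved[..., None] / 2.0, 2, axis=-1)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; draws masks from an externally owned generator."""

    def __init__(self, rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def commit_bn(self):
        for layer in self.layers:
            if isinstance(layer, BatchNorm3d):
                layer.commit()

    def set_bn_policy(self, policy: str):
        if policy not in ("batch", "running"):
            raise ValueError("policy must be 'batch' or 'running'")
        for layer in self.layers:
            if isinstance(layer, BatchNorm3d):
                layer.policy = policy

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                out[f"{i}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads().items():
                out[f"{i}.{k}"] = v
        return out

    def buffers(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.buffers().items():
                out[f"{i}.{k}"] = v
        return out

    def set_params(self, flat: dict):
        for i, layer in enumerate(self.layers):
            for k in layer.params():
                key = f"{i}.{k}"
                if key in flat:
                    getattr(layer, k)[...] = flat[key]

    def set_buffers(self, flat: dict):
        for i, layer in enumerate(self.layers):
            for k in layer.buffers():
                key = f"{i}.{k}"
                if key in flat:
                    getattr(layer, k)[...] = flat[key]


class Adam:
    """Adam over a named parameter dict; state keyed by name.

    Updates are written in place so that several optimizers can own disjoint
    (or overlapping, with independent moments) parameter groups of one model.
    With ``lr == 0`` the step is a no-op and touches nothing.
    """

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m, self.v = {}, {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> bool:
        if self.lr == 0.0:
            return False
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in params.items():
            g = grads[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(p, dtype=np.float64)
                self.v[key] = np.zeros_like(p, dtype=np.float64)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * (g * g)
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
        return True
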