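"""Minimal numpy neural-network engine for the residual grading network.

Implements exactly the pieces the grader architecture needs -- 2-D
convolution (im2col + BLAS), batch normalisation, ReLU, max/global-average
pooling, a fully connected head, residual blocks with identity or projection
shortcuts, and Adam -- with hand-derived backward passes. Gradients flow all
the way back to the input image, which is what the saliency map consumes.

Conventions: activations are (N, C, H, W); convolution and linear kernels are
He-initialised; biases are omitted in convolutions (each is followed by batch
norm). Parameters carry an ``l2`` flag marking whether they belong to the
weight-decay term (convolution and linear kernels do; biases and
normalisation parameters do not).
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "l2", "name")

    def __init__(self, value: np.ndarray, l2: bool = False, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.l2 = l2
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def state(self) -> dict[str, np.ndarray]:
        """Non-trainable buffers (e.g. batch-norm running statistics)."""
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, ksize: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, ksize
        self.stride = stride
        self.pad = ksize // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * ksize * ksize))
        self.W = Param(rng.normal(0.0, std, (cout, cin, ksize, ksize)).astype(dtype),
                       l2=True, name="conv.W")
        self._cache = None

    def params(self):
        return [self.W]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, OH, OW, k, k) -> (N*OH*OW, C*k*k)
        oh, ow = sw.shape[2], sw.shape[3]
        cols = np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * oh * ow, c * k * k)
        return cols, (n, c, h, w, oh, ow)

    def forward(self, x, training):
        cols, shape = self._im2col(x)
        n, c, h, w, oh, ow = shape
        wmat = self.W.value.reshape(self.cout, -1)
        out = cols @ wmat.T
        self._cache = (cols, shape)
        return out.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w, oh, ow) = self._cache
        p, k, s = self.pad, self.k, self.stride
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)
                                    ).reshape(n * oh * ow, self.cout)
        self.W.grad += (dmat.T @ cols).reshape(self.W.value.shape)
        dcols = dmat @ self.W.value.reshape(self.cout, -1)
        dsw = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += dsw[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype), name="bn.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), name="bn.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * invstd[:, None, None]
        self._cache = (xhat.astype(x.dtype), invstd.astype(x.dtype), training)
        return self.gamma.value[:, None, None] * self._cache[0] + self.beta.value[:, None, None]

    def backward(self, dout):
        xhat, invstd, training = self._cache
        axes = (0, 2, 3)
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = (self.gamma.value * invstd)[:, None, None]
        if not training:
            return dout * g
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        return g / m * (m * dout - dbeta[:, None, None] - xhat * dgamma[:, None, None])


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, ksize: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = ksize, stride, pad

    def forward(self, x, training):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        sw = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        oh, ow = sw.shape[2], sw.shape[3]
        flat = sw.reshape(n, c, oh, ow, k * k)
        self._arg = flat.argmax(axis=-1)
        self._shape = (n, c, h, w, oh, ow)
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h, w, oh, ow = self._shape
        p, k, s = self.pad, self.k, self.stride
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        ni, ci, ohi, owi = np.indices((n, c, oh, ow))
        ii = ohi * s + self._arg // k
        jj = owi * s + self._arg % k
        np.add.at(dxp, (ni, ci, ii, jj), dout)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(dout.dtype)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, std, (cin, cout)).astype(dtype),
                       l2=True, name="fc.W")
        self.b = Param(np.zeros(cout, dtype=dtype), name="fc.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class ResidualBlock(Layer):
    """Two 3x3 convolutions with batch norm; identity or projection shortcut.

    Identity form keeps W x H x C; the downsampling form has stride 2 on the
    first convolution, doubles (in general: changes) the channel count and
    projects the shortcut through a 1x1 stride-2 convolution.
    """

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.short_conv = Conv2d(cin, cout, 1, stride=stride, pad=0,
                                     rng=rng, dtype=dtype)
            self.short_bn = BatchNorm2d(cout, dtype=dtype)
        else:
            self.short_conv = None
            self.short_bn = None

    def sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.short_conv is not None:
            subs += [self.short_conv, self.short_bn]
        return subs

    def params(self):
        return [p for l in self.sublayers() for p in l.params()]

    def state(self):
        out = {}
        for i, l in enumerate(self.sublayers()):
            for k, v in l.state().items():
                out[f"{i}.{k}"] = v
        return out

    def forward(self, x, training):
        r = self.conv1.forward(x, training)
        r = self.bn1.forward(r, training)
        r = self.relu1.forward(r, training)
        r = self.conv2.forward(r, training)
        r = self.bn2.forward(r, training)
        if self.short_conv is not None:
            idt = self.short_bn.forward(self.short_conv.forward(x, training), training)
        else:
            idt = x
        return self.relu_out.forward(r + idt, training)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dr = self.bn2.backward(d)
        dr = self.conv2.backward(dr)
        dr = self.relu1.backward(dr)
        dr = self.bn1.backward(dr)
        dx = self.conv1.backward(dr)
        if self.short_conv is not None:
            dx = dx + self.short_conv.backward(self.short_bn.backward(d))
        else:
            dx = dx + d
        return dx


class Sequential(Layer):
    """Plain layer chain; also the container used for whole networks."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def state(self):
        out = {}
        for i, l in enumerate(self.layers):
            for k, v in l.state().items():
                out[f"layer{i}.{k}"] = v
        return out

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- (de)serialisation -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param{i}": p.value for i, p in enumerate(self.params())}
        out.update({f"buffer.{k}": v for k, v in self.state().items()})
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        mismatches = []
        params = self.params()
        for i, p in enumerate(params):
            a = arrays[f"param{i}"]
            if a.shape != p.value.shape:
                mismatches.append(f"param{i}: {a.shape} vs {p.value.shape}")
            else:
                p.value = a.astype(p.value.dtype).copy()
        if mismatches:
            raise ValueError("parameter shape mismatch: " + "; ".join(mismatches))
        buffers = self.state()
        for k, v in buffers.items():
            v[...] = arrays[f"buffer.{k}"].astype(v.dtype)


class Adam:
    """Adam with decoupled-from-schedule learning rate passed per step."""

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay  # lambda of the L2 loss term
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.l2:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value = p.value - lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
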