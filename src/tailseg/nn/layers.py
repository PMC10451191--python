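"""Neural-network modules built on the tape autodiff primitives.

Conventions: NCHW float64 feature maps; He-normal initialisation for
convolution kernels from an explicit ``numpy.random.Generator`` so that a
model rebuilt from (config, seed) is bit-identical; batch-normalisation
running statistics use momentum 0.1 and biased batch variance.
"""

from __future__ import annotations

import numpy as np

from . import tape
from .tape import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight module container with named parameters and buffers."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def register_buffer(self, name, value):
        arr = np.asarray(value)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)

    def _set_buffer(self, name, value):
        self._buffers[name][...] = value

    # -- modes / state -------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        d = {n: p.data.copy() for n, p in self.named_parameters()}
        d.update({n: b.copy() for n, b in self.named_buffers()})
        return d

    def astype(self, dtype):
        """Cast all parameters and buffers (recursively) to ``dtype``."""
        for p in self._params.values():
            p.data = p.data.astype(dtype)
        for name in list(self._buffers):
            self.register_buffer(name, self._buffers[name].astype(dtype))
        for m in self._modules.values():
            m.astype(dtype)
        return self

    def dtype(self):
        for p in self.parameters():
            return p.data.dtype
        return np.dtype(np.float64)

    def load_state_dict(self, d):
        own_p = dict(self.named_parameters())
        own_b = dict(self.named_buffers())
        missing = (set(own_p) | set(own_b)) - set(d)
        extra = set(d) - (set(own_p) | set(own_b))
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for n, p in own_p.items():
            if p.data.shape != d[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data[...] = d[n]
        for n, b in own_b.items():
            b[...] = d[n]

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _he_normal(rng: np.random.Generator, shape, fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, padding=0, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_he_normal(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return tape.conv2d(x, self.weight, self.bias,
                           stride=self.stride, padding=self.padding)


class ConvTranspose2x(Module):
    """Learnable x2 upsampling (2x2 kernel, stride 2)."""

    def __init__(self, cin, cout, rng, bias=True):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (cin, cout, 2, 2), cin * 4))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return tape.conv_transpose2x(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c))
        self.register_buffer("running_var", np.ones(c))

    def _norm(self, x):
        """Normalized input (tape tensor); updates running stats in train mode."""
        if self.training:
            xhat, mu, var = tape.batch_normalize(x, eps=self.eps)
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.ravel())
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * var.ravel())
            return xhat
        c = x.shape[1]
        sh = (1, c, 1, 1)
        return tape.fixed_normalize(x, self.running_mean.reshape(sh),
                                    self.running_var.reshape(sh), eps=self.eps)

    def forward(self, x):
        return tape.channel_affine(self._norm(x), self.gamma, self.beta)


class ChannelAttention(Module):
    """Normalisation-based channel gate.

    The input is batch-normalised per channel; each channel's gate is a
    sigmoid of the normalised signal scaled by its learnable scale factor
    alpha and that factor's share of the total, W_c = alpha_c / sum(alpha).
    The gate multiplies the input elementwise, softly suppressing channels
    whose scale factor is small — uninformative channels for MRI feature
    maps where contrast is weak.

    ``nam_style=False`` (default) reads the gate literally as
    sigmoid(W_c * alpha_c * xhat + beta_c); ``nam_style=True`` scales the
    whole affine-normalised output, sigmoid(W_c * (alpha_c * xhat + beta_c)).
    """

    def __init__(self, c, eps=1e-5, momentum=0.1, nam_style=False):
        super().__init__()
        self.eps, self.momentum, self.nam_style = eps, momentum, nam_style
        self.alpha = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c))
        self.register_buffer("running_var", np.ones(c))

    def forward(self, x):
        c = x.shape[1]
        if abs(self.alpha.data.sum()) < 1e-12:
            raise ValueError("degenerate channel scales: sum(alpha) is zero")
        sh = (1, c, 1, 1)
        if self.training:
            xhat, mu, var = tape.batch_normalize(x, eps=self.eps)
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.ravel())
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * var.ravel())
        else:
            xhat = tape.fixed_normalize(x, self.running_mean.reshape(sh),
                                        self.running_var.reshape(sh),
                                        eps=self.eps)
        w = tape.div(self.alpha, tape.tsum(self.alpha))
        zero = tape.Tensor(np.zeros(c))
        if self.nam_style:
            # sigmoid(W_c * (alpha_c * xhat + beta_c))
            inner = tape.channel_affine(xhat, self.alpha, self.beta)
            pre = tape.channel_affine(inner, w, zero)
        else:
            # sigmoid(W_c * alpha_c * xhat + beta_c)
            pre = tape.channel_affine(xhat, tape.mul(w, self.alpha), self.beta)
        return tape.mul(x, tape.sigmoid(pre))


class SpatialAttention(Module):
    """7x7 spatial gate over channel-mean and channel-max planes.

    The per-pixel mean and max over channels are stacked into a 2-plane
    descriptor, convolved with a single 7x7 kernel (zero padding 3, bias),
    and squashed by a sigmoid; the resulting (0,1) map multiplies every
    channel of the input.
    """

    KERNEL = 7

    def __init__(self, rng):
        super().__init__()
        k = self.KERNEL
        self.weight = Parameter(_he_normal(rng, (1, 2, k, k), 2 * k * k))
        self.bias = Parameter(np.zeros(1))

    def forward(self, x):
        avg = tape.tmean(x, axis=1, keepdims=True)
        mx = tape.channel_max(x)
        planes = tape.concat([avg, mx], axis=1)
        pre = tape.conv2d(planes, self.weight, self.bias,
                          padding=self.KERNEL // 2)
        return tape.mul(x, tape.sigmoid(pre))


class Adam:
    """Adam optimizer over a parameter list (standard bias-corrected form)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad * p.grad - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
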