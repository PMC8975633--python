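"""Minimal neural-network layers and an Adam optimizer on top of `autodiff`.

Layers follow the NCHW convention (batch, channel, row, column) and the
weight-shape conventions common to image-translation networks: convolution
weights are ``(out_ch, in_ch, k, k)``, transposed-convolution weights
``(in_ch, out_ch, k, k)``. Initialisation is zero-mean Gaussian with standard
deviation 0.02, the usual choice for adversarial image translation.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialisation."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        mods = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat state dict for checkpointing --------------------------------
    def state_dict(self, prefix: str = ""):
        state = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                state[key] = value.data.copy()
            elif isinstance(value, Tensor):  # buffers (running stats)
                state[key] = value.data.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, (Parameter, Tensor)):
                if key not in state:
                    raise KeyError(f"missing parameter {key!r} in checkpoint")
                arr = np.asarray(state[key])
                if arr.shape != value.data.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: checkpoint {arr.shape}, "
                        f"model {value.data.shape}"
                    )
                value.data = arr.astype(np.float64).copy()
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")


def count_parameters(model: Module) -> int:
    """Exact number of trainable scalars in a model."""
    return int(sum(p.size for p in model.parameters()))


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2D convolution via im2col; padding is zero or reflection."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 pad_mode="zero", bias=True, rng=None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        if pad_mode not in ("zero", "reflect"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        self.pad_mode = pad_mode
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, 0.02, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x = ad.reflect_pad_hw(x, p) if self.pad_mode == "reflect" else ad.pad_zero_hw(x, p)
        Hp, Wp = H + 2 * p, W + 2 * p
        if Hp < k or Wp < k:
            raise ValueError(f"input {H}x{W} too small for kernel {k} (pad {p})")
        Ho = (Hp - k) // s + 1
        Wo = (Wp - k) // s + 1
        if s == 1:
            out = ad.conv2d_s1(x, self.weight)
        else:
            cols = ad.im2col(x, k, s)                         # (C*k*k, N*L)
            w = ad.reshape(self.weight, (self.out_ch, C * k * k))
            out = ad.matmul(w, cols)                          # (out_ch, N*L)
            out = ad.transpose(ad.reshape(out, (self.out_ch, N, Ho, Wo)),
                               (1, 0, 2, 3))
        if self.bias is not None:
            out = out + ad.reshape(self.bias, (1, self.out_ch, 1, 1))
        return out


class ConvTranspose2d(Module):
    """Stride-s transposed convolution (the adjoint of Conv2d's unfolding)."""

    def __init__(self, in_ch, out_ch, kernel, stride=2, padding=1,
                 output_padding=1, bias=True, rng=None):
        super().__init__()
        if output_padding > padding and output_padding >= stride:
            raise ValueError("output_padding must be < stride")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding, self.output_padding = padding, output_padding
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, 0.02, (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        Ho = (H - 1) * s - 2 * p + k + op
        Wo = (W - 1) * s - 2 * p + k + op
        canvas_h = (H - 1) * s + k
        canvas_w = (W - 1) * s + k
        w = ad.reshape(self.weight, (self.in_ch, self.out_ch * k * k))
        wt = ad.transpose(w, (1, 0))
        x_flat = ad.reshape(ad.transpose(x, (1, 0, 2, 3)), (C, N * H * W))
        cols = ad.matmul(wt, x_flat)                          # (out_ch*k*k, N*H*W)
        full = ad.col2im(cols, (canvas_h, canvas_w), k, s, self.out_ch, N)
        out = ad.crop_hw(full, p, p + Ho, p, p + Wo)
        if self.bias is not None:
            out = out + ad.reshape(self.bias, (1, self.out_ch, 1, 1))
        return out


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics for eval mode."""

    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = Tensor(np.zeros(channels))
        self.running_var = Tensor(np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.channels, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            with ad.no_grad():
                m = self.momentum
                self.running_mean.data = (1 - m) * self.running_mean.data \
                    + m * mu.data.reshape(-1)
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                unbias = n / max(n - 1, 1)
                self.running_var.data = (1 - m) * self.running_var.data \
                    + m * var.data.reshape(-1) * unbias
            xhat = xc / ad.sqrt(var + self.eps)
        else:
            mu = Tensor(self.running_mean.data.reshape(shape))
            sd = Tensor(np.sqrt(self.running_var.data.reshape(shape) + self.eps))
            xhat = (x - mu) / sd
        return xhat * ad.reshape(self.gamma, shape) + ad.reshape(self.beta, shape)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x):
        return ad.tanh(x)


class Adam:
    """Adam with decoupled per-step learning rate (set ``lr`` between epochs)."""

    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
            "lr": self.lr,
        }

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
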