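"""Layer/module abstractions over the autodiff tensors.

Initialisation draws from the engine-global RNG (`manual_seed`), so model
construction is reproducible end to end.  Convolutions use Kaiming-uniform
init; transformer linear layers use a truncated normal (std 0.02).
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import (
    Tensor,
    as_tensor,
    avg_pool2d,
    concat,
    conv2d,
    conv_transpose2x2,
    dropout,
    get_rng,
    softmax,
)

DEFAULT_DTYPE = np.float32


def _trunc_normal(shape, std=0.02, dtype=DEFAULT_DTYPE):
    rng = get_rng()
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(dtype)


def _kaiming_uniform(shape, fan_in, dtype=DEFAULT_DTYPE):
    bound = math.sqrt(6.0 / fan_in)
    return get_rng().uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    """Tiny nn.Module analogue: parameter discovery, train/eval, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield (f"{prefix}{name}", val)
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # buffers (running stats) are any plain ndarrays named in _buffers
    _buffer_names: tuple = ()

    def state_dict(self, prefix=""):
        out = {}
        for name, p in self.named_parameters(prefix=prefix):
            out[name] = p.data
        for mod_name, mod in self._named_modules(prefix):
            for bname in mod._buffer_names:
                out[f"{mod_name}{bname}"] = getattr(mod, bname)
        return out

    def _named_modules(self, prefix=""):
        yield prefix, self
        for name, child in self._children():
            yield from child._named_modules(prefix=f"{prefix}{name}.")

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name]).astype(p.data.dtype)
        for mod_name, mod in self._named_modules():
            for bname in mod._buffer_names:
                key = f"{mod_name}{bname}"
                if key in state:
                    setattr(mod, bname, np.asarray(state[key]).astype(DEFAULT_DTYPE))


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Lambda(Module):
    def __init__(self, fn):
        super().__init__()
        self.fn = fn

    def forward(self, x):
        return self.fn(x)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, init="kaiming"):
        super().__init__()
        if init == "kaiming":
            w = _kaiming_uniform((in_features, out_features), in_features)
        else:
            w = _trunc_normal((in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=DEFAULT_DTYPE), requires_grad=True) if bias else None

    def forward(self, x):
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """Stride-1 convolution with `same` padding for odd kernels by default."""

    def __init__(self, in_ch, out_ch, kernel_size, padding=None, bias=True):
        super().__init__()
        k = kernel_size
        if padding is None:
            padding = k // 2
        self.padding = padding
        fan_in = in_ch * k * k
        self.weight = Tensor(_kaiming_uniform((out_ch, in_ch, k, k), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DEFAULT_DTYPE), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class DepthwiseConv2d(Module):
    """Per-channel 3x3 (or kxk) convolution, `same` padding."""

    def __init__(self, channels, kernel_size=3):
        super().__init__()
        k = kernel_size
        self.padding = k // 2
        self.weight = Tensor(_kaiming_uniform((channels, k, k), k * k), requires_grad=True)
        self.bias = Tensor(np.zeros((channels, 1, 1), dtype=DEFAULT_DTYPE), requires_grad=True)

    def forward(self, x):
        from .tensor import depthwise_conv2d
        return depthwise_conv2d(x, self.weight, padding=self.padding) + self.bias


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, in_ch, out_ch, bias=True):
        super().__init__()
        self.weight = Tensor(_kaiming_uniform((in_ch, out_ch, 2, 2), in_ch * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DEFAULT_DTYPE), requires_grad=True) if bias else None

    def forward(self, x):
        return conv_transpose2x2(x, self.weight, self.bias)


class AvgPool2d(Module):
    def __init__(self, factor):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        return avg_pool2d(x, self.factor)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(num_features, dtype=DEFAULT_DTYPE)

    def forward(self, x):
        x = as_tensor(x)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1).astype(x.data.dtype))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1).astype(x.data.dtype))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    """Normalises the last axis; per-token zero mean / unit variance."""

    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DEFAULT_DTYPE), requires_grad=True)

    def forward(self, x):
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x):
        return dropout(x, self.p, self.training)


class Activation(Module):
    def __init__(self, kind):
        super().__init__()
        self.kind = kind

    def forward(self, x):
        return getattr(as_tensor(x), self.kind)()


class MultiHeadSelfAttention(Module):
    """Standard softmax self-attention over (N, L, D) token sequences.

    The last attention map (detached numpy, shape (N, heads, L, L)) is kept
    on `last_attn` for inspection.
    """

    def __init__(self, dim, n_heads, drop=0.0):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, init="trunc_normal")
        self.proj = Linear(dim, dim, init="trunc_normal")
        self.drop = Dropout(drop)
        self.last_attn = None

    def forward(self, x):
        x = as_tensor(x)
        N, L, D = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(N, L, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (N, h, L, hd)
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd)), axis=-1)
        self.last_attn = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(N, L, D)
        return self.drop(self.proj(out))


class TransformerBlock(Module):
    """Pre-norm ViT block: MHSA + 2x-expansion GELU MLP, residual both times."""

    def __init__(self, dim, n_heads, drop=0.0, mlp_ratio=2):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, drop=drop)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, init="trunc_normal")
        self.fc2 = Linear(dim * mlp_ratio, dim, init="trunc_normal")
        self.drop = Dropout(drop)

    def forward(self, x):
        x = as_tensor(x)
        x = x + self.attn(self.norm1(x))
        x = x + self.drop(self.fc2(self.fc1(self.norm2(x)).gelu()))
        return x
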