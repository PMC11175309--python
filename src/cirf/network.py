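"""The five coupled-fusion sub-networks and the two dataflows.

Architecture
------------
A shared Parallel Decomposition Encoder (PDE) splits each single-channel
input into *base* features (global structure/contrast, from a ViT branch)
and *detail* features (edges/texture, from a CNN branch), each
``(N, 64, H, W)``.  The two branches exchange information between stacks:
detail maps are pooled/flattened/layer-normalised into extra tokens for
the ViT; base tokens are reshaped/bilinearly-interpolated/batch-normalised
into an extra map for the CNN.

Fusion path:    Tf = DFD(cat(BFB(Phi1B + Phi2B), DFB(Phi1D + Phi2D)))
Reconstruction: Tk_hat = DRD(cat(PhikB, PhikD)), through the SAME encoder.

* BFB (base fusion) is a lite-transformer style block: one head group
  models local context with a GLU-gated convolution, the other long-range
  context with softmax attention over a pooled token grid.
* DFB (detail fusion) is a residual fusion CNN: two conv/BN cells with an
  ELU between them, a convolutional residual from input to output, and a
  final ReLU6 that bounds every activation to [0, 6].
* DFD and DRD are Restormer-style decoders (channel-wise transposed
  attention + gated depthwise-conv feed-forward) with separate parameters,
  ending in a sigmoid so fused/reconstructed images lie in [0, 1].

At inference only the fusion path runs; the reconstruction decoder is
never executed (``drd.n_calls`` counts executions for verification).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import (
    Tensor,
    avg_pool2d,
    concat,
    no_grad,
    upsample_bilinear,
)
from ._autodiff.modules import (
    Activation,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    DepthwiseConv2d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    MultiHeadSelfAttention,
    Sequential,
    TransformerBlock,
    _trunc_normal,
)
from .data import random_mask

__all__ = [
    "ModelConfig",
    "EncoderOutput",
    "PDEncoder",
    "BaseFusionBlock",
    "DetailFusionBlock",
    "RestormerDecoder",
    "FusionModel",
    "save_model",
    "load_model",
]

_DIVISOR = 32  # input sides must divide this (stem pooling x patch grid)


@dataclass
class ModelConfig:
    patch_size: int = 8
    n_heads: int = 4
    vit_depth: int = 6           # transformer blocks in total, split across stacks
    drop_rate: float = 0.10
    n_interaction_stacks: int = 2  # the "i" of the encoder
    stem_kernel: int = 7
    feature_channels: int = 64
    relu6_cap: float = 6.0
    vit_dim: int = 128
    restormer_blocks: int = 2
    image_size: int = 256        # nominal size; fixes the learned pos-embed grid

    def __post_init__(self):
        if self.n_interaction_stacks < 1:
            raise ValueError("need at least one encoder stack")
        if self.vit_depth < self.n_interaction_stacks:
            raise ValueError("vit_depth must be >= number of stacks")

    @classmethod
    def small(cls, image_size: int = 64):
        """Desk-scale preset for CPU experiments: shallower ViT and decoder,
        same 64-channel feature contract."""
        return cls(vit_depth=2, vit_dim=64, restormer_blocks=1,
                   image_size=image_size)


@dataclass
class EncoderOutput:
    base: Tensor    # (N, 64, H, W)
    detail: Tensor  # (N, 64, H, W)


def _check_input(x: Tensor):
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
    _, _, h, w = x.shape
    if h % _DIVISOR or w % _DIVISOR:
        raise ValueError(
            f"input sides must be divisible by {_DIVISOR}; got {h}x{w}")


class PDEncoder(Module):
    """Parallel ViT-CNN decomposition encoder with cross-branch interaction."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        ch = cfg.feature_channels
        p = cfg.patch_size
        self.stem = Sequential(
            Conv2d(1, 32, cfg.stem_kernel), Activation("relu"),
            Conv2d(32, ch, 3), Activation("relu"),
        )  # followed by 2x2 average pooling in forward
        # ViT branch: extra conv, then 8x8 patch embedding of the halved map
        self.vit_pre = Sequential(Conv2d(ch, 96, 3), Activation("relu"))
        self.patch_embed = Linear(96 * p * p, cfg.vit_dim, init="trunc_normal")
        base_grid = cfg.image_size // (2 * p)
        self.pos_embed = Tensor(
            _trunc_normal((1, base_grid, base_grid, cfg.vit_dim)), requires_grad=True)
        self.pos_drop = Dropout(cfg.drop_rate)
        n_stacks = cfg.n_interaction_stacks
        depths = [cfg.vit_depth // n_stacks] * n_stacks
        for k in range(cfg.vit_depth % n_stacks):
            depths[k] += 1
        self.vit_stacks = [
            Sequential(*[TransformerBlock(cfg.vit_dim, cfg.n_heads, drop=cfg.drop_rate)
                         for _ in range(d)])
            for d in depths
        ]
        self.cnn_stacks = [
            Sequential(
                Conv2d(ch, ch, 3), BatchNorm2d(ch), Activation("elu"),
                Conv2d(ch, ch, 3), BatchNorm2d(ch), Activation("elu"),
            )
            for _ in range(n_stacks)
        ]
        # interaction adapters (stacks 2..i)
        self.d2b_norm = [LayerNorm(ch) for _ in range(n_stacks - 1)]
        self.d2b_proj = [Linear(ch, cfg.vit_dim, init="trunc_normal")
                         for _ in range(n_stacks - 1)]
        self.b2d_proj = [Linear(cfg.vit_dim, ch, init="trunc_normal")
                         for _ in range(n_stacks - 1)]
        self.b2d_norm = [BatchNorm2d(ch) for _ in range(n_stacks - 1)]
        # restore to full resolution via transposed convolutions
        self.vit_restore = Sequential(
            ConvTranspose2x2(cfg.vit_dim, ch), Activation("relu"),
            ConvTranspose2x2(ch, ch), Activation("relu"),
            ConvTranspose2x2(ch, ch), Activation("relu"),
            ConvTranspose2x2(ch, ch),
        )  # x16: patch grid back to H, W
        self.cnn_restore = ConvTranspose2x2(ch, ch)  # x2: half res back to H, W

    # -- interaction primitives (exposed for inspection/tests) ------------
    def interact_detail_to_base(self, detail_map: Tensor, stage: int = 1) -> Tensor:
        """Detail feature map -> extra ViT tokens: pool to the patch grid,
        flatten to per-cell channel tokens, layer-normalise, then project
        to the token width."""
        p = self.cfg.patch_size
        pooled = avg_pool2d(detail_map, p)              # (N, C, gh, gw)
        n, c, gh, gw = pooled.shape
        tok = pooled.reshape(n, c, gh * gw).transpose(0, 2, 1)
        idx = stage - 1
        return self.d2b_proj[idx](self.d2b_norm[idx](tok))

    def interact_base_to_detail(self, tokens: Tensor, grid_hw, stage: int = 1) -> Tensor:
        """ViT tokens -> extra CNN feature map: reshape to the patch grid,
        bilinear-interpolate up to the CNN resolution, batch-normalise."""
        p = self.cfg.patch_size
        gh, gw = grid_hw
        idx = stage - 1
        mapped = self.b2d_proj[idx](tokens)             # (N, L, C)
        n, L, c = mapped.shape
        grid = mapped.transpose(0, 2, 1).reshape(n, c, gh, gw)
        up = upsample_bilinear(grid, p)
        return self.b2d_norm[idx](up)

    def _resize_pos(self, gh: int, gw: int, dtype) -> Tensor:
        pos = self.pos_embed  # (1, bg, bg, D)
        bg = pos.shape[1]
        grid = pos.transpose(0, 3, 1, 2)  # (1, D, bg, bg)
        for g, ax in ((gh, 0), (gw, 1)):
            cur = grid.shape[2 + ax]
            if g == cur:
                continue
            # integer-factor resize through the least common multiple
            lcm = cur * g // math.gcd(cur, g)
            if lcm // cur > 1:
                f = (lcm // cur, 1) if ax == 0 else (1, lcm // cur)
                grid = upsample_bilinear(grid, f)
            if lcm // g > 1:
                f = (lcm // g, 1) if ax == 0 else (1, lcm // g)
                grid = avg_pool2d(grid, f)
        n, d, gh2, gw2 = grid.shape
        return grid.reshape(1, d, gh2 * gw2).transpose(0, 2, 1)

    def forward(self, x) -> EncoderOutput:
        x = ad.as_tensor(x)
        _check_input(x)
        p = self.cfg.patch_size
        s = avg_pool2d(self.stem(x), 2)                 # (N, 64, H/2, W/2)
        n, ch, hs, ws = s.shape
        gh, gw = hs // p, ws // p

        v = self.vit_pre(s)                             # (N, 96, H/2, W/2)
        patches = v.reshape(n, 96, gh, p, gw, p)
        patches = patches.transpose(0, 2, 4, 1, 3, 5).reshape(n, gh * gw, 96 * p * p)
        tokens = self.patch_embed(patches) + self._resize_pos(gh, gw, v.dtype)
        tokens = self.pos_drop(tokens)
        c = s
        for stage in range(self.cfg.n_interaction_stacks):
            if stage > 0:
                tokens = tokens + self.interact_detail_to_base(c, stage)
                c = c + self.interact_base_to_detail(tokens_prev, (gh, gw), stage)
            tokens_prev = tokens
            tokens = self.vit_stacks[stage](tokens)
            c = self.cnn_stacks[stage](c)

        grid = tokens.transpose(0, 2, 1).reshape(n, self.cfg.vit_dim, gh, gw)
        base = self.vit_restore(grid)                   # (N, 64, H, W)
        detail = self.cnn_restore(c)                    # (N, 64, H, W)
        return EncoderOutput(base=base, detail=detail)


class BaseFusionBlock(Module):
    """Lite-transformer base fusion: a convolutional (GLU-gated) head group
    for local context and an attention head group for long range, pooled to
    an 8x-coarser token grid, concatenated and projected with a residual."""

    POOL = 8

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        ch = cfg.feature_channels
        half = ch // 2
        self.split = half
        self.local_glu = Conv2d(half, ch, 3)      # -> gate + value
        self.local_out = Conv2d(half, half, 3)
        self.attn = MultiHeadSelfAttention(half, cfg.n_heads, drop=0.0)
        self.attn_norm = LayerNorm(half)
        self.proj = Conv2d(ch, ch, 1)

    def forward(self, base_sum: Tensor) -> Tensor:
        x = ad.as_tensor(base_sum)
        n, ch, h, w = x.shape
        half = self.split
        xl, xg = x[:, :half], x[:, half:]
        # local head group: GLU-gated convolution
        gv = self.local_glu(xl)
        loc = self.local_out(gv[:, :half] * gv[:, half:].sigmoid())
        # long-range head group: attention over the pooled token grid
        pool = avg_pool2d(xg, self.POOL)
        gh, gw = pool.shape[2], pool.shape[3]
        tok = pool.reshape(n, half, gh * gw).transpose(0, 2, 1)
        tok = self.attn(self.attn_norm(tok))
        glob = tok.transpose(0, 2, 1).reshape(n, half, gh, gw)
        glob = upsample_bilinear(glob, self.POOL)
        return x + self.proj(concat([loc, glob], axis=1))


class DetailFusionBlock(Module):
    """Residual fusion CNN: conv/BN cells with an ELU between them, a
    convolutional residual line, and a closing ReLU6 bounding outputs to
    [0, 6]."""

    def __init__(self, cfg: ModelConfig, use_residual: bool = True):
        super().__init__()
        ch = cfg.feature_channels
        self.use_residual = use_residual
        self.cell1 = Sequential(Conv2d(ch, ch, 3), BatchNorm2d(ch),
                                Conv2d(ch, ch, 3), BatchNorm2d(ch))
        self.cell2 = Sequential(Conv2d(ch, ch, 3), BatchNorm2d(ch),
                                Conv2d(ch, ch, 3), BatchNorm2d(ch))
        self.residual = Sequential(Conv2d(ch, ch, 3), BatchNorm2d(ch))

    def forward(self, detail_sum: Tensor) -> Tensor:
        x = ad.as_tensor(detail_sum)
        y = self.cell2(self.cell1(x).elu())
        if self.use_residual:
            y = y + self.residual(x)
        return y.relu6()


class _ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of an NCHW map."""

    def __init__(self, ch):
        super().__init__()
        self.norm = LayerNorm(ch)

    def forward(self, x):
        return self.norm(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)


class _MDTA(Module):
    """Multi-dconv-head transposed attention: attention across channels,
    linear in the number of pixels."""

    def __init__(self, ch, n_heads):
        super().__init__()
        self.n_heads = n_heads
        self.qkv = Conv2d(ch, 3 * ch, 1)
        self.qkv_d = DepthwiseConv2d(3 * ch)  # per-channel spatial mixing
        self.out = Conv2d(ch, ch, 1)
        self.temperature = Tensor(np.ones((n_heads, 1, 1), dtype=np.float32),
                                  requires_grad=True)

    def forward(self, x):
        n, ch, h, w = x.shape
        hd = ch // self.n_heads
        qkv = self.qkv_d(self.qkv(x)).reshape(n, 3, self.n_heads, hd, h * w)
        q, k, v = qkv[:, 0], qkv[:, 1], qkv[:, 2]  # (n, heads, hd, HW)
        qn = q / ((q * q).sum(axis=-1, keepdims=True) + 1e-8).sqrt()
        kn = k / ((k * k).sum(axis=-1, keepdims=True) + 1e-8).sqrt()
        attn = ad.softmax((qn @ kn.transpose(0, 1, 3, 2)) * self.temperature, axis=-1)
        out = (attn @ v).reshape(n, ch, h, w)
        return self.out(out)


class _GDFN(Module):
    """Gated depthwise-conv feed-forward."""

    def __init__(self, ch, expansion=2):
        super().__init__()
        hidden = ch * expansion
        self.inp = Conv2d(ch, 2 * hidden, 1)
        self.dconv = DepthwiseConv2d(2 * hidden)
        self.out = Conv2d(hidden, ch, 1)
        self.hidden = hidden

    def forward(self, x):
        y = self.dconv(self.inp(x))
        return self.out(y[:, :self.hidden].gelu() * y[:, self.hidden:])


class _RestormerBlock(Module):
    def __init__(self, ch, n_heads):
        super().__init__()
        self.norm1 = _ChannelLayerNorm(ch)
        self.attn = _MDTA(ch, n_heads)
        self.norm2 = _ChannelLayerNorm(ch)
        self.ffn = _GDFN(ch)

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.ffn(self.norm2(x))


class RestormerDecoder(Module):
    """Restormer-style decoder: 1x1 reduce, transformer blocks with
    channel attention, conv head with sigmoid -> image in [0, 1].

    Used with separate parameter sets as both the fusion decoder (DFD) and
    the reconstruction decoder (DRD).  ``n_calls`` counts forward passes.
    """

    def __init__(self, cfg: ModelConfig, in_ch: int | None = None):
        super().__init__()
        ch = cfg.feature_channels
        self.in_ch = in_ch if in_ch is not None else 2 * ch
        self.reduce = Conv2d(self.in_ch, ch, 1)
        self.blocks = [_RestormerBlock(ch, cfg.n_heads)
                       for _ in range(cfg.restormer_blocks)]
        self.head = Sequential(Conv2d(ch, 32, 3), Activation("relu"),
                               Conv2d(32, 1, 3))
        self.n_calls = 0

    def forward(self, features: Tensor) -> Tensor:
        x = ad.as_tensor(features)
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"decoder expects {self.in_ch} channels, got {x.shape[1]}")
        self.n_calls += 1
        y = self.reduce(x)
        for blk in self.blocks:
            y = blk(y)
        return self.head(y).sigmoid()


class FusionModel(Module):
    """The full coupled model: shared encoder, fusion blocks + fusion
    decoder, and a reconstruction decoder with its own parameters."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        self.encoder = PDEncoder(self.cfg)
        self.bfb = BaseFusionBlock(self.cfg)
        self.dfb = DetailFusionBlock(self.cfg)
        self.dfd = RestormerDecoder(self.cfg)
        self.drd = RestormerDecoder(self.cfg)

    # -- fusion path ------------------------------------------------------
    def forward_fusion(self, t1: Tensor, t2: Tensor) -> Tensor:
        """Training-time fusion forward (keeps the graph)."""
        e1 = self.encoder(t1)
        e2 = self.encoder(t2)
        psi_b = self.bfb(e1.base + e2.base)
        psi_d = self.dfb(e1.detail + e2.detail)
        return self.dfd(concat([psi_b, psi_d], axis=1))

    def fuse(self, t1, t2) -> np.ndarray:
        """Inference entry point: eval mode, no gradient graph, and the
        reconstruction branch is never executed.

        The batch is processed one sample at a time: in eval mode every
        normalisation is per-sample or running-statistics based, so the
        result is identical to a batched forward while the peak memory of
        the full-resolution decoder stays flat in N.
        """
        was_training = self.training
        self.eval()
        t1, t2 = ad.as_tensor(t1), ad.as_tensor(t2)
        try:
            with no_grad():
                outs = [
                    self.forward_fusion(t1[i:i + 1], t2[i:i + 1]).data
                    for i in range(t1.shape[0])
                ]
        finally:
            self.train(was_training)
        return np.concatenate(outs, axis=0)

    # -- reconstruction path ----------------------------------------------
    def forward_reconstruction(self, tk: Tensor) -> Tensor:
        e = self.encoder(tk)
        return self.drd(concat([e.base, e.detail], axis=1))

    def reconstruct(self, tk, mask_ratio: float = 0.0, seed: int = 0) -> Tensor:
        """Per-modality reconstruction through the shared encoder; patch
        masking is applied to the input when mask_ratio > 0."""
        tk = ad.as_tensor(tk)
        if mask_ratio > 0:
            masked = np.stack([
                random_mask(tk.data[i, 0], mask_ratio, seed=seed + i)
                for i in range(tk.shape[0])
            ])[:, None].astype(tk.dtype)
            tk = Tensor(masked)
        return self.forward_reconstruction(tk)


# -- checkpointing --------------------------------------------------------

def save_model(model: FusionModel, path) -> None:
    state = {k: np.asarray(v) for k, v in model.state_dict().items()}
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_model(path) -> FusionModel:
    with np.load(path) as npz:
        cfg = ModelConfig(**json.loads(bytes(npz["__config__"]).decode()))
        model = FusionModel(cfg)
        model.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
    return model
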