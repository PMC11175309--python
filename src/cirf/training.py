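"""Coupled multi-task training and the inference entry point.

Every training step runs BOTH branches through the shared encoder: the
fusion branch on the original pair (unsupervised fusion loss) and the
reconstruction branch on the (optionally patch-masked) inputs
(supervised reconstruction loss), combined as
``total = (1 - sigma) * loss1 + sigma * loss2`` and optimised jointly
with one Adam optimiser over all parameters.

Everything is seeded: parameter init, data order, masking and dropout
derive from ``TrainConfig.seed``, so two identical runs produce
bit-identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, manual_seed
from ._autodiff.optim import Adam
from .data import ImagePair, yuv_to_rgb
from .losses import (
    LossWeights,
    fusion_loss,
    rec_loss,
    total_loss,
    total_rec_loss,
)
from .network import FusionModel, ModelConfig

__all__ = ["TrainConfig", "LossBreakdown", "TrainLog", "train_step", "train", "infer"]


@dataclass
class TrainConfig:
    weights: LossWeights = field(default_factory=LossWeights)
    model: ModelConfig = field(default_factory=ModelConfig)
    batch_size: int = 4
    learning_rate: float = 1e-4
    n_epochs: int = 1
    n_steps: int | None = None   # when set, overrides n_epochs
    seed: int = 0
    image_size: int = 256

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    # hyper-parameter presets mirroring the per-dataset ablation optima
    @classmethod
    def atlas_like(cls, **kw):
        return cls(weights=LossWeights.atlas(), **kw)

    @classmethod
    def ixi_like(cls, **kw):
        return cls(weights=LossWeights.ixi(), **kw)

    @classmethod
    def rire_like(cls, **kw):
        return cls(weights=LossWeights.rire(), **kw)


@dataclass
class LossBreakdown:
    rec_1: float
    rec_2: float
    loss1: float
    l_mi: float
    l_scd: float
    l_ssim: float
    l_qabf: float
    loss2: float
    total: float

    def as_dict(self):
        return dict(self.__dict__)


@dataclass
class TrainLog:
    steps: list = field(default_factory=list)      # LossBreakdown per step
    epoch_means: list = field(default_factory=list)

    def append_epoch(self, first: int):
        chunk = self.steps[first:]
        if chunk:
            keys = chunk[0].as_dict().keys()
            self.epoch_means.append(
                {k: float(np.mean([getattr(s, k) for s in chunk])) for k in keys})


def _batch_tensor(pairs: list[ImagePair], which: str) -> Tensor:
    arrs = [getattr(p, which)[None] for p in pairs]
    return Tensor(np.stack(arrs).astype(np.float32))


_NAN_ORDER = ("rec_1", "rec_2", "l_mi", "l_scd", "l_ssim", "l_qabf")


def train_step(batch: list[ImagePair], model: FusionModel, opt: Adam,
               cfg: TrainConfig, mask_seed: int = 0) -> LossBreakdown:
    """One coupled step: both branches forward, one Adam update."""
    w = cfg.weights
    t1 = _batch_tensor(batch, "a")
    t2 = _batch_tensor(batch, "b")
    opt.zero_grad()

    fused = model.forward_fusion(t1, t2)
    r1 = model.reconstruct(t1, w.mask_ratio, seed=mask_seed)
    r2 = model.reconstruct(t2, w.mask_ratio, seed=mask_seed + 10007)

    rl1 = rec_loss(r1, t1, w)
    rl2 = rec_loss(r2, t2, w)
    loss1 = total_rec_loss(rl1, rl2, w)
    loss2, terms = fusion_loss(t1, t2, fused, w)
    total = total_loss(loss1, loss2, w)

    scalars = {
        "rec_1": float(rl1.data), "rec_2": float(rl2.data),
        "l_mi": float(terms["l_mi"].data), "l_scd": float(terms["l_scd"].data),
        "l_ssim": float(terms["l_ssim"].data), "l_qabf": float(terms["l_qabf"].data),
    }
    for name in _NAN_ORDER:
        if not np.isfinite(scalars[name]):
            raise FloatingPointError(f"non-finite loss term: {name}")

    total.backward()
    opt.step()

    l1 = float(w.mu) * (scalars["rec_1"] + scalars["rec_2"])
    l2 = float(loss2.data)
    return LossBreakdown(
        rec_1=scalars["rec_1"], rec_2=scalars["rec_2"], loss1=l1,
        l_mi=scalars["l_mi"], l_scd=scalars["l_scd"],
        l_ssim=scalars["l_ssim"], l_qabf=scalars["l_qabf"], loss2=l2,
        total=(1.0 - float(w.sigma)) * l1 + float(w.sigma) * l2,
    )


def train(dataset: list[ImagePair], cfg: TrainConfig,
          callback=None) -> tuple[FusionModel, TrainLog]:
    """Train a fresh model on a dataset of pairs.

    Deterministic given ``cfg.seed``: the seed drives parameter init,
    epoch shuffling, dropout and the reconstruction-branch masking.
    ``callback(step_index, breakdown)`` is invoked after every step.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    manual_seed(cfg.seed)
    model = FusionModel(cfg.model)
    model.train()
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(cfg.seed + 1)
    log = TrainLog()

    n = len(dataset)
    bs = cfg.batch_size
    step_idx = 0
    done = False
    epoch = 0
    while not done:
        first = len(log.steps)
        perm = order_rng.permutation(n)
        for lo in range(0, n, bs):
            batch = [dataset[i] for i in perm[lo:lo + bs]]
            bd = train_step(batch, model, opt, cfg, mask_seed=cfg.seed + 31 * step_idx)
            log.steps.append(bd)
            if callback is not None:
                callback(step_idx, bd)
            step_idx += 1
            if cfg.n_steps is not None and step_idx >= cfg.n_steps:
                done = True
                break
        log.append_epoch(first)
        epoch += 1
        if cfg.n_steps is None and epoch >= cfg.n_epochs:
            done = True
    model.eval()
    return model, log


def infer(dataset: list[ImagePair], model: FusionModel) -> list[np.ndarray]:
    """Fusion-branch-only inference.  Pseudo-colour pairs are fused on the
    Y channel and re-stitched with the original U/V planes (RGB output);
    grayscale pairs return grayscale."""
    model.eval()
    outputs = []
    for p in dataset:
        fused = model.fuse(p.a[None, None].astype(np.float32),
                           p.b[None, None].astype(np.float32))[0, 0]
        fused = np.clip(fused.astype(np.float64), 0.0, 1.0)
        if p.color_b is not None:
            from .data import rgb_to_yuv
            _, u, v = rgb_to_yuv(p.color_b)
            outputs.append(yuv_to_rgb(fused, u, v))
        else:
            outputs.append(fused)
    return outputs
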