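"""Train the coupled model briefly at desk scale and fuse a held-out pair.

Runs 30 coupled steps (both branches through the shared encoder) on eight
synthetic 64x64 pairs with the desk-scale model preset, then compares the
total loss at the start and end and scores the fusion of an unseen pair.
Expect the run to take a few minutes on one CPU; losses should drop
noticeably even this early in training.
"""

import numpy as np

from cirf import (
    LossWeights,
    ModelConfig,
    TrainConfig,
    evaluate_all,
    synth_dataset,
    train,
)
from cirf.training import infer

pairs = synth_dataset(8, seed=0, size=64)
held = synth_dataset(1, seed=99, size=64)

cfg = TrainConfig(
    weights=LossWeights.atlas(),          # lambda=0.3, sigma=0.2, mask 0.1
    model=ModelConfig.small(image_size=64),
    batch_size=1, learning_rate=3e-4, n_steps=30, seed=0, image_size=64,
)
model, log = train(pairs, cfg)

first, last = log.steps[0], log.steps[-1]
print(f"total loss: step 0 = {first.total:.3f}, step 29 = {last.total:.3f}")
print(f"  reconstruction part (loss1): {first.loss1:.3f} -> {last.loss1:.3f}")
print(f"  fusion part (loss2):         {first.loss2:.3f} -> {last.loss2:.3f}")

fused = infer(held, model)[0]
rep = evaluate_all(held[0].a, held[0].b, fused)
print(f"held-out fusion: ssim {rep.ssim:.3f}  qabf {rep.qabf:.3f}  "
      f"scd {rep.scd:.3f}  rsfe {rep.rsfe:+.3f}")
print("The falling total shows both branches learning through the one "
      "shared encoder; the metric row scores the unseen fusion.")
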