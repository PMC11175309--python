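# Methods

## The model

`cirf` fuses two co-registered 2-D medical images (MR/CT grayscale, or a
pseudo-colour SPECT/PET rendering paired with a grayscale scan) into one
image that retains the complementary content of both. The design couples
two tasks through one encoder:

* **Fusion branch** (the product): a Parallel Decomposition Encoder (PDE)
  splits each input `T_k` into *base* features `Phi_k^B` (low-frequency
  structure and contrast, from a ViT branch) and *detail* features
  `Phi_k^D` (edges and texture, from a CNN branch), both `(N, 64, H, W)`.
  Base features of the two modalities are summed and fused by a
  lite-transformer Base Fusion Block (local GLU-gated convolution head
  group + long-range attention head group over a pooled token grid);
  detail features are summed and fused by a residual fusion CNN (two
  conv/BN cells with an ELU between, a convolutional residual line, and a
  closing ReLU6 that bounds activations to [0, 6]). The concatenated
  fused features are decoded by a Restormer-style decoder (channel-wise
  transposed attention + gated depthwise-conv feed-forward, sigmoid head)
  into the fused image `T_f` in [0, 1].
* **Reconstruction branch** (training scaffold): each modality — original
  or with a fraction of 16 x 16 patches zeroed (masked-image-modeling
  style) — passes through the *same* encoder and a second Restormer
  decoder with its own parameters, reconstructing its input. At inference
  this branch is cut; only the fusion path executes.

Both branches are optimised *simultaneously* with one Adam optimiser:

```
L_rec,k = MSE + alpha * (1 - SSIM) + beta * SG,   k = 1, 2
loss1   = mu * (L_rec,1 + L_rec,2)
loss2   = lambda * (L_MI + L_SCD) + (1 - lambda) * (L_SSIM + L_QABF)
total   = (1 - sigma) * loss1 + sigma * loss2
```

where SG is the mean absolute difference of Sobel gradient magnitudes
(replicate-padded, so constants have zero gradient and the loss is
offset-invariant), and each fusion term is one minus the normalised
average of a fusion metric over the two (source, fused) pairs.

### Loss normalisations and surrogates

The fusion metrics live on different scales, so each term is mapped into
[0, 1] before the lambda-weighting:

* SSIM and the two SCD Pearson correlations: `(x + 1) / 2`, then averaged;
* QAB/F is already in [0, 1];
* MI is normalised per source by the symmetric uncertainty
  `2 I(S;F) / (H(S) + H(F))`.

Training needs differentiable versions: MI uses soft joint histograms
(triangular kernel, 32 bins, bandwidth 1/32); QAB/F replaces absolute
values and min/max with smooth counterparts (eps = 1e-6) but keeps the
published sigmoid constants; SCD and SSIM are natively smooth. The
evaluation-grade metrics module keeps the exact, non-surrogate
definitions, and the tests assert that the surrogates track them
(QAB/F within 0.05 on random triples; SSIM to 1e-6 against the standard
implementation).

## The evaluation metrics

Eight metrics score a fused image `F` against sources `A`, `B`; intensity
metrics use the 8-bit scale (x255):

| metric | definition used here |
|---|---|
| SD | population standard deviation of F |
| PSNR | `10 log10(255^2 / mean(MSE(A,F), MSE(B,F)))`, +inf at zero error |
| SCD | `r(F-B, A) + r(F-A, B)` (Pearson; zero-variance term = 0) |
| MI | `I(A;F) + I(B;F)`, 256-bin joint histograms, log2 |
| SSIM | mean of SSIM(A,F), SSIM(B,F); Gaussian 11x11, K1=.01, K2=.03, L=255 |
| QAB/F | Sobel strength/orientation preservation, sigmoid-mapped, edge-strength weighted |
| VIFF | 4-scale pixel-domain visual information fidelity, noise variance 2 |
| rSFe | `(SF_f - SF_r)/SF_r` from four directional differences (diagonals weighted 1/sqrt 2), reference = element-wise max of source differences |

Two definition choices deserve emphasis:

* **QAB/F normalisation.** The classical sigmoid constants
  (Gamma_g=0.9994, k_g=-15, delta_g=0.5; Gamma_a=0.9879, k_a=-22,
  delta_a=0.8) give ~0.975 at perfect edge preservation. Here each
  sigmoid response is divided by its value at perfect preservation, so
  that `QAB/F(A, B, F=A=B) = 1` exactly while preserving the constants'
  shape. All reported values use this normalised form.
* **VIFF combination.** Per scale, the fused fidelity is
  `(VID_A + VID_B) / (VIND_A + VIND_B)` (visual information of the
  distorted/reference channels summed over both sources), and the four
  scales are averaged. This makes the identity value exactly 1 and is
  monotone under blur and additive noise. On images smaller than a
  scale's window the remaining scales are skipped (at 32 x 32 two scales
  survive; from 64 x 64 all four).

Other conventions: MI bins are equal-width on the 8-bit scale; degenerate
Pearson terms in SCD are defined as 0; constant-source QAB/F returns 0
with a warning; rSFe raises on two constant sources (the reference
frequency is zero).

## The synthetic phantom generator

`synth_pair(seed, size, profile)` emulates what the method needs from
paired modalities: shared latent anatomy with complementary frequency
emphasis. It draws 4-7 soft super-Gaussian ellipses (flat core, smooth
rim) over a smooth random background; modality A is a Gaussian-smoothed
tissue-contrast rendering (low-frequency rich), modality B combines the
same anatomy with its Sobel edge map and band-pass texture inside the
structures (high-frequency rich). The `pseudo-color` profile wraps B in
an analytic hot colormap and exposes its BT.601 Y channel as the fusion
input. Across seeds the pair correlates at r >= 0.3 (shared anatomy) and
B carries the larger mean gradient magnitude; both properties are
asserted in tests.

What the phantoms do *not* model: scanner noise statistics, intensity
inhomogeneity, partial-volume effects, misregistration, or anatomical
variability of real MR/CT/SPECT data. Passing tests therefore show that
the architecture, losses and metrics behave as specified and that
training converges on controlled inputs - not that the trained weights
transfer to clinical images.

## Numerical and engineering choices

* **Compute backend.** The networks and losses run on a small
  reverse-mode automatic-differentiation engine over numpy arrays
  (`cirf._autodiff`): broadcast arithmetic, matmul, stride-1 convolution
  (im2col GEMM, with a shift-and-GEMM fallback for very large maps),
  2x2-stride-2 transposed convolution, depthwise convolution, average
  pooling, bilinear upsampling, layer/batch norm, softmax attention and
  seeded dropout. Every spatial primitive is verified against central
  differences in the test suite.
* **Precision.** Parameters are float32; operations follow the input
  dtype, so float64 inputs give float64 graphs (used by the
  gradient-check tests). Scalar weights stay python floats to avoid
  silent upcasting.
* **Colour.** Analog BT.601 YUV (Y = 0.299R + 0.587G + 0.114B); only Y is
  fused, U/V pass through and are re-attached, then RGB is clipped.
* **Masking.** Patch-wise (16 x 16), fill value 0, count =
  `round(ratio * n_patches)`; deterministic per seed.
* **Encoder geometry.** Stem: 7x7 conv (1->32), 3x3 conv (->64), 2x2
  average pool. The ViT branch applies an extra 3x3 conv (64->96), 8x8
  patch embedding to 128-dim tokens (4 heads, depth 6 split across the
  i=2 interaction stacks, dropout 0.10, learned positional embeddings
  resized between grids via integer up/downsampling through the LCM),
  and restores resolution with four 2x2 transposed convolutions. The CNN
  branch runs conv/BN/ELU stacks at half resolution and restores with
  one transposed convolution. Input sides must be divisible by 32.
* **Interaction.** Detail -> base: average-pool to the token grid,
  layer-normalise the per-cell channel vectors, linear-project into the
  token width, add. Base -> detail: linear-project tokens to 64
  channels, reshape to the grid, bilinear-upsample to the CNN
  resolution, batch-normalise, add.
* **Weighting defaults.** alpha = beta = mu = 1 (the balance weights are
  otherwise unconstrained; exposed in config), lambda = 0.3 throughout;
  presets: atlas-like (sigma 0.2, mask 0.1), ixi-like (sigma 0.2, mask
  0), rire-like (sigma 0.4, mask 0).
* **Optimiser.** Adam (beta1 0.9, beta2 0.999), default lr 1e-4, no
  schedule; one optimiser over all parameters of both branches.

## Desk-scale preset and problem sizes

CPU-scale work uses `ModelConfig.small()`: ViT depth 2, token width 64,
one Restormer block per decoder, the 64-channel feature contract
unchanged. The smoke-training check runs 200 Adam steps at batch 1 and
lr 3e-4 on 32 synthetic 64 x 64 pairs with the atlas-like weights; at
lr 1e-3 the sigmoid output head saturates to a near-binary anatomy mask
within 200 steps (the information terms reward contrast faster than the
edge term can shape it, and saturated logits stop the QAB/F gradient),
so 3e-4 is the desk-scale default. Architecture contracts are exercised
at the full working configuration (256 x 256, batch 4, ViT depth 6).

## Known limitations

* 2-D only; no DICOM/NIfTI readers and no registration - inputs are
  assumed co-registered, PNG/TIFF.
* The engine is single-threaded numpy; training beyond desk scale is not
  its purpose.
* Batch statistics: MI/SCD surrogates pool all pixels of a batch rather
  than averaging per-image values (identical at batch 1; slightly
  different otherwise).
* The VIFF scale combination follows the documented construction above;
  published VIFF implementations differ in block weighting, so absolute
  VIFF values should be compared only within this package.
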