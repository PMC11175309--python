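"""Differentiable training losses.

Two loss families drive the coupled training:

* the supervised reconstruction loss per source k,
  ``L_rec,k = L_MSE + alpha * (1 - SSIM) + beta * L_SG``, where ``L_SG`` is
  the mean absolute difference between the Sobel gradient magnitudes of the
  reconstruction and its target; the branch total is
  ``loss1 = mu * (L_rec,1 + L_rec,2)``;
* the unsupervised fusion loss built from differentiable surrogates of four
  fusion metrics, ``loss2 = lam*(L_MI + L_SCD) + (1-lam)*(L_SSIM + L_QABF)``,
  each term being one minus the normalised average of the metric over the
  two (source, fused) pairs;

combined as ``total = (1-sigma)*loss1 + sigma*loss2``.

Normalisations (each term lands in [0, 1]):

* SSIM and the Pearson correlations of SCD are mapped from [-1, 1] with
  (x+1)/2 before averaging;
* QAB/F is already in [0, 1];
* MI is normalised per source by the symmetric uncertainty
  2*I(S;F) / (H(S) + H(F)).

Differentiable surrogates: MI uses soft (triangular-kernel) joint
histograms with 32 bins; QAB/F replaces hard absolute values and min/max
with smooth counterparts (eps = 1e-6); SCD and SSIM are natively smooth.
The evaluation-grade definitions live in :mod:`cirf.metrics`; tests assert
surrogate/exact agreement.

Inputs are numpy arrays or Tensors shaped ``(H, W)``, ``(N, H, W)`` or
``(N, 1, H, W)`` with intensities in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor, concat, depthwise_conv2d

__all__ = [
    "LossWeights",
    "loss_sg",
    "mse_loss",
    "ssim_index",
    "rec_loss",
    "total_rec_loss",
    "fusion_loss",
    "total_loss",
    "differentiability_check",
    "soft_pearson",
    "soft_symmetric_uncertainty",
    "soft_qabf",
]


@dataclass
class LossWeights:
    """The scalar hyper-parameters of the loss (all dimensionless).

    alpha, beta weight the SSIM and gradient terms of the reconstruction
    loss; mu balances the magnitude of the reconstruction branch total;
    lam trades information terms (MI, SCD) against structural terms
    (SSIM, QAB/F) in the fusion loss; sigma trades reconstruction against
    fusion in the total; mask_ratio is the fraction of image patches
    blanked before the reconstruction branch's encoder pass.
    """

    alpha: float = 1.0
    beta: float = 1.0
    mu: float = 1.0
    lam: float = 0.3
    sigma: float = 0.2
    mask_ratio: float = 0.1

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        for name in ("lam", "sigma", "mask_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def atlas(cls):
        return cls(lam=0.3, sigma=0.2, mask_ratio=0.1)

    @classmethod
    def ixi(cls):
        return cls(lam=0.3, sigma=0.2, mask_ratio=0.0)

    @classmethod
    def rire(cls):
        return cls(lam=0.3, sigma=0.4, mask_ratio=0.0)


# -- plumbing -------------------------------------------------------------

def _as_batch(x) -> Tensor:
    """-> (N, 1, H, W) tensor."""
    x = as_tensor(x)
    if x.ndim == 2:
        return x.reshape(1, 1, *x.shape)
    if x.ndim == 3:
        return x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
    if x.ndim == 4:
        return x
    raise ValueError(f"unsupported image batch shape {x.shape}")


def _pair(x, y):
    xb, yb = _as_batch(x), _as_batch(y)
    if xb.shape != yb.shape:
        raise ValueError(f"shape mismatch: {xb.shape} vs {yb.shape}")
    return xb, yb


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)


def _edge_pad1(x: Tensor) -> Tensor:
    """Replicate-pad an NCHW tensor by one pixel (differentiable)."""
    x = concat([x[:, :, :1, :], x, x[:, :, -1:, :]], axis=2)
    return concat([x[:, :, :, :1], x, x[:, :, :, -1:]], axis=3)


def _sobel_mag(x: Tensor, eps: float = 1e-12) -> Tensor:
    # edge padding: constant images have zero gradient magnitude everywhere
    kx = Tensor(_SOBEL_X.astype(x.dtype)[None])
    ky = Tensor(_SOBEL_X.T.astype(x.dtype)[None])
    xp = _edge_pad1(x)
    gx = depthwise_conv2d(xp, kx)
    gy = depthwise_conv2d(xp, ky)
    return (gx * gx + gy * gy + eps).sqrt()


def _gauss_kernel(n: int, sigma: float, dtype) -> np.ndarray:
    ax = np.arange(n) - (n - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return (k / k.sum()).astype(dtype)


# -- reconstruction losses ------------------------------------------------

def mse_loss(recon, target) -> Tensor:
    r, t = _pair(recon, target)
    d = r - t
    return (d * d).mean()


def loss_sg(recon, target) -> Tensor:
    """Spatial-gradient loss: mean | |grad recon| - |grad target| | with a
    Sobel gradient magnitude; invariant to constant offsets."""
    r, t = _pair(recon, target)
    return (_sobel_mag(r) - _sobel_mag(t)).smooth_abs(1e-24).mean()


def ssim_index(x, y, win: int = 11, sigma: float = 1.5,
               k1: float = 0.01, k2: float = 0.03) -> Tensor:
    """Differentiable mean SSIM on the [0,1] scale (Gaussian window,
    valid positions only).  Scale-invariant w.r.t. the 8-bit convention
    because the stabilisers scale with the dynamic range."""
    x, y = _pair(x, y)
    if x.shape[-1] < win or x.shape[-2] < win:
        raise ValueError(f"images must be at least {win}x{win} for SSIM")
    w = Tensor(_gauss_kernel(win, sigma, x.dtype)[None])
    c1, c2 = k1 ** 2, k2 ** 2
    mx = depthwise_conv2d(x, w)
    my = depthwise_conv2d(y, w)
    sxx = depthwise_conv2d(x * x, w) - mx * mx
    syy = depthwise_conv2d(y * y, w) - my * my
    sxy = depthwise_conv2d(x * y, w) - mx * my
    num = (mx * my * 2.0 + c1) * (sxy * 2.0 + c2)
    den = (mx * mx + my * my + c1) * (sxx + syy + c2)
    return (num / den).mean()


def rec_loss(recon, target, w: LossWeights) -> Tensor:
    """Per-source reconstruction loss: MSE + alpha*(1 - SSIM) + beta*SG."""
    out = mse_loss(recon, target)
    if w.alpha:
        out = out + w.alpha * (1.0 - ssim_index(recon, target))
    if w.beta:
        out = out + w.beta * loss_sg(recon, target)
    return out


def total_rec_loss(rec_1, rec_2, w: LossWeights):
    """Reconstruction-branch total: mu * (L_rec,1 + L_rec,2)."""
    return w.mu * (rec_1 + rec_2)


# -- fusion-loss surrogates -----------------------------------------------

def soft_pearson(x: Tensor, y: Tensor) -> Tensor:
    """Pearson correlation over all pixels of a batch, eps-guarded."""
    xc = x - x.mean()
    yc = y - y.mean()
    num = (xc * yc).sum()
    den = ((xc * xc).sum() * (yc * yc).sum() + 1e-12).sqrt()
    return num / (den + 1e-12)


def _soft_marginal(x: Tensor, n_bins: int) -> Tensor:
    """Triangular-kernel soft histogram weights, (P, n_bins)."""
    centers = ((np.arange(n_bins) + 0.5) / n_bins).astype(x.dtype)
    d = x.reshape(x.size, 1) - Tensor(centers[None, :])
    return (1.0 - d.smooth_abs(1e-24) * float(n_bins)).relu()


def soft_symmetric_uncertainty(x: Tensor, y: Tensor, n_bins: int = 32) -> Tensor:
    """2*I(X;Y)/(H(X)+H(Y)) from soft joint histograms; in [0, 1]."""
    eps = 1e-12
    wx = _soft_marginal(x, n_bins)
    wy = _soft_marginal(y, n_bins)
    n = float(wx.shape[0])
    joint = wx.transpose(1, 0) @ wy * (1.0 / n)
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mi = (joint * ((joint + eps) / (px @ py + eps)).log()).sum()
    hx = -(px * (px + eps).log()).sum()
    hy = -(py * (py + eps).log()).sum()
    return (2.0 * mi) / (hx + hy + eps)


def soft_qabf(a: Tensor, b: Tensor, f: Tensor, eps: float = 1e-6) -> Tensor:
    """Smooth edge-preservation surrogate mirroring metrics.qabf."""
    from .metrics import QABF_CONSTANTS as c

    def strength_orientation(x):
        kx = Tensor(_SOBEL_X.astype(x.dtype)[None])
        ky = Tensor(_SOBEL_X.T.astype(x.dtype)[None])
        gx = depthwise_conv2d(x, kx, padding=1)
        gy = depthwise_conv2d(x, ky, padding=1)
        g = (gx * gx + gy * gy + eps * eps).sqrt()
        # sign-preserving guard keeps arctan(gy/gx) near +-pi/2 at gx ~ 0
        sgn = np.where(gx.data >= 0, 1.0, -1.0).astype(x.dtype)
        alpha = (gy / (gx + Tensor(sgn) * 1e-8)).arctan()
        return g, alpha

    def sigmoid_pres(x, gamma, k, delta):
        perfect = gamma / (1.0 + np.exp(k * (1.0 - delta)))
        return (gamma / ((((x - delta) * k).exp()) + 1.0)) * (1.0 / perfect)

    ga, ala = strength_orientation(a)
    gb, alb = strength_orientation(b)
    gf, alf = strength_orientation(f)

    def q_pair(gs, als):
        d = gs - gf
        s = (d * d + eps).sqrt()
        mn = (gs + gf - s) * 0.5
        mx = (gs + gf + s) * 0.5
        G = (mn + eps) / (mx + eps)
        A = 1.0 - (als - alf).smooth_abs(eps * eps) * (2.0 / np.pi)
        qg = sigmoid_pres(G, c["gamma_g"], c["k_g"], c["delta_g"])
        qa = sigmoid_pres(A, c["gamma_a"], c["k_a"], c["delta_a"])
        return qg * qa

    num = (q_pair(ga, ala) * ga + q_pair(gb, alb) * gb).sum()
    den = (ga + gb).sum()
    return num / (den + 1e-12)


def _clamp01(x: Tensor) -> Tensor:
    return 1.0 - (1.0 - x.relu()).relu()


def fusion_loss(a, b, f, w: LossWeights):
    """Unsupervised fusion loss.

    Returns ``(loss2, terms)`` where terms is a dict of the four components
    ``l_mi, l_scd, l_ssim, l_qabf`` (each a scalar Tensor in [0, 1]) and
    ``loss2 = lam*(l_mi + l_scd) + (1-lam)*(l_ssim + l_qabf)``.
    """
    ab, bb = _pair(a, b)
    fb = _as_batch(f)
    if fb.shape != ab.shape:
        raise ValueError("fused batch shape mismatch")
    lam = float(w.lam)

    su = soft_symmetric_uncertainty(ab, fb) + soft_symmetric_uncertainty(bb, fb)
    l_mi = _clamp01(1.0 - su * 0.5)

    r1 = soft_pearson(fb - bb, ab)
    r2 = soft_pearson(fb - ab, bb)
    l_scd = _clamp01(1.0 - ((r1 + 1.0) * 0.5 + (r2 + 1.0) * 0.5) * 0.5)

    s = ssim_index(ab, fb) + ssim_index(bb, fb)
    l_ssim = _clamp01(1.0 - ((s * 0.5) + 1.0) * 0.5)

    l_qabf = _clamp01(1.0 - soft_qabf(ab, bb, fb))

    loss2 = lam * (l_mi + l_scd) + (1.0 - lam) * (l_ssim + l_qabf)
    terms = {"l_mi": l_mi, "l_scd": l_scd, "l_ssim": l_ssim, "l_qabf": l_qabf}
    return loss2, terms


def total_loss(loss1, loss2, w: LossWeights):
    """(1 - sigma) * loss1 + sigma * loss2."""
    s = float(w.sigma)
    return (1.0 - s) * loss1 + s * loss2


# -- diagnostics ----------------------------------------------------------

def differentiability_check(loss_fn, *arrays, wrt: int = 0) -> dict:
    """Evaluate ``loss_fn(*tensors)`` with gradient tracking and report the
    gradient health with respect to argument ``wrt``."""
    tensors = []
    for i, arr in enumerate(arrays):
        tensors.append(Tensor(np.asarray(arr, dtype=np.float64),
                              requires_grad=(i == wrt)))
    out = loss_fn(*tensors)
    if isinstance(out, tuple):
        out = out[0]
    out.backward()
    g = tensors[wrt].grad
    finite = g is not None and np.isfinite(g).all()
    return {
        "ok": bool(finite and np.abs(g).max() > 0),
        "finite": bool(finite),
        "max_abs_grad": float(np.abs(g).max()) if g is not None else float("nan"),
        "value": float(out.data),
    }
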