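"""Evaluation-grade fusion-quality metrics.

All eight metrics take the two co-registered sources A, B and the fused
image F as [0,1] float arrays (colour inputs are reduced to their BT.601
Y channel).  Quantities that depend on absolute intensity (SD, PSNR, MI,
SSIM) are evaluated on the 8-bit scale (x255, maximum intensity 255), the
convention of the fusion-metric literature.

Definitions
-----------
SD      population standard deviation of F (contrast).
PSNR    10*log10(255^2 / mean(MSE(A,F), MSE(B,F))); +inf at zero error.
SCD     Pearson r(F-B, A) + r(F-A, B); a zero-variance operand makes that
        term 0.  Range [-2, 2].
MI      I(A;F) + I(B;F) from 256-bin joint histograms, log base 2 (bits).
SSIM    mean of SSIM(A,F) and SSIM(B,F), Gaussian 11x11 window, K1=0.01,
        K2=0.03, L=255 (Wang et al. configuration).
QAB/F   Xydeas-Petrovic edge-information preservation: Sobel edge strength
        g and orientation alpha per pixel; sigmoid-mapped strength and
        orientation preservation, each normalised so that perfect
        preservation scores exactly 1; edge-strength-weighted average over
        both sources.  Range [0, 1].
VIFF    multi-scale (4 scales) pixel-domain visual information fidelity of
        F against each source under a Gaussian scale mixture model with
        noise variance 2; per scale the fused fidelity is
        (VID_A + VID_B) / (VIND_A + VIND_B), and scales are averaged.
        Equals 1 when F reproduces both sources exactly.
rSFe    relative spatial-frequency error: directional first differences
        (rows, columns, two diagonals weighted 1/sqrt(2)) of F versus the
        element-wise max-magnitude reference differences of A and B;
        (SF_f - SF_r)/SF_r.  0 is ideal; >0 injected noise, <0 lost detail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.metrics import structural_similarity

__all__ = [
    "MetricReport",
    "sd",
    "psnr",
    "scd",
    "mi",
    "ssim_fusion",
    "qabf",
    "viff",
    "rsfe",
    "evaluate_all",
    "QABF_CONSTANTS",
]

# Xydeas-Petrovic sigmoid constants (strength: Gamma_g, k_g, delta_g;
# orientation: Gamma_a, k_a, delta_a)
QABF_CONSTANTS = dict(gamma_g=0.9994, k_g=-15.0, delta_g=0.5,
                      gamma_a=0.9879, k_a=-22.0, delta_a=0.8)


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3 and img.shape[2] == 3:
        # BT.601 luma (same weights as data.rgb_to_yuv)
        img = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    return img


def _triple(a, b, f):
    a, b, f = _to_gray(a), _to_gray(b), _to_gray(f)
    if not (a.shape == b.shape == f.shape):
        raise ValueError("A, B and F must share a shape")
    return a, b, f


# -- intensity statistics -------------------------------------------------

def sd(f) -> float:
    """Population standard deviation of the fused image on the 8-bit scale."""
    return float(np.std(_to_gray(f) * 255.0))


def psnr(a, b, f) -> float:
    a, b, f = (x * 255.0 for x in _triple(a, b, f))
    mse = 0.5 * (np.mean((a - f) ** 2) + np.mean((b - f) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0 ** 2 / mse))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        return 0.0
    return float((xc * yc).sum() / den)


def scd(a, b, f) -> float:
    a, b, f = _triple(a, b, f)
    return _pearson(f - b, a) + _pearson(f - a, b)


# -- information ----------------------------------------------------------

def _quantize8(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.intp)


def _mi_pair(x: np.ndarray, y: np.ndarray) -> float:
    qx, qy = _quantize8(x), _quantize8(y)
    joint = np.bincount(qx.ravel() * 256 + qy.ravel(), minlength=256 * 256)
    joint = joint.reshape(256, 256) / qx.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(px, py)
    return float((joint[nz] * np.log2(joint[nz] / denom[nz])).sum())


def mi(a, b, f) -> float:
    a, b, f = _triple(a, b, f)
    return _mi_pair(a, f) + _mi_pair(b, f)


def ssim_fusion(a, b, f) -> float:
    a, b, f = _triple(a, b, f)
    if min(a.shape) < 11:
        raise ValueError("images must be at least 11x11 for the SSIM window")
    kw = dict(gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
              data_range=255.0)
    s1 = structural_similarity(a * 255.0, f * 255.0, **kw)
    s2 = structural_similarity(b * 255.0, f * 255.0, **kw)
    return float(0.5 * (s1 + s2))


# -- edge preservation ----------------------------------------------------

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


def _edge_strength_orientation(img: np.ndarray):
    gx = ndimage.correlate(img, _SOBEL_X, mode="constant")
    gy = ndimage.correlate(img, _SOBEL_Y, mode="constant")
    g = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.arctan(gy / gx)
    alpha = np.where(np.isnan(alpha), 0.0, alpha)  # gx = gy = 0
    return g, alpha


def _sigmoid_pres(x: np.ndarray, gamma: float, k: float, delta: float) -> np.ndarray:
    raw = gamma / (1.0 + np.exp(k * (x - delta)))
    perfect = gamma / (1.0 + np.exp(k * (1.0 - delta)))
    return raw / perfect


def _q_pair(gs, als, gf, alf):
    """Per-pixel preservation of one source's edges in F."""
    m = np.minimum(gs, gf)
    M = np.maximum(gs, gf)
    with np.errstate(invalid="ignore"):
        G = np.where(M > 0, m / np.where(M > 0, M, 1.0), 1.0)
    A = 1.0 - np.abs(als - alf) / (np.pi / 2.0)
    c = QABF_CONSTANTS
    qg = _sigmoid_pres(G, c["gamma_g"], c["k_g"], c["delta_g"])
    qa = _sigmoid_pres(A, c["gamma_a"], c["k_a"], c["delta_a"])
    return qg * qa


def qabf(a, b, f) -> float:
    a, b, f = _triple(a, b, f)
    if min(a.shape) < 3:
        raise ValueError("images must be at least 3x3")
    if a.max() == a.min() and b.max() == b.min():
        warnings.warn("QAB/F undefined for all-constant sources; returning 0")
        return 0.0
    ga, ala = _edge_strength_orientation(a)
    gb, alb = _edge_strength_orientation(b)
    gf, alf = _edge_strength_orientation(f)
    qaf = _q_pair(ga, ala, gf, alf)
    qbf = _q_pair(gb, alb, gf, alf)
    wsum = (ga + gb).sum()
    if wsum == 0:
        warnings.warn("QAB/F undefined for all-constant sources; returning 0")
        return 0.0
    return float(np.clip((qaf * ga + qbf * gb).sum() / wsum, 0.0, 1.0))


# -- visual information fidelity ------------------------------------------

_VIF_NOISE = 2.0
_VIF_EPS = 1e-10


def _gauss_win(n: int, sdv: float) -> np.ndarray:
    ax = np.arange(n) - (n - 1) / 2.0
    g1 = np.exp(-(ax ** 2) / (2.0 * sdv ** 2))
    win = np.outer(g1, g1)
    return win / win.sum()


def _vif_terms(ref: np.ndarray, dist: np.ndarray, win: np.ndarray):
    mu1 = fftconvolve(ref, win, mode="valid")
    mu2 = fftconvolve(dist, win, mode="valid")
    s11 = fftconvolve(ref * ref, win, mode="valid") - mu1 * mu1
    s22 = fftconvolve(dist * dist, win, mode="valid") - mu2 * mu2
    s12 = fftconvolve(ref * dist, win, mode="valid") - mu1 * mu2
    s11 = np.maximum(s11, 0.0)
    s22 = np.maximum(s22, 0.0)
    g = s12 / (s11 + _VIF_EPS)
    sv = s22 - g * s12
    g = np.where(s11 < _VIF_EPS, 0.0, g)
    sv = np.where(s11 < _VIF_EPS, s22, sv)
    s11 = np.where(s11 < _VIF_EPS, 0.0, s11)
    sv = np.where(g < 0, s22, sv)
    g = np.maximum(g, 0.0)
    sv = np.maximum(sv, _VIF_EPS)
    vid = np.log10(1.0 + g * g * s11 / (sv + _VIF_NOISE)).sum()
    vind = np.log10(1.0 + s11 / _VIF_NOISE).sum()
    return vid, vind


def viff(a, b, f, n_scales: int = 4) -> float:
    a, b, f = _triple(a, b, f)
    if min(a.shape) < 32:
        raise ValueError("images must be at least 32x32 for the 4-scale VIFF")
    a = a * 255.0
    b = b * 255.0
    f = f * 255.0
    vals = []
    for scale in range(1, n_scales + 1):
        n = 2 ** (4 - scale + 1) + 1
        win = _gauss_win(n, n / 5.0)
        if scale > 1:
            def down(x):
                y = fftconvolve(x, win, mode="valid")
                return y[::2, ::2]
            a, b, f = down(a), down(b), down(f)
        if min(a.shape) < n:  # too small for this scale's window
            break
        vid_a, vind_a = _vif_terms(a, f, win)
        vid_b, vind_b = _vif_terms(b, f, win)
        den = vind_a + vind_b
        vals.append((vid_a + vid_b) / den if den > 0 else 1.0)
    return float(np.mean(vals))


# -- spatial frequency ----------------------------------------------------

_DIAG_W = 1.0 / np.sqrt(2.0)


def _dir_diffs(x: np.ndarray):
    return (
        x[:, 1:] - x[:, :-1],          # row (horizontal)
        x[1:, :] - x[:-1, :],          # column (vertical)
        x[1:, 1:] - x[:-1, :-1],       # main diagonal
        x[1:, :-1] - x[:-1, 1:],       # secondary diagonal
    )


def _sf_from_diffs(diffs) -> float:
    w = (1.0, 1.0, _DIAG_W, _DIAG_W)
    return float(np.sqrt(sum(wi * np.mean(d ** 2) for wi, d in zip(w, diffs))))


def rsfe(a, b, f):
    """Returns (signed rSFe, |rSFe|)."""
    a, b, f = _triple(a, b, f)
    sf_f = _sf_from_diffs(_dir_diffs(f))
    ref = [np.maximum(np.abs(da), np.abs(db))
           for da, db in zip(_dir_diffs(a), _dir_diffs(b))]
    sf_r = _sf_from_diffs(ref)
    if sf_r == 0:
        raise ValueError("reference spatial frequency is zero (constant sources)")
    r = (sf_f - sf_r) / sf_r
    return float(r), float(abs(r))


# -- report ---------------------------------------------------------------

@dataclass
class MetricReport:
    sd: float
    psnr: float
    scd: float
    mi: float
    ssim: float
    qabf: float
    viff: float
    rsfe: float
    rsfe_abs: float

    CSV_HEADER = "file,sd,psnr,scd,mi,ssim,qabf,viff,rsfe"

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def csv_row(self, label: str) -> str:
        vals = [self.sd, self.psnr, self.scd, self.mi, self.ssim,
                self.qabf, self.viff, self.rsfe]
        return label + "," + ",".join(f"{v:.6g}" for v in vals)


def evaluate_all(a, b, f) -> MetricReport:
    """The full eight-metric report for one (A, B, F) triple.  Colour inputs
    are evaluated on their Y channel."""
    a, b, f = _triple(a, b, f)
    r_signed, r_abs = rsfe(a, b, f)
    return MetricReport(
        sd=sd(f),
        psnr=psnr(a, b, f),
        scd=scd(a, b, f),
        mi=mi(a, b, f),
        ssim=ssim_fusion(a, b, f),
        qabf=qabf(a, b, f),
        viff=viff(a, b, f),
        rsfe=r_signed,
        rsfe_abs=r_abs,
    )
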