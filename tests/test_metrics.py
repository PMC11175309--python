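"""The eight fusion metrics against independent brute-force oracles, plus
their identity cases and invariances.

Each oracle below recomputes the metric from its definition with explicit
loops/direct formulas, independent of the vectorised implementations in
``cirf.metrics``.
"""

import numpy as np
import pytest
from scipy import ndimage

from cirf import metrics as M


# ---------------------------------------------------------------------------
# oracles


def oracle_sd(f):
    x = f.ravel() * 255.0
    m = x.sum() / x.size
    return np.sqrt(((x - m) ** 2).sum() / x.size)


def oracle_pearson(x, y):
    x, y = x.ravel(), y.ravel()
    n = x.size
    sx, sy = x.sum() / n, y.sum() / n
    cov = ((x - sx) * (y - sy)).sum()
    den = np.sqrt(((x - sx) ** 2).sum() * ((y - sy) ** 2).sum())
    return 0.0 if den == 0 else cov / den


def oracle_scd(a, b, f):
    return oracle_pearson(f - b, a) + oracle_pearson(f - a, b)


def oracle_mi_pair(x, y):
    """Double-loop joint-histogram mutual information."""
    qx = np.clip(np.round(x * 255), 0, 255).astype(int)
    qy = np.clip(np.round(y * 255), 0, 255).astype(int)
    joint = np.zeros((256, 256))
    for i, j in zip(qx.ravel(), qy.ravel()):
        joint[i, j] += 1
    joint /= qx.size
    px, py = joint.sum(1), joint.sum(0)
    out = 0.0
    for i in range(256):
        for j in range(256):
            if joint[i, j] > 0:
                out += joint[i, j] * np.log2(joint[i, j] / (px[i] * py[j]))
    return out


def oracle_ssim_pair(x, y, win=11, sigma=1.5):
    """Sliding Gaussian-window SSIM, valid positions, L=255."""
    x, y = x * 255.0, y * 255.0
    ax = np.arange(win) - win // 2
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    c1, c2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
    h, wd = x.shape
    vals = []
    for i in range(h - win + 1):
        for j in range(wd - win + 1):
            px = x[i:i + win, j:j + win]
            py = y[i:i + win, j:j + win]
            mx, my = (w * px).sum(), (w * py).sum()
            vx = (w * px * px).sum() - mx * mx
            vy = (w * py * py).sum() - my * my
            cxy = (w * px * py).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * cxy + c2)) /
                        ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return np.mean(vals)


def _oracle_grad(img):
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    h, w = img.shape
    pad = np.zeros((h + 2, w + 2))
    pad[1:-1, 1:-1] = img
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = pad[i:i + 3, j:j + 3]
            gx[i, j] = (win * kx).sum()
            gy[i, j] = (win * kx.T).sum()
    return gx, gy


def oracle_qabf(a, b, f):
    c = M.QABF_CONSTANTS

    def strength_orientation(img):
        gx, gy = _oracle_grad(img)
        g = np.sqrt(gx ** 2 + gy ** 2)
        al = np.zeros_like(g)
        h, w = img.shape
        for i in range(h):
            for j in range(w):
                if gx[i, j] == 0 and gy[i, j] == 0:
                    al[i, j] = 0.0
                elif gx[i, j] == 0:
                    al[i, j] = np.pi / 2 * np.sign(gy[i, j])
                else:
                    al[i, j] = np.arctan(gy[i, j] / gx[i, j])
        return g, al

    def pres(x, gamma, k, delta):
        raw = gamma / (1 + np.exp(k * (x - delta)))
        return raw / (gamma / (1 + np.exp(k * (1 - delta))))

    ga, ala = strength_orientation(a)
    gb, alb = strength_orientation(b)
    gf, alf = strength_orientation(f)
    num = den = 0.0
    h, w = a.shape
    for i in range(h):
        for j in range(w):
            for gs, als in ((ga, ala), (gb, alb)):
                mg, Mg = sorted((gs[i, j], gf[i, j]))
                G = 1.0 if Mg == 0 else mg / Mg
                A = 1 - abs(als[i, j] - alf[i, j]) / (np.pi / 2)
                q = pres(G, c["gamma_g"], c["k_g"], c["delta_g"]) * \
                    pres(A, c["gamma_a"], c["k_a"], c["delta_a"])
                num += q * gs[i, j]
                den += gs[i, j]
    return num / den


def _win_conv_valid(img, win):
    n = win.shape[0]
    h, w = img.shape
    out = np.zeros((h - n + 1, w - n + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = (img[i:i + n, j:j + n] * win).sum()
    return out


def oracle_viff(a, b, f):
    """Loop-based recomputation of the documented VIFF procedure."""
    def gwin(n, sd):
        ax = np.arange(n) - (n - 1) / 2
        g1 = np.exp(-(ax ** 2) / (2 * sd ** 2))
        w = np.outer(g1, g1)
        return w / w.sum()

    def terms(ref, dist, win):
        mu1 = _win_conv_valid(ref, win)
        mu2 = _win_conv_valid(dist, win)
        s11 = np.maximum(_win_conv_valid(ref * ref, win) - mu1 ** 2, 0)
        s22 = np.maximum(_win_conv_valid(dist * dist, win) - mu2 ** 2, 0)
        s12 = _win_conv_valid(ref * dist, win) - mu1 * mu2
        vid = vind = 0.0
        for i in range(s11.shape[0]):
            for j in range(s11.shape[1]):
                sx, sy, sxy = s11[i, j], s22[i, j], s12[i, j]
                g = sxy / (sx + 1e-10)
                sv = sy - g * sxy
                if sx < 1e-10:
                    g, sv, sx = 0.0, sy, 0.0
                if g < 0:
                    g, sv = 0.0, sy
                sv = max(sv, 1e-10)
                vid += np.log10(1 + g * g * sx / (sv + 2.0))
                vind += np.log10(1 + sx / 2.0)
        return vid, vind

    a, b, f = a * 255.0, b * 255.0, f * 255.0
    vals = []
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        win = gwin(n, n / 5)
        if scale > 1:
            a = _win_conv_valid(a, win)[::2, ::2]
            b = _win_conv_valid(b, win)[::2, ::2]
            f = _win_conv_valid(f, win)[::2, ::2]
        if min(a.shape) < n:
            break
        va, na = terms(a, f, win)
        vb, nb = terms(b, f, win)
        den = na + nb
        vals.append((va + vb) / den if den > 0 else 1.0)
    return np.mean(vals)


def oracle_rsfe(a, b, f):
    wd = 1 / np.sqrt(2)

    def diffs(x):
        return [x[:, 1:] - x[:, :-1], x[1:, :] - x[:-1, :],
                x[1:, 1:] - x[:-1, :-1], x[1:, :-1] - x[:-1, 1:]]

    def sf(ds):
        ws = [1, 1, wd, wd]
        return np.sqrt(sum(w * (d ** 2).mean() for w, d in zip(ws, ds)))

    sff = sf(diffs(f))
    ref = [np.maximum(np.abs(da), np.abs(db))
           for da, db in zip(diffs(a), diffs(b))]
    sfr = sf(ref)
    return (sff - sfr) / sfr


def oracle_psnr(a, b, f):
    a, b, f = a * 255, b * 255, f * 255
    mse = (((a - f) ** 2).mean() + ((b - f) ** 2).mean()) / 2
    return np.inf if mse == 0 else 10 * np.log10(255 ** 2 / mse)


def _triples(n, rng, lo=16, hi=32):
    for _ in range(n):
        s = int(rng.integers(lo, hi + 1))
        a = rng.random((s, s))
        b = rng.random((s, s))
        f = np.clip(0.5 * (a + b) + 0.1 * rng.standard_normal((s, s)), 0, 1)
        yield a, b, f


# ---------------------------------------------------------------------------
# oracle agreement


class TestOracleAgreement:
    def test_direct_formula_metrics_match_oracles(self, rng):
        """SD, PSNR, SCD, rSFe and MI vs direct-formula / double-loop
        oracles on 50 random triples."""
        for a, b, f in _triples(50, rng):
            assert abs(M.sd(f) - oracle_sd(f)) < 1e-9
            assert abs(M.psnr(a, b, f) - oracle_psnr(a, b, f)) < 1e-9
            assert abs(M.scd(a, b, f) - oracle_scd(a, b, f)) < 1e-9
            assert abs(M.rsfe(a, b, f)[0] - oracle_rsfe(a, b, f)) < 1e-9

    def test_mi_matches_double_loop_histogram(self, rng):
        for a, b, f in _triples(6, rng, lo=16, hi=16):
            expect = oracle_mi_pair(a, f) + oracle_mi_pair(b, f)
            assert abs(M.mi(a, b, f) - expect) < 1e-9

    def test_ssim_matches_windowed_oracle(self, rng):
        for a, b, f in _triples(6, rng, lo=16, hi=24):
            expect = 0.5 * (oracle_ssim_pair(a, f) + oracle_ssim_pair(b, f))
            assert abs(M.ssim_fusion(a, b, f) - expect) < 1e-6

    def test_qabf_matches_pixel_loop_oracle(self, rng):
        for a, b, f in _triples(6, rng, lo=16, hi=20):
            assert abs(M.qabf(a, b, f) - oracle_qabf(a, b, f)) < 1e-6

    def test_viff_matches_loop_oracle(self, rng):
        for a, b, f in _triples(3, rng, lo=32, hi=32):
            assert abs(M.viff(a, b, f) - oracle_viff(a, b, f)) < 1e-6


# ---------------------------------------------------------------------------
# identity and hand-computed cases


class TestIdentities:
    def test_perfect_fusion_identity_suite(self, rng):
        a = rng.random((64, 64))
        rep = M.evaluate_all(a, a, a)
        assert rep.ssim == 1.0
        assert rep.qabf >= 0.999
        assert abs(rep.viff - 1.0) < 1e-6
        assert rep.rsfe == 0.0
        assert np.isinf(rep.psnr)

    def test_scd_of_additive_fusion_is_two(self, rng):
        a, b = rng.random((32, 32)) / 2, rng.random((32, 32)) / 2
        assert abs(M.scd(a, b, a + b) - 2.0) < 1e-12
        # the -2 extreme: both difference images exactly anti-correlated
        # with their partner source (F constant, identical sources)
        assert abs(M.scd(a, a, np.full_like(a, 0.75)) - (-2.0)) < 1e-12

    def test_sd_hand_cases(self):
        assert M.sd(np.full((16, 16), 0.3)) == 0.0
        half = np.zeros((16, 16))
        half[:8] = 1.0
        assert abs(M.sd(half) - 127.5) < 1e-9

    def test_psnr_hand_cases(self):
        z, o = np.zeros((16, 16)), np.ones((16, 16))
        assert M.psnr(z, z, o) == 0.0
        assert abs(M.psnr(z, o, z) - 10 * np.log10(2)) < 1e-12

    def test_mi_self_information_of_binary_image(self):
        half = np.zeros((16, 16))
        half[:8] = 1.0
        # I(X;X) = H(X) = 1 bit per source term
        assert abs(M.mi(half, half, half) - 2.0) < 1e-12

    def test_mi_near_zero_for_independent_images(self, rng):
        """Independent sources share (almost) no information with F.

        Intensities are quantised to 16 levels so that the joint-histogram
        finite-sample bias ((Kx-1)(Ky-1)/(2N ln2)) stays well under the
        bound; with continuous noise and 256 bins the bias alone is
        several bits at this image size.
        """
        vals = []
        for _ in range(10):
            a, b, f = (np.floor(rng.random((128, 128)) * 16) / 16
                       for _ in range(3))
            vals.append(M.mi(a, b, f))
        assert max(vals) <= 0.1

    def test_ssim_penalises_mean_shift(self, rng):
        a = rng.random((32, 32)) * 0.5
        assert M.ssim_fusion(a + 10 / 255, a + 10 / 255, a) < 1.0

    def test_qabf_low_for_constant_fusion(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert M.qabf(a, b, np.full_like(a, 0.5)) < 0.1

    def test_qabf_warns_and_zero_for_constant_sources(self):
        c = np.full((16, 16), 0.5)
        with pytest.warns(UserWarning):
            assert M.qabf(c, c, c) == 0.0

    def test_viff_decreases_under_blur_and_noise(self, rng):
        a = np.clip(ndimage.gaussian_filter(rng.random((64, 64)), 1), 0, 1)
        blurred = ndimage.gaussian_filter(a, 1.5)
        assert M.viff(a, a, blurred) < 1.0
        b = rng.random((64, 64))
        base = np.clip(0.5 * (a + b), 0, 1)
        noise = rng.standard_normal((64, 64))
        vals = [M.viff(a, b, np.clip(base + s * noise, 0, 1))
                for s in (0.01, 0.05, 0.15)]
        assert vals[0] > vals[1] > vals[2]

    def test_rsfe_hand_cases(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert M.rsfe(a, b, np.full_like(a, 0.5))[0] == -1.0
        with pytest.raises(ValueError):
            M.rsfe(np.full((16, 16), 0.2), np.full((16, 16), 0.8),
                   rng.random((16, 16)))

    def test_evaluate_all_consistent_with_members(self, random_triple):
        a, b, f = random_triple
        rep = M.evaluate_all(a, b, f)
        assert rep.sd == M.sd(f)
        assert rep.scd == M.scd(a, b, f)
        assert rep.qabf == M.qabf(a, b, f)
        assert rep.rsfe_abs == abs(rep.rsfe)

    def test_color_inputs_use_luma(self, rng):
        a = rng.random((32, 32))
        b_rgb = np.stack([rng.random((32, 32))] * 3, -1)
        y = 0.299 * b_rgb[..., 0] + 0.587 * b_rgb[..., 1] + 0.114 * b_rgb[..., 2]
        f = np.clip(0.5 * (a + y), 0, 1)
        assert M.scd(a, b_rgb, f) == M.scd(a, y, f)


# ---------------------------------------------------------------------------
# invariances


class TestInvariances:
    def test_source_swap_symmetry(self, rng):
        for a, b, f in _triples(10, rng, lo=32, hi=32):
            for fn in (M.psnr, M.scd, M.mi, M.ssim_fusion, M.qabf, M.viff):
                assert abs(fn(a, b, f) - fn(b, a, f)) < 1e-12
            assert abs(M.rsfe(a, b, f)[0] - M.rsfe(b, a, f)[0]) < 1e-12

    def test_metric_ranges(self, rng):
        for a, b, f in _triples(100, rng, lo=16, hi=16):
            assert 0.0 <= M.qabf(a, b, f) <= 1.0
            assert -2.0 <= M.scd(a, b, f) <= 2.0
            assert M.mi(a, b, f) >= 0.0
            assert M.sd(f) >= 0.0

    def test_translation_covariance(self, rng):
        """Rolling A, B, F together by whole pixels (periodic wrap).

        Histogram/moment metrics are exactly invariant; windowed and edge
        metrics (SSIM, VIFF, QAB/F, rSFe) see the wrap seam through their
        windows/borders, so they move by a few percent at this image size
        (tolerance 0.05).
        """
        a, b, f = next(_triples(1, rng, lo=32, hi=32))
        sh = (5, 9)
        ar, br, fr = (np.roll(x, sh, (0, 1)) for x in (a, b, f))
        assert abs(M.sd(f) - M.sd(fr)) < 1e-12
        assert abs(M.psnr(a, b, f) - M.psnr(ar, br, fr)) < 1e-12
        assert abs(M.mi(a, b, f) - M.mi(ar, br, fr)) < 1e-12
        assert abs(M.scd(a, b, f) - M.scd(ar, br, fr)) < 1e-12
        assert abs(M.ssim_fusion(a, b, f) - M.ssim_fusion(ar, br, fr)) < 0.05
        assert abs(M.viff(a, b, f) - M.viff(ar, br, fr)) < 0.05
        assert abs(M.qabf(a, b, f) - M.qabf(ar, br, fr)) < 0.05
        assert abs(M.rsfe(a, b, f)[0] - M.rsfe(ar, br, fr)[0]) < 0.05
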