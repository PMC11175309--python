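"""Image I/O, colour handling, dataset plumbing and the synthetic phantom
generator for multi-modal fusion experiments.

Conventions
-----------
Images live in memory as float64 arrays in [0, 1] (``Image2D``: shape
``(H, W)``; ``ColorImage``: shape ``(H, W, 3)``, RGB).  Pseudo-colour
modalities (SPECT/PET-like) are fused on their luma channel only: the
colour image is converted to analog BT.601 YUV, the Y plane is fused
against the grayscale partner, and the original U/V planes are re-attached
afterwards.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

import imageio.v3 as iio
import tifffile

__all__ = [
    "ImagePair",
    "SplitSpec",
    "load_image",
    "save_image",
    "rgb_to_yuv",
    "yuv_to_rgb",
    "augment_six",
    "random_mask",
    "split_dataset",
    "synth_pair",
    "synth_dataset",
    "write_pair_dir",
    "load_pair_dir",
]

MASK_PATCH = 16  # side of the square patches zeroed by random_mask

# analog BT.601 luma weights and chroma scalings
_WR, _WG, _WB = 0.299, 0.587, 0.114
_U_SCALE = 0.492
_V_SCALE = 0.877


def _validate_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError("images must be at least 8x8")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


@dataclass
class ImagePair:
    """A co-registered pair; when modality B is pseudo-colour, ``b`` is its
    Y channel and ``color_b`` holds the full RGB rendering."""

    a: np.ndarray
    b: np.ndarray
    color_b: np.ndarray | None = None

    def __post_init__(self):
        self.a = _validate_gray(self.a)
        self.b = _validate_gray(self.b)
        if self.a.shape != self.b.shape:
            raise ValueError("pair modalities must share H and W")


@dataclass
class SplitSpec:
    n_total: int
    n_test: int
    augmentation_fold: int = 1

    def __post_init__(self):
        if not (0 < self.n_test < self.n_total):
            raise ValueError("need 0 < n_test < n_total")
        if self.augmentation_fold < 1:
            raise ValueError("augmentation_fold must be >= 1")


# -- file I/O -------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read PNG/TIFF into [0,1] floats; (H,W) gray or (H,W,3) RGB."""
    path = pathlib.Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    return arr.astype(np.float64)


def save_image(path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write [0,1] floats as 8- or 16-bit PNG/TIFF (16-bit grayscale only)."""
    path = pathlib.Path(path)
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 8:
        q = np.round(img * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        if img.ndim != 2:
            raise ValueError("16-bit output supported for grayscale only")
        q = np.round(img * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    else:
        iio.imwrite(path, q)


# -- colour ---------------------------------------------------------------

def rgb_to_yuv(img: np.ndarray):
    """RGB -> analog BT.601 YUV; Y in [0,1], U/V zero-centred."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB, got shape {img.shape}")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    y = _WR * r + _WG * g + _WB * b
    u = _U_SCALE * (b - y)
    v = _V_SCALE * (r - y)
    return y, u, v


def yuv_to_rgb(y: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    y, u, v = (np.asarray(c, dtype=np.float64) for c in (y, u, v))
    if not (y.shape == u.shape == v.shape):
        raise ValueError("Y, U, V must share a shape")
    r = y + v / _V_SCALE
    b = y + u / _U_SCALE
    g = (y - _WR * r - _WB * b) / _WG
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 1.0)


# -- augmentation, masking, splitting -------------------------------------

def augment_six(img: np.ndarray) -> list[np.ndarray]:
    """The six-fold training augmentation: original, three rotations, two
    mirrors, in a fixed order."""
    img = np.asarray(img)
    return [
        img.copy(),
        np.rot90(img, 1).copy(),   # 90 deg counterclockwise
        np.rot90(img, 2).copy(),   # 180 deg
        np.rot90(img, 3).copy(),   # 90 deg clockwise
        np.fliplr(img).copy(),
        np.flipud(img).copy(),
    ]


def random_mask(img: np.ndarray, ratio: float, seed: int,
                patch: int = MASK_PATCH, fill: float = 0.0) -> np.ndarray:
    """Zero out a fraction ``ratio`` of non-overlapping ``patch``-square
    tiles (masked-image-modeling style).  Deterministic given ``seed``."""
    img = np.asarray(img, dtype=np.float64)
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("mask ratio must lie in [0, 1]")
    h, w = img.shape[-2:]
    if h % patch or w % patch:
        raise ValueError(f"image sides must be divisible by the mask patch size {patch}")
    gh, gw = h // patch, w // patch
    n_patches = gh * gw
    n_masked = int(round(ratio * n_patches))
    out = img.copy()
    if n_masked == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_patches, size=n_masked, replace=False)
    for idx in chosen:
        i, j = divmod(int(idx), gw)
        out[..., i * patch:(i + 1) * patch, j * patch:(j + 1) * patch] = fill
    return out


def split_dataset(spec: SplitSpec, seed: int):
    """Shuffle pair indices, hold out ``n_test``, replicate the training
    indices across the augmentation transforms.

    Returns ``(train, test)`` where ``train`` is a list of
    ``(pair_index, aug_index)`` tuples of length
    ``(n_total - n_test) * augmentation_fold`` and ``test`` a list of pair
    indices.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(spec.n_total)
    test = [int(i) for i in perm[: spec.n_test]]
    train_pairs = [int(i) for i in perm[spec.n_test:]]
    train = [(i, a) for a in range(spec.augmentation_fold) for i in train_pairs]
    return train, test


# -- synthetic phantoms ---------------------------------------------------

def _hot_colormap(x: np.ndarray) -> np.ndarray:
    """Classic 'hot' ramp: black -> red -> yellow -> white."""
    r = np.clip(3.0 * x, 0.0, 1.0)
    g = np.clip(3.0 * x - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * x - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def _normalize01(x: np.ndarray, lo=0.02, hi=0.98) -> np.ndarray:
    mn, mx = x.min(), x.max()
    if mx - mn < 1e-12:
        return np.full_like(x, lo)
    return lo + (hi - lo) * (x - mn) / (mx - mn)


def synth_pair(seed: int, size: int = 256, profile: str = "grayscale-pair") -> ImagePair:
    """Generate a co-registered synthetic modality pair.

    A latent "anatomy" of random soft ellipses over a smooth background is
    rendered twice: modality A as a smoothly varying tissue-contrast map
    (low-frequency rich, MR-T1-like) and modality B as an edge/texture
    emphasised view of the same structures (high-frequency rich, CT/T2-like).
    ``profile="pseudo-color"`` additionally wraps B in a hot-colormap RGB
    rendering (SPECT/PET-like) whose Y channel becomes modality B.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if profile not in ("grayscale-pair", "pseudo-color"):
        raise ValueError(f"unknown profile {profile!r}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    # latent anatomy: 4-7 soft ellipses with distinct tissue intensities
    tissue = np.zeros((size, size))
    n_blobs = rng.integers(4, 8)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
        ay, ax = rng.uniform(size / 12, size / 4, size=2)
        th = rng.uniform(0, np.pi)
        inten = rng.uniform(0.3, 1.0)
        u = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        v = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        d2 = (u / ay) ** 2 + (v / ax) ** 2
        tissue += inten * np.exp(-(d2 ** 2) * 3.0)  # super-gaussian: flat core, soft rim

    bg = ndimage.gaussian_filter(rng.normal(size=(size, size)), size / 10.0)

    # modality A: smooth contrast map
    a = _normalize01(ndimage.gaussian_filter(tissue, 2.5) + 0.6 * _normalize01(bg) * 0.3)

    # modality B: same anatomy, edge and fine-texture emphasised
    smooth = ndimage.gaussian_filter(tissue, 1.0)
    gx = ndimage.sobel(smooth, axis=1)
    gy = ndimage.sobel(smooth, axis=0)
    edges = np.hypot(gx, gy)
    edges = edges / (edges.max() + 1e-12)
    noise = rng.normal(size=(size, size))
    texture = ndimage.gaussian_filter(noise, 0.8) - ndimage.gaussian_filter(noise, 2.5)
    texture = texture / (np.abs(texture).max() + 1e-12)
    mask = tissue > 0.15
    b = _normalize01(0.55 * _normalize01(tissue) + 1.1 * edges + 0.18 * texture * mask)

    if profile == "pseudo-color":
        color = _hot_colormap(b)
        y, _, _ = rgb_to_yuv(color)
        return ImagePair(a=a, b=np.clip(y, 0.0, 1.0), color_b=color)
    return ImagePair(a=a, b=b)


def synth_dataset(n: int, seed: int, size: int = 256,
                  profile: str = "grayscale-pair") -> list[ImagePair]:
    """n independent phantom pairs; pair i uses a seed derived from (seed, i)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n)
    return [synth_pair(int(s) % (2 ** 31), size=size, profile=profile)
            for s in child_seeds]


def write_pair_dir(pairs: list[ImagePair], out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(pairs):
        save_image(out / f"{i:04d}_a.png", p.a)
        if p.color_b is not None:
            save_image(out / f"{i:04d}_b.png", p.color_b)
        else:
            save_image(out / f"{i:04d}_b.png", p.b)


def load_pair_dir(dir_path) -> list[ImagePair]:
    """Load `*_a.png` / `*_b.png` pairs; RGB B images go through YUV."""
    d = pathlib.Path(dir_path)
    pairs = []
    for a_path in sorted(d.glob("*_a.png")) + sorted(d.glob("*_a.tif*")):
        b_candidates = list(d.glob(a_path.name.replace("_a.", "_b.").replace(
            a_path.suffix, "") + ".*"))
        b_path = d / (a_path.name[: -len("_a" + a_path.suffix)] + "_b" + a_path.suffix)
        if not b_path.exists() and b_candidates:
            b_path = b_candidates[0]
        a = load_image(a_path)
        b = load_image(b_path)
        if b.ndim == 3:
            y, _, _ = rgb_to_yuv(b)
            pairs.append(ImagePair(a=a, b=np.clip(y, 0, 1), color_b=b))
        else:
            pairs.append(ImagePair(a=a, b=b))
    return pairs
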