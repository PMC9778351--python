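"""Synthetic breast-ultrasound-like phantoms with pixel-wise ground truth.

A phantom emulates the gross appearance of a B-mode breast image: horizontal
tissue bands (fat over mammary over muscle, background below), gently
undulating band boundaries, an optional dark elliptical tumor embedded in the
mammary band, dark background patches with tumor-like intensity (decoys),
Gaussian boundary blur and multiplicative speckle. It is a geometric stand-in
for real data — no acoustic simulation — so that every other module can be
exercised without downloads; see the methods note for what this does and does
not establish about real images.

Class indices: 0 background, 1 fat, 2 mammary, 3 muscle, 4 tumor
(display palette black/green/yellow/blue/red). Coordinates are row-major,
origin top-left, 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, warp

from .metrics import CLASS_PALETTE

logger = logging.getLogger(__name__)

AUGMENT_OPS = ("hflip", "hshift", "vshift", "rotation", "zoom", "shear")

__all__ = ["PhantomParams", "PhantomSample", "generate_phantom", "normalize_intensity",
           "augment", "make_dataset", "write_pair", "read_pair", "write_dataset",
           "read_dataset", "AUGMENT_OPS"]


@dataclass
class PhantomParams:
    """Knobs of the phantom generator (defaults give a 128x128 image)."""

    size: int = 128
    # Row fractions where fat/mammary, mammary/muscle and muscle/background meet.
    band_fracs: tuple[float, float, float] = (0.22, 0.55, 0.80)
    wave_amplitude: float = 0.03          # boundary undulation, fraction of height
    tumor_prob: float = 0.9
    tumor_axes_frac: tuple[float, float] = (0.08, 0.16)   # semi-axis range, fraction of size
    tumor_eccentricity: float = 0.7       # vertical/horizontal semi-axis ratio
    # Mean 8-bit intensity per tissue: background, fat, mammary, muscle, tumor.
    tissue_means: tuple[float, ...] = (45.0, 175.0, 125.0, 95.0, 40.0)
    tissue_sd: float = 0.0                # additive per-pixel texture, 8-bit units
    speckle_strength: float = 0.15        # std of unit-mean multiplicative noise
    blur_sigma: float = 1.5               # boundary blur, pixels
    n_decoys: int = 2                     # tumor-intensity patches in the background
    seed: int = 0

    def __post_init__(self):
        f1, f2, f3 = self.band_fracs
        if not (0.0 < f1 < f2 < f3 < 1.0):
            raise ValueError("band fractions must be strictly increasing in (0, 1)")
        if len(self.tissue_means) != 5:
            raise ValueError("need 5 tissue mean intensities")


@dataclass
class PhantomSample:
    image: np.ndarray                     # uint8 (H, W)
    mask: np.ndarray                      # int64 (H, W) in {0..4}
    params: PhantomParams = field(repr=False, default=None)
    seed: int | None = None


def _band_mask(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    s = params.size
    cols = np.arange(s)
    rows = np.arange(s)[:, None]
    freq = rng.uniform(0.5, 1.5)
    mask = np.zeros((s, s), dtype=np.int64)
    boundaries = []
    for frac in params.band_fracs:
        phase = rng.uniform(0, 2 * np.pi)
        boundaries.append((frac + params.wave_amplitude * np.sin(2 * np.pi * freq * cols / s + phase)) * s)
    b1, b2, b3 = boundaries
    mask[(rows >= 0) & (rows < b1)] = 1        # fat
    mask[(rows >= b1) & (rows < b2)] = 2       # mammary
    mask[(rows >= b2) & (rows < b3)] = 3       # muscle
    return mask                                 # rows >= b3 stay background


def _place_tumor(mask: np.ndarray, params: PhantomParams, rng: np.random.Generator,
                 max_retries: int = 25) -> bool:
    """Stamp an ellipse of class 4 fully inside the mammary band."""
    s = params.size
    yy, xx = np.mgrid[0:s, 0:s]
    for attempt in range(max_retries):
        shrink = 0.9 ** attempt
        ax = rng.uniform(*params.tumor_axes_frac) * s * shrink
        ay = ax * params.tumor_eccentricity
        cx = rng.uniform(0.2, 0.8) * s
        col = int(np.clip(round(cx), 0, s - 1))
        mam_rows = np.flatnonzero(mask[:, col] == 2)
        if mam_rows.size < 3:
            continue
        cy = rng.uniform(mam_rows[0] + ay, mam_rows[-1] - ay) if mam_rows[-1] - ay > mam_rows[0] + ay \
            else mam_rows.mean()
        ellipse = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        if ellipse.sum() < 8:
            continue
        if np.all(mask[ellipse] == 2):
            mask[ellipse] = 4
            return True
        logger.debug("tumor placement retry %d (ellipse crossed the mammary band)", attempt + 1)
    logger.warning("could not place a tumor after %d retries; emitting tumor-free phantom", max_retries)
    return False


def generate_phantom(params: PhantomParams, seed: int | None = None) -> PhantomSample:
    """Render one phantom; deterministic given ``params`` and ``seed``."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mask = _band_mask(params, rng)
    if rng.random() < params.tumor_prob:
        _place_tumor(mask, params, rng)

    means = np.asarray(params.tissue_means, dtype=np.float64)
    img = means[mask]
    if params.tissue_sd > 0:
        img = img + rng.normal(0.0, params.tissue_sd, img.shape)

    # Background patches with tumor-like intensity (the classic false-positive bait).
    bg = mask == 0
    if bg.any() and params.n_decoys > 0:
        s = params.size
        yy, xx = np.mgrid[0:s, 0:s]
        bg_rows, bg_cols = np.nonzero(bg)
        for _ in range(params.n_decoys):
            k = rng.integers(bg_rows.size)
            cy, cx = bg_rows[k], bg_cols[k]
            r = rng.uniform(0.03, 0.07) * s
            blob = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r) & bg
            img[blob] = means[4]

    if params.blur_sigma > 0:
        img = gaussian_filter(img, params.blur_sigma)
    if params.speckle_strength > 0:
        shape = 1.0 / params.speckle_strength ** 2
        img = img * rng.gamma(shape, 1.0 / shape, img.shape)
    img = np.clip(img, 0, 255).round().astype(np.uint8)
    return PhantomSample(image=img, mask=mask, params=params, seed=seed)


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to ``[-1, 1]`` via ``x / 127.5 - 1``."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr / 127.5 - 1.0


# ----------------------------------------------------------------- augmentation
_DEFAULT_RANGES = {
    "hshift": 0.10,      # fraction of width
    "vshift": 0.10,      # fraction of height
    "rotation": 15.0,    # degrees
    "zoom": (0.9, 1.1),  # scale factor
    "shear": 10.0,       # degrees
}


def augment(sample: PhantomSample, ops, seed: int | None = None) -> PhantomSample:
    """Apply geometric augmentations to an image/mask pair, keeping them aligned.

    ``ops`` is a sequence drawn from ``hflip, hshift, vshift, rotation, zoom,
    shear``; each entry is either a name (magnitude drawn from bounded
    defaults using ``seed``) or a ``(name, value)`` pair for explicit
    magnitudes. The image is interpolated bilinearly, the mask with nearest
    neighbor; exposed pixels become background (class 0, background
    intensity).
    """
    rng = np.random.default_rng(seed)
    img = sample.image.astype(np.float64)
    mask = sample.mask.copy()
    h, w = img.shape
    bg_intensity = float(sample.params.tissue_means[0]) if sample.params else 0.0

    tform = AffineTransform()
    flip = False
    center = AffineTransform(translation=(-w / 2, -h / 2))
    uncenter = AffineTransform(translation=(w / 2, h / 2))
    for op in ops:
        name, value = op if isinstance(op, (tuple, list)) else (op, None)
        if name not in AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {name!r}; choose from {AUGMENT_OPS}")
        if name == "hflip":
            flip = not flip
            continue
        if value is None:
            bound = _DEFAULT_RANGES[name]
            value = rng.uniform(*bound) if isinstance(bound, tuple) else rng.uniform(-bound, bound)
        if name == "hshift":
            step = AffineTransform(translation=(value * w, 0))
        elif name == "vshift":
            step = AffineTransform(translation=(0, value * h))
        elif name == "rotation":
            step = uncenter + AffineTransform(rotation=np.deg2rad(value)) + center
        elif name == "zoom":
            step = uncenter + AffineTransform(scale=(value, value)) + center
        elif name == "shear":
            step = uncenter + AffineTransform(shear=np.deg2rad(value)) + center
        tform = tform + step

    if flip:
        img = np.fliplr(img)
        mask = np.fliplr(mask)
    if not np.allclose(tform.params, np.eye(3)):
        # skimage's ``+`` composes left-to-right; warp wants the inverse map.
        img = warp(img, tform.inverse, order=1, cval=bg_intensity, preserve_range=True)
        mask = warp(mask.astype(np.float64), tform.inverse, order=0, cval=0.0,
                    preserve_range=True).astype(np.int64)
    return PhantomSample(image=np.clip(img, 0, 255).round().astype(np.uint8),
                         mask=np.ascontiguousarray(mask), params=sample.params, seed=sample.seed)


# --------------------------------------------------------------------- dataset
def make_dataset(n: int, params: PhantomParams, seed: int = 0,
                 k_folds: int = 10) -> tuple[list[PhantomSample], list[np.ndarray]]:
    """Generate ``n`` phantoms plus a disjoint, exhaustive ``k_folds`` partition."""
    if n < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} samples, got {n}")
    root = np.random.SeedSequence(seed)
    sample_seeds = root.generate_state(n + 1)
    samples = [generate_phantom(params, int(s) % (2 ** 31)) for s in sample_seeds[:n]]
    rng = np.random.default_rng(sample_seeds[n])
    order = rng.permutation(n)
    folds = [np.sort(order[i::k_folds]) for i in range(k_folds)]
    return samples, folds


# -------------------------------------------------------------------- file I/O
def _palette_bytes() -> bytes:
    flat = [v for rgb in CLASS_PALETTE for v in rgb]
    return bytes(flat + [0] * (768 - len(flat)))


def write_pair(sample: PhantomSample, out_dir, stem: str) -> tuple[Path, Path]:
    """Write ``<stem>.png`` (grayscale) and ``<stem>_mask.png`` (indexed palette)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{stem}.png"
    mask_path = out_dir / f"{stem}_mask.png"
    Image.fromarray(sample.image, mode="L").save(img_path)
    m = Image.fromarray(sample.mask.astype(np.uint8), mode="P")
    m.putpalette(_palette_bytes())
    m.save(mask_path)
    return img_path, mask_path


def read_pair(image_path, mask_path) -> PhantomSample:
    """Read an image/mask pair written by :func:`write_pair`.

    Also accepts the public BUS datasets' plain binary tumor masks
    (grayscale or bilevel PNG: zero -> background, nonzero -> tumor).
    """
    img = np.asarray(Image.open(image_path).convert("L"))
    m = Image.open(mask_path)
    if m.mode == "P":
        idx = np.asarray(m)
        pal = m.getpalette() or []
        pal = np.asarray(pal + [0] * (768 - len(pal))).reshape(256, 3)
        colors = {tuple(pal[i]): None for i in np.unique(idx)}
        class_of = {rgb: c for c, rgb in enumerate(CLASS_PALETTE)}
        unknown = [rgb for rgb in colors if rgb not in class_of]
        if unknown:
            raise ValueError(f"mask {mask_path} contains non-palette colors: {unknown}; "
                             f"expected {list(CLASS_PALETTE)}")
        lut = np.zeros(256, dtype=np.int64)
        for i in np.unique(idx):
            lut[i] = class_of[tuple(pal[i])]
        mask = lut[idx]
    else:
        arr = np.asarray(m.convert("L"))
        vals = np.unique(arr)
        if not np.all(np.isin(vals, [0, 1, 255])):
            raise ValueError(f"mask {mask_path} is neither palette-indexed nor binary "
                             f"(values {vals.tolist()})")
        mask = np.where(arr > 0, 4, 0).astype(np.int64)   # tumor / background
    return PhantomSample(image=img, mask=mask, params=None, seed=None)


def write_dataset(samples: list[PhantomSample], folds: list[np.ndarray], out_dir,
                  params: PhantomParams) -> pd.DataFrame:
    """Write all pairs plus a manifest CSV and the generator parameters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fold_of = np.empty(len(samples), dtype=np.int64)
    for f, idx in enumerate(folds):
        fold_of[idx] = f
    rows = []
    for i, s in enumerate(samples):
        img_path, mask_path = write_pair(s, out_dir, f"phantom_{i:04d}")
        rows.append({"image": img_path.name, "mask": mask_path.name, "fold": int(fold_of[i]),
                     "has_tumor": bool((s.mask == 4).any()), "seed": s.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "params.json").write_text(json.dumps(asdict(params), indent=2))
    return manifest


def read_dataset(root) -> tuple[list[PhantomSample], list[np.ndarray], pd.DataFrame]:
    """Load a dataset directory written by :func:`write_dataset`."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    params = None
    params_file = root / "params.json"
    if params_file.exists():
        params = PhantomParams(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in json.loads(params_file.read_text()).items()})
    samples = []
    for _, row in manifest.iterrows():
        s = read_pair(root / row["image"], root / row["mask"])
        samples.append(replace(s, params=params, seed=row.get("seed")))
    k = int(manifest["fold"].max()) + 1
    folds = [np.asarray(manifest.index[manifest["fold"] == f]) for f in range(k)]
    return samples, folds, manifest
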