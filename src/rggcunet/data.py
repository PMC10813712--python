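"""Data plumbing: synthetic signet-ring-cell patches, dense patch cropping
and prediction stitching, augmentation, polygon annotations, and image I/O.

The synthetic generator emulates the morphology a pathologist sees in an
H&E-stained signet ring cell: intracellular mucin inflates the cell into a
pale disc and pushes the nucleus into a darker crescent against the cell
border (the "signet ring").  Patches are rendered on a pink/purple
stromal background with low-frequency tone variation and pixel noise;
cells may overlap and cluster.  The ground-truth mask is the exact union
of the cell ellipses (no anti-aliasing), and the patch label ``y_p`` is 1
iff at least one cell was placed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, warp


# ---------------------------------------------------------------------------
# synthetic patch generation
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Rendering parameters of the synthetic signet-ring-cell generator.

    Ranges are inclusive; ``seed`` fixes every random choice, so equal
    configs render bitwise-identical patches.
    """
    patch_size: int = 128
    n_cells: tuple[int, int] = (1, 4)          # cells per positive patch
    cell_radius: tuple[float, float] = (12.0, 24.0)   # semi-major axis, px
    aspect: tuple[float, float] = (0.75, 1.0)  # semi-minor / semi-major
    nucleus_eccentricity: float = 0.85         # nucleus offset / cell radius
    overlap_allowed: bool = True
    background_tone: tuple[float, float, float] = (0.91, 0.75, 0.86)
    cytoplasm_tone: tuple[float, float, float] = (0.93, 0.88, 0.94)
    nucleus_tone: tuple[float, float, float] = (0.42, 0.22, 0.55)
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.cell_radius[0] < 2:
            raise ValueError("cell radii must be >= 2 px")
        if not (0 <= self.nucleus_eccentricity < 1):
            raise ValueError("nucleus_eccentricity must lie in [0, 1)")
        if self.patch_size < 2 * self.cell_radius[1] + 4:
            raise ValueError(
                f"patch_size {self.patch_size} too small for max cell radius "
                f"{self.cell_radius[1]}")


def _ellipse_interior(shape, center, axes, angle):
    """Exact boolean interior of a rotated ellipse, tested at pixel centres."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_srcc_patch(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic patch.

    Returns ``(image, mask)``: an (H, W, 3) float image in [0, 1] and the
    exact binary (H, W) uint8 mask.  ``mask.any()`` gives the patch label.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.patch_size

    # H&E-like background: base tone + smooth tonal field + pixel noise
    image = np.empty((s, s, 3), dtype=np.float64)
    tone_field = gaussian_filter(rng.normal(0.0, 1.0, (s, s)), sigma=s / 8.0)
    tone_field /= max(np.abs(tone_field).max(), 1e-9)
    for ch, base in enumerate(cfg.background_tone):
        image[..., ch] = base + 0.04 * tone_field

    mask = np.zeros((s, s), dtype=bool)
    n = int(rng.integers(cfg.n_cells[0], cfg.n_cells[1] + 1))
    placed: list[tuple[float, float, float]] = []
    for _ in range(n):
        for _attempt in range(40):
            r = rng.uniform(*cfg.cell_radius)
            b = r * rng.uniform(*cfg.aspect)
            angle = rng.uniform(0, np.pi)
            cy = rng.uniform(r + 1, s - r - 1)
            cx = rng.uniform(r + 1, s - r - 1)
            if cfg.overlap_allowed or all(
                    np.hypot(cy - py, cx - px) > r + pr
                    for py, px, pr in placed):
                break
        placed.append((cy, cx, r))
        cell = _ellipse_interior((s, s), (cy, cx), (r, b), angle)
        mask |= cell

        # pale mucin-filled cytoplasm with a faint membrane rim
        rim = cell & ~_ellipse_interior((s, s), (cy, cx),
                                        (r - 1.5, b - 1.5), angle)
        cyto = np.array(cfg.cytoplasm_tone) + rng.normal(0, 0.01, 3)
        image[cell] = cyto
        image[rim] = np.clip(cyto - 0.12, 0, 1)

        # eccentric crescent nucleus tangent to the cell border
        theta = rng.uniform(0, 2 * np.pi)
        off = cfg.nucleus_eccentricity * min(r, b)
        ncy, ncx = cy + off * np.sin(theta), cx + off * np.cos(theta)
        nr = 0.45 * min(r, b)
        nucleus = _ellipse_interior((s, s), (ncy, ncx), (nr, 0.7 * nr),
                                    theta) & cell
        image[nucleus] = np.array(cfg.nucleus_tone) + rng.normal(0, 0.02, 3)

    image += rng.normal(0.0, cfg.noise_sigma, image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return image, mask.astype(np.uint8)


def generate_dataset(cfg: SynthConfig, n_patches: int, base_seed: int = 0,
                     negative_fraction: float = 0.75):
    """Generate a list of (image, mask) patches with per-patch seeds
    ``base_seed + i``; a ``negative_fraction`` share are lesion-free.

    The positive:negative mix mirrors the 1:3 ratio typical of screening
    sets for this task.
    """
    out = []
    for i in range(n_patches):
        seed = base_seed + i
        is_neg = np.random.default_rng(seed ^ 0x5EED).random() < negative_fraction
        c = replace(cfg, seed=seed, n_cells=(0, 0) if is_neg else cfg.n_cells)
        out.append(generate_srcc_patch(c))
    return out


# ---------------------------------------------------------------------------
# dense cropping / stitching
# ---------------------------------------------------------------------------

def _grid_starts(length: int, patch: int, stride: int) -> list[int]:
    starts = list(range(0, length - patch + 1, stride))
    if starts[-1] != length - patch:
        starts.append(length - patch)  # border-aligned final tile
    return starts


def dense_crop(image: np.ndarray, mask: np.ndarray | None = None,
               patch_size: int = 128, stride: int = 64):
    """Tile an image (and optional mask) into overlapping patches.

    Returns a list of ``(image_patch, mask_patch, (row, col))`` offsets;
    the last row/column of tiles is aligned to the border so every pixel
    is covered.
    """
    H, W = image.shape[:2]
    if H < patch_size or W < patch_size:
        raise ValueError(
            f"image {H}x{W} smaller than patch {patch_size}; pad it first "
            "(see pad_to_multiple)")
    patches = []
    for r in _grid_starts(H, patch_size, stride):
        for c in _grid_starts(W, patch_size, stride):
            ip = image[r:r + patch_size, c:c + patch_size]
            mp = None if mask is None else mask[r:r + patch_size,
                                               c:c + patch_size]
            patches.append((ip, mp, (r, c)))
    return patches


def stitch(patch_predictions, full_size: tuple[int, int]) -> np.ndarray:
    """Assemble per-patch class-probability maps into a full-size map.

    ``patch_predictions``: iterable of ``(prob_map, (row, col))`` with
    ``prob_map`` of shape (C, h, w).  Overlaps are averaged in probability
    space and the result renormalised per pixel.  Every pixel must be
    covered by at least one patch.
    """
    H, W = full_size
    acc = None
    count = np.zeros((H, W), dtype=np.float64)
    for prob, (r, c) in patch_predictions:
        prob = np.asarray(prob)
        if acc is None:
            acc = np.zeros((prob.shape[0], H, W), dtype=np.float64)
        h, w = prob.shape[1:]
        acc[:, r:r + h, c:c + w] += prob
        count[r:r + h, c:c + w] += 1
    if acc is None or (count == 0).any():
        raise ValueError("stitch: some pixels are not covered by any patch")
    acc /= count
    acc /= acc.sum(axis=0, keepdims=True)
    return acc


def pad_to_multiple(image: np.ndarray, multiple: int = 16):
    """Reflect-pad (H, W[, C]) to the next multiple; returns (padded, (H, W))."""
    H, W = image.shape[:2]
    ph = (-H) % multiple
    pw = (-W) % multiple
    if ph == 0 and pw == 0:
        return image, (H, W)
    pads = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pads, mode="reflect"), (H, W)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Strengths for the training-time augmentation chain: Gaussian blur,
    hue/saturation jitter, affine warps, and horizontal/vertical flips."""
    blur_sigma: tuple[float, float] = (0.0, 1.5)
    blur_prob: float = 0.5
    hue_shift: float = 0.04          # max absolute hue offset (fraction of 1)
    sat_range: tuple[float, float] = (0.8, 1.2)
    rotate_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.05
    flip_prob: float = 0.5


IDENTITY_AUGMENT = AugmentConfig(blur_sigma=(0.0, 0.0), blur_prob=0.0,
                                 hue_shift=0.0, sat_range=(1.0, 1.0),
                                 rotate_deg=0.0, scale_range=(1.0, 1.0),
                                 translate_frac=0.0, flip_prob=0.0)


def augment(image: np.ndarray, mask: np.ndarray, seed: int,
            cfg: AugmentConfig | None = None):
    """Deterministically augment an image/mask pair.

    Photometric ops (blur, hue/saturation) touch only the image; geometric
    ops (affine, flips) are applied identically to both, with bilinear
    interpolation for the image and nearest-neighbour (re-binarised) for
    the mask.  The image stays clipped to [0, 1] and the mask binary.
    """
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask)

    # photometric -------------------------------------------------------
    sigma = rng.uniform(*cfg.blur_sigma)
    do_blur = rng.random() < cfg.blur_prob
    if do_blur and sigma > 0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    hue = rng.uniform(-cfg.hue_shift, cfg.hue_shift)
    sat = rng.uniform(*cfg.sat_range)
    if hue != 0.0 or sat != 1.0:
        hsv = rgb2hsv(np.clip(img, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * sat, 0, 1)
        img = hsv2rgb(hsv)

    # geometric ---------------------------------------------------------
    rot = np.deg2rad(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
    scale = rng.uniform(*cfg.scale_range)
    H, W = msk.shape
    ty = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * H
    tx = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * W
    if rot != 0.0 or scale != 1.0 or tx != 0.0 or ty != 0.0:
        centre = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        tf = (AffineTransform(translation=-centre)
              + AffineTransform(rotation=rot, scale=scale)
              + AffineTransform(translation=centre + (tx, ty)))
        img = warp(img, tf.inverse, order=1, mode="reflect",
                   preserve_range=True)
        msk = warp(msk.astype(np.float64), tf.inverse, order=0,
                   mode="constant", cval=0, preserve_range=True)
    if rng.random() < cfg.flip_prob:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < cfg.flip_prob:
        img, msk = img[::-1], msk[::-1]
    return (np.clip(img, 0.0, 1.0),
            (np.asarray(msk) > 0.5).astype(np.uint8))


# ---------------------------------------------------------------------------
# polygon annotations (labelme-style)
# ---------------------------------------------------------------------------

def polygons_to_mask(polygons, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterise a union of polygons; a pixel is foreground iff its centre
    ``(col + 0.5, row + 0.5)`` lies inside or on any polygon (even-odd rule,
    so self-intersecting rings are handled consistently)."""
    H, W = image_size
    mask = np.zeros((H, W), dtype=bool)
    px = np.arange(W) + 0.5
    py = np.arange(H) + 0.5
    X, Y = np.meshgrid(px, py)
    for poly in polygons:
        pts = np.asarray(poly, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise ValueError("each polygon needs >= 3 (x, y) vertices")
        inside = np.zeros((H, W), dtype=bool)
        on_edge = np.zeros((H, W), dtype=bool)
        n = pts.shape[0]
        for i in range(n):
            x1, y1 = pts[i]
            x2, y2 = pts[(i + 1) % n]
            # even-odd ray cast along +x
            cond = (y1 > Y) != (y2 > Y)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
            inside ^= cond & (X < xint)
            # points lying on the segment count as foreground
            dx, dy = x2 - x1, y2 - y1
            seg2 = dx * dx + dy * dy
            if seg2 == 0:
                continue
            t = ((X - x1) * dx + (Y - y1) * dy) / seg2
            t = np.clip(t, 0.0, 1.0)
            d2 = (X - (x1 + t * dx)) ** 2 + (Y - (y1 + t * dy)) ** 2
            on_edge |= d2 < 1e-18
        mask |= inside | on_edge
    return mask.astype(np.uint8)


def read_labelme_json(path: str | Path):
    """Extract polygon vertex lists from a labelme-style JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    return [shape["points"] for shape in doc.get("shapes", [])
            if shape.get("shape_type", "polygon") == "polygon"]


# ---------------------------------------------------------------------------
# image / mask / manifest I/O
# ---------------------------------------------------------------------------

def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an [0, 1] float RGB image as 8-bit PNG/TIFF."""
    arr = (np.clip(image, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit image as (H, W, 3) float in [0, 1]."""
    if str(path).lower().endswith((".tif", ".tiff")):
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    return arr.astype(np.float64) / 255.0


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG (0 background, 255 foreground)."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG; any value > 0 counts as foreground."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 0).astype(np.uint8)


def write_manifest(path: str | Path, pairs) -> None:
    """Write a dataset manifest: one "image<TAB>mask" pair per line."""
    with open(path, "w") as fh:
        for img, msk in pairs:
            fh.write(f"{img}\t{msk}\n")


def read_manifest(path: str | Path):
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            img, msk = line.split("\t")
            pairs.append((img, msk))
    return pairs


def make_fixture_dir(out_dir: str | Path, n: int, seed: int,
                     cfg: SynthConfig | None = None,
                     negative_fraction: float = 0.75) -> Path:
    """Render ``n`` synthetic patches into ``out_dir`` with a manifest."""
    cfg = cfg or SynthConfig()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    pairs = []
    data = generate_dataset(cfg, n, base_seed=seed,
                            negative_fraction=negative_fraction)
    for i, (img, msk) in enumerate(data):
        ip = out / "images" / f"patch_{i:04d}.png"
        mp = out / "masks" / f"patch_{i:04d}.png"
        save_image(ip, img)
        save_mask(mp, msk)
        pairs.append((ip, mp))
    manifest = out / "manifest.tsv"
    write_manifest(manifest, pairs)
    return manifest
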