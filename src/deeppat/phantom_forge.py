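"""Synthetic mouse-cross-section phantoms, augmentation and dataset plumbing.

A phantom emulates the visual statistics of a small-animal photoacoustic
cross section: a bright elliptical body outline (skin/rib line), a handful
of filled elliptical organ blobs at distinct intensities, one or two thin
curvilinear vessel-like structures, and a smooth dim background.  All
features are placed so that, after normalization to [-1, 1], the background
is strictly negative and every feature is strictly positive and pairwise
disconnected — which makes simple connected-component accounting of the
generated content possible in tests and demos.

Nothing here simulates optics or acoustics; the phantoms exist so the full
measurement -> proxy -> network pipeline can be exercised without any
external dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize, rotate as _sk_rotate

from .errors import InvalidArgumentError, InvalidGeometryError

__all__ = [
    "Phantom",
    "AugmentationSpec",
    "DatasetSplit",
    "generate_phantom",
    "augment",
    "normalize",
    "split_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass
class Phantom:
    """A square grayscale reconstruction target with values in [-1, 1]."""

    pixels: np.ndarray
    side_length: int
    label: str = ""
    #: feature bookkeeping written by :func:`generate_phantom`
    #: (keys: n_blobs, n_vessels); empty for externally loaded images.
    features: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise InvalidArgumentError("phantom pixels must be a square 2-D array")
        if self.side_length != self.pixels.shape[0]:
            raise InvalidArgumentError("side_length disagrees with the pixel array")


@dataclass(frozen=True)
class AugmentationSpec:
    """Rotations (degrees), flips, and an optional center crop.

    ``crop_fraction`` < 1 adds, for every rotated/flipped variant, a center
    crop of that linear fraction resized back to the original side.  Flips
    are involutions and rotation by 0 degrees is the identity, so the
    identity spec reproduces the input exactly.
    """

    rotation_degrees: tuple = (0.0,)
    flips: tuple = ()
    crop_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.crop_fraction <= 1.0):
            raise InvalidArgumentError("crop_fraction must lie in (0, 1]")
        for f in self.flips:
            if f not in ("horizontal", "vertical"):
                raise InvalidArgumentError(f"unknown flip {f!r}")

    @property
    def output_count(self) -> int:
        base = len(self.rotation_degrees) * (1 + len(self.flips))
        return base * (2 if self.crop_fraction < 1.0 else 1)


@dataclass
class DatasetSplit:
    train: list
    test: list
    train_fraction: float


def _smooth_background(rng: np.random.Generator, n: int) -> np.ndarray:
    """Dim smooth field in [-1.0, -0.7]: low-frequency cosine mixture."""
    yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    f = np.zeros((n, n))
    for _ in range(3):
        fx, fy = rng.uniform(0.5, 2.0, size=2)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        f += np.cos(2 * np.pi * fx * xx + ph[0]) * np.cos(2 * np.pi * fy * yy + ph[1])
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return -1.0 + 0.3 * f


def _ellipse_mask(n, cy, cx, ry, rx, angle):
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _dilate(mask: np.ndarray, it: int = 1) -> np.ndarray:
    m = mask.copy()
    for _ in range(it):
        grown = m.copy()
        grown[1:, :] |= m[:-1, :]
        grown[:-1, :] |= m[1:, :]
        grown[:, 1:] |= m[:, :-1]
        grown[:, :-1] |= m[:, 1:]
        m = grown
    return m

def generate_phantom(side_length: int, complexity: int, seed: int) -> Phantom:
    """Generate one synthetic cross-section phantom.

    Parameters
    ----------
    side_length : int
        Image side N (pixels), at least 16.
    complexity : int
        Number of interior organ blobs (>= 0).
    seed : int
        Fixes all randomness; identical calls are bit-identical.

    The result contains exactly one bright body outline (an elliptical
    ring), ``complexity`` organ blobs at distinct positive intensities, and
    at least one thin vessel curve; all bright features are separated from
    each other by at least one background pixel.
    """
    if side_length < 16:
        raise InvalidGeometryError("side_length must be >= 16")
    if complexity < 0:
        raise InvalidArgumentError("complexity must be non-negative")
    rng = np.random.default_rng(seed)
    n = side_length
    img = _smooth_background(rng, n)

    cy, cx = n / 2 + rng.uniform(-n / 32, n / 32, size=2)
    ry = n * rng.uniform(0.40, 0.45)
    rx = n * rng.uniform(0.33, 0.38)
    body_angle = rng.uniform(0, np.pi)
    thick = max(1.0, n / 40)
    outer = _ellipse_mask(n, cy, cx, ry, rx, body_angle)
    inner = _ellipse_mask(n, cy, cx, ry - thick, rx - thick, body_angle)
    ring = outer & ~inner
    img[ring] = 0.9

    # bright features must stay disconnected: occupied = dilation of all
    # features so far; a candidate is rejected if it touches it.
    occupied = _dilate(ring, 2)
    interior = _ellipse_mask(n, cy, cx, ry - 3 * thick, rx - 3 * thick, body_angle)

    n_blobs = 0
    intensities = 0.30 + 0.5 * (np.arange(max(complexity, 1)) % 5) / 4.0
    for b in range(complexity):
        placed = False
        for _ in range(60):
            bry = rng.uniform(n / 16, n / 9)
            brx = rng.uniform(n / 16, n / 9)
            bcy = rng.uniform(cy - ry + 2 * bry, cy + ry - 2 * bry)
            bcx = rng.uniform(cx - rx + 2 * brx, cx + rx - 2 * brx)
            cand = _ellipse_mask(n, bcy, bcx, bry, brx, rng.uniform(0, np.pi))
            if cand.any() and (cand <= interior).all() and not (cand & occupied).any():
                img[cand] = intensities[b]
                occupied |= _dilate(cand, 2)
                n_blobs += 1
                placed = True
                break
        if not placed:
            # shrink until it fits somewhere deterministic near the center
            cand = _ellipse_mask(n, cy, cx, n / 24, n / 24, 0.0)
            if not (cand & occupied).any():
                img[cand] = intensities[b]
                occupied |= _dilate(cand, 2)
                n_blobs += 1

    n_vessels = 0
    for _ in range(40):
        if n_vessels >= 1 + (complexity > 1):
            break
        # quadratic Bezier curve inside the interior region
        pts = []
        for _ in range(3):
            a = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0.2, 0.85)
            pts.append((cy + r * (ry - 3 * thick) * np.sin(a),
                        cx + r * (rx - 3 * thick) * np.cos(a)))
        t = np.linspace(0, 1, 6 * n)
        (y0, x0), (y1, x1), (y2, x2) = pts
        ys = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * y1 + t**2 * y2
        xs = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * x1 + t**2 * x2
        cand = np.zeros((n, n), dtype=bool)
        iy = np.clip(np.round(ys).astype(int), 0, n - 1)
        ix = np.clip(np.round(xs).astype(int), 0, n - 1)
        cand[iy, ix] = True
        if cand.sum() < n // 8:
            continue
        if (cand <= interior).all() and not (cand & occupied).any():
            img[cand] = 1.0
            occupied |= _dilate(cand, 1)
            n_vessels += 1

    if n_vessels == 0:
        # deterministic fallback: find the longest free horizontal run in
        # the interior and lay a gently wavy vessel along it
        free = interior & ~occupied
        best = (0, 0, 0)  # (length, row, start)
        for row in range(n):
            run = 0
            for col in range(n):
                run = run + 1 if free[row, col] else 0
                if run > best[0]:
                    best = (run, row, col - run + 1)
        length, row, start = best
        if length >= 5:
            cols = np.arange(start + 1, start + length - 1)
            wave = np.round(np.sin(cols / max(4.0, n / 10))).astype(int)
            rows = np.clip(row + wave, 0, n - 1)
            # fall back to the guaranteed-free base row where the wavy
            # offset would collide; keeps the curve 8-connected
            rows = np.where(free[rows, cols], rows, row)
            cand = np.zeros((n, n), dtype=bool)
            cand[rows, cols] = True
            if cand.any():
                img[cand] = 1.0
                occupied |= _dilate(cand, 1)
                n_vessels += 1

    pixels = np.clip(img, -1.0, 1.0)
    ph = normalize(pixels)
    ph.label = f"synthetic/side={n}/complexity={complexity}/seed={seed}"
    ph.features = {"n_blobs": n_blobs, "n_vessels": n_vessels}
    return ph


def normalize(image: np.ndarray) -> Phantom:
    """Affinely map an arbitrary 2-D array onto [-1, 1] (min -> -1, max -> +1).

    A constant image has no range to stretch; it maps to all zeros with a
    warning instead of raising, so batch pipelines keep running.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidArgumentError("normalize expects a 2-D array")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        warnings.warn("constant image normalized to zeros", stacklevel=2)
        out = np.zeros_like(arr)
    else:
        out = 2.0 * (arr - lo) / (hi - lo) - 1.0
    return Phantom(pixels=out, side_length=arr.shape[0], label="normalized")


def _apply_rotation(px: np.ndarray, deg: float) -> np.ndarray:
    deg = float(deg) % 360.0
    if deg in (0.0, 90.0, 180.0, 270.0):
        return np.rot90(px, k=int(deg // 90))
    # bilinear interpolation, zero padding outside the support
    return _sk_rotate(px, deg, resize=False, order=1, mode="constant", cval=0.0,
                      preserve_range=True)


def _apply_flip(px: np.ndarray, flip: str) -> np.ndarray:
    return px[:, ::-1] if flip == "horizontal" else px[::-1, :]


def _center_crop_resize(px: np.ndarray, fraction: float) -> np.ndarray:
    n = px.shape[0]
    m = max(2, int(round(n * fraction)))
    off = (n - m) // 2
    crop = px[off:off + m, off:off + m]
    out = resize(crop, (n, n), order=1, mode="edge", anti_aliasing=False,
                 preserve_range=True)
    return np.clip(out, -1.0, 1.0)


def augment(image: Phantom, spec: AugmentationSpec) -> list:
    """Expand one phantom into its rotated / flipped / cropped variants.

    Output count is ``|rotations| * (1 + |flips|)``, doubled when
    ``crop_fraction < 1``.  Every output satisfies the [-1, 1] invariant;
    right-angle rotations and flips are exact index permutations.
    """
    px = image.pixels
    base_variants = []
    for deg in spec.rotation_degrees:
        r = _apply_rotation(px, deg)
        base_variants.append((f"rot{deg}", r))
        for flip in spec.flips:
            base_variants.append((f"rot{deg}+{flip}", _apply_flip(r, flip)))
    out = []
    for tag, arr in base_variants:
        out.append(Phantom(np.clip(arr, -1, 1).copy(), image.side_length,
                           label=f"{image.label}|{tag}"))
        if spec.crop_fraction < 1.0:
            c = _center_crop_resize(arr, spec.crop_fraction)
            out.append(Phantom(c, image.side_length,
                               label=f"{image.label}|{tag}+crop{spec.crop_fraction}"))
    return out


def split_dataset(phantoms: list, train_fraction: float, seed: int) -> DatasetSplit:
    """Random disjoint train/test partition, reproducible under ``seed``.

    The train size is ``round(train_fraction * len(phantoms))``, so 1130
    phantoms at fraction 0.8 give the 904/226 partition.
    """
    if not phantoms:
        raise InvalidArgumentError("cannot split an empty phantom list")
    if not (0.0 < train_fraction < 1.0):
        raise InvalidArgumentError("train_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(phantoms))
    n_train = int(round(train_fraction * len(phantoms)))
    n_train = min(max(n_train, 1), len(phantoms) - 1)
    train = [phantoms[i] for i in order[:n_train]]
    test = [phantoms[i] for i in order[n_train:]]
    return DatasetSplit(train=train, test=test, train_fraction=train_fraction)


def save_dataset(split: DatasetSplit, directory) -> Path:
    """Persist a split as 16-bit PNGs plus a JSON manifest."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"train": [], "test": [], "train_fraction": split.train_fraction}
    for part in ("train", "test"):
        for k, ph in enumerate(getattr(split, part)):
            name = f"{part}_{k:05d}.png"
            u16 = np.round((ph.pixels + 1.0) / 2.0 * 65535).astype(np.uint16)
            iio.imwrite(directory / name, u16)
            manifest[part].append({"file": name, "label": ph.label,
                                   "side_length": ph.side_length})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory / "manifest.json"


def load_dataset(directory) -> DatasetSplit:
    import imageio.v3 as iio

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    parts = {}
    for part in ("train", "test"):
        items = []
        for rec in manifest[part]:
            u16 = iio.imread(directory / rec["file"]).astype(np.float64)
            px = u16 / 65535 * 2.0 - 1.0
            items.append(Phantom(px, rec["side_length"], label=rec["label"]))
        parts[part] = items
    return DatasetSplit(train=parts["train"], test=parts["test"],
                        train_fraction=manifest["train_fraction"])
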