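"""Slide tiling, tissue filtering and stain color normalization.

Slides are cut into non-overlapping 224x224 patches at a 20x-equivalent
resolution. Two cheap rules then drop patches irrelevant to diagnosis:

* **background** — textureless bright-field regions, detected by counting
  Canny edge pixels on the grayscale patch; a patch with fewer than 23
  edge pixels is background (strict ``<``);
* **blood** — hemorrhage, detected in HSV space: a patch is blood when at
  least half its pixels fall inside a saturated-red hue/saturation/value
  box.

External cohorts scanned elsewhere can additionally be color-normalized
(Reinhard-style channel-statistics matching in CIELAB) to a reference
color distribution fitted on kept in-house patches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color as skcolor
from skimage import feature as skfeature

PATCH_SIZE = 224

PatchStatus = str  # "kept" | "background" | "blood"


@dataclass
class FilterConfig:
    """Thresholds for the background and blood patch filters.

    Hue is on the 0-179 scale, saturation/value on 0-255; the two hue
    intervals cover the red wrap-around.
    """

    edge_count_threshold: int = 23
    blood_hue_bounds: tuple[tuple[float, float], tuple[float, float]] = ((0, 10), (160, 179))
    blood_saturation_min: float = 100.0
    blood_value_min: float = 60.0
    blood_pixel_fraction: float = 0.5
    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.edge_count_threshold < 0:
            raise ValueError("edge_count_threshold must be >= 0")
        for lo, hi in self.blood_hue_bounds:
            if lo > hi:
                raise ValueError("hue bounds must be ordered low <= high")
        if not (0.0 < self.blood_pixel_fraction <= 1.0):
            raise ValueError("blood_pixel_fraction must lie in (0, 1]")


@dataclass
class PatchGridEntry:
    row: int
    col: int
    x0: int
    y0: int
    status: PatchStatus = "kept"


@dataclass
class PatchGrid:
    """Tiling of one slide: grid entries with pixel offsets and statuses."""

    slide_id: str
    patch_size: int
    entries: list[PatchGridEntry] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.entries:
            return (0, 0)
        return (
            max(e.row for e in self.entries) + 1,
            max(e.col for e in self.entries) + 1,
        )

    def kept(self) -> list[PatchGridEntry]:
        return [e for e in self.entries if e.status == "kept"]

    def status_counts(self) -> dict[str, int]:
        counts = {"kept": 0, "background": 0, "blood": 0}
        for e in self.entries:
            counts[e.status] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": self.slide_id,
                "row": [e.row for e in self.entries],
                "col": [e.col for e in self.entries],
                "x0": [e.x0 for e in self.entries],
                "y0": [e.y0 for e in self.entries],
                "status": [e.status for e in self.entries],
            }
        )


def _validate_patch(patch: np.ndarray, patch_size: int | None = None) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("patch must be an H x W x 3 RGB array")
    if patch_size is not None and patch.shape[:2] != (patch_size, patch_size):
        raise ValueError(f"patch must be {patch_size} x {patch_size}, got {patch.shape[:2]}")
    return patch


def load_image(path: str | Path) -> np.ndarray:
    """Read a plain PNG/TIFF image as an RGB uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def downsample_to_20x(image: np.ndarray, native_magnification: float) -> np.ndarray:
    """Block-average an image from its native objective power down to 20x."""
    if native_magnification == 20:
        return image
    factor = native_magnification / 20.0
    if factor < 1 or abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"native magnification {native_magnification} is not an integer "
            "multiple of the 20x target"
        )
    f = int(round(factor))
    H, W = (image.shape[0] // f) * f, (image.shape[1] // f) * f
    blocks = image[:H, :W].astype(np.float64).reshape(H // f, f, W // f, f, 3)
    return np.clip(np.rint(blocks.mean(axis=(1, 3))), 0, 255).astype(np.uint8)


def tile_slide(
    image: np.ndarray,
    slide_id: str = "slide",
    patch_size: int = PATCH_SIZE,
    native_magnification: float = 20,
) -> tuple[PatchGrid, list[np.ndarray]]:
    """Cut a slide into non-overlapping ``patch_size`` square patches at 20x.

    Right/bottom remainder strips smaller than one patch are dropped (floor
    tiling, no padding); every patch starts with status ``kept``.
    """
    image = _validate_patch(image)
    image = downsample_to_20x(image, native_magnification)
    H, W = image.shape[:2]
    n_rows, n_cols = H // patch_size, W // patch_size
    if n_rows < 1 or n_cols < 1:
        raise ValueError(
            f"image of {H}x{W} at 20x is smaller than one {patch_size}px patch"
        )
    grid = PatchGrid(slide_id=slide_id, patch_size=patch_size)
    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * patch_size, c * patch_size
            grid.entries.append(PatchGridEntry(row=r, col=c, x0=x0, y0=y0))
            patches.append(image[y0 : y0 + patch_size, x0 : x0 + patch_size])
    return grid, patches


def count_edge_pixels(patch: np.ndarray, config: FilterConfig | None = None) -> int:
    """Number of Canny edge pixels on the grayscale patch."""
    config = config or FilterConfig()
    patch = _validate_patch(patch)
    gray = skcolor.rgb2gray(patch) * 255.0
    edges = skfeature.canny(
        gray,
        sigma=config.canny_sigma,
        low_threshold=config.canny_low,
        high_threshold=config.canny_high,
    )
    return int(edges.sum())


def is_background(patch: np.ndarray, config: FilterConfig | None = None) -> bool:
    """Textureless background: strictly fewer edge pixels than the threshold."""
    config = config or FilterConfig()
    return count_edge_pixels(patch, config) < config.edge_count_threshold


def blood_pixel_mask(patch: np.ndarray, config: FilterConfig | None = None) -> np.ndarray:
    """Boolean mask of pixels inside the configured blood HSV box."""
    config = config or FilterConfig()
    patch = _validate_patch(patch)
    hsv = skcolor.rgb2hsv(patch)
    h = hsv[..., 0] * 179.0
    s = hsv[..., 1] * 255.0
    v = hsv[..., 2] * 255.0
    in_hue = np.zeros(h.shape, dtype=bool)
    for lo, hi in config.blood_hue_bounds:
        in_hue |= (h >= lo) & (h <= hi)
    return in_hue & (s >= config.blood_saturation_min) & (v >= config.blood_value_min)


def is_blood(patch: np.ndarray, config: FilterConfig | None = None) -> bool:
    config = config or FilterConfig()
    return float(blood_pixel_mask(patch, config).mean()) >= config.blood_pixel_fraction


def filter_patches(
    grid: PatchGrid,
    patches: list[np.ndarray],
    config: FilterConfig | None = None,
) -> PatchGrid:
    """Assign each grid entry a status: background first, then blood, else kept.

    Statuses are mutually exclusive and the assignment is deterministic and
    independent across patches.
    """
    config = config or FilterConfig()
    if len(grid.entries) != len(patches):
        raise ValueError("grid and patch list are misaligned")
    for entry, patch in zip(grid.entries, patches):
        if is_background(patch, config):
            entry.status = "background"
        elif is_blood(patch, config):
            entry.status = "blood"
        else:
            entry.status = "kept"
    return grid


# ---------------------------------------------------------------------------
# Reinhard-style color normalization
# ---------------------------------------------------------------------------


@dataclass
class ColorReferenceStats:
    """Per-channel mean and SD in CIELAB, fitted from reference patches."""

    mean: np.ndarray  # (3,)
    sd: np.ndarray  # (3,)


def fit_color_reference(patches: list[np.ndarray]) -> ColorReferenceStats:
    """Fit the reference color distribution from kept reference patches."""
    if not patches:
        raise ValueError("need at least one reference patch")
    lab = np.concatenate(
        [skcolor.rgb2lab(_validate_patch(p)).reshape(-1, 3) for p in patches]
    )
    return ColorReferenceStats(mean=lab.mean(axis=0), sd=lab.std(axis=0))


def normalize_color(patch: np.ndarray, reference: ColorReferenceStats) -> np.ndarray:
    """Match the patch's per-channel CIELAB statistics to the reference.

    A fixed point of its own statistics: normalizing the reference patch
    against stats fitted on itself returns it unchanged (within 8-bit
    rounding). Degenerate patches with a zero-variance channel are
    returned unchanged with a warning.
    """
    patch = _validate_patch(patch)
    lab = skcolor.rgb2lab(patch)
    mean = lab.reshape(-1, 3).mean(axis=0)
    sd = lab.reshape(-1, 3).std(axis=0)
    if np.any(sd < 1e-12):
        warnings.warn("degenerate patch with zero color variance; returned unchanged")
        return patch.copy()
    out = (lab - mean) / sd * reference.sd + reference.mean
    rgb = skcolor.lab2rgb(out)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
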