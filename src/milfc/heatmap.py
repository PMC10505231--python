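"""Slide heatmaps and representative-patch extraction.

Each kept patch gets a patch-level FC value (the sigmoid of its raw
score, so values live in (0, 1) like the slide label): low values mean
copy-number loss and are drawn red, high values mean intact and are drawn
blue; patches omitted by the tissue filters (background, blood) are drawn
a fixed purple. The 100 highest- and lowest-scoring patches are exported
with their grid/pixel locations as the slide's representative evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .bags import sigmoid
from .wsi import PatchGrid

RED = np.array([220, 20, 20], dtype=np.uint8)  # fc = 0, loss
BLUE = np.array([20, 20, 220], dtype=np.uint8)  # fc = 1, intact
PURPLE = np.array([128, 0, 128], dtype=np.uint8)  # omitted patches


def patch_fc_values(patch_scores: np.ndarray) -> np.ndarray:
    """Map raw patch scores to patch-level FC values in (0, 1)."""
    patch_scores = np.asarray(patch_scores, dtype=np.float64)
    if not np.all(np.isfinite(patch_scores)):
        raise ValueError("patch scores must be finite")
    return sigmoid(patch_scores)


def fc_to_color(fc: np.ndarray) -> np.ndarray:
    """Linear red -> blue interpolation over fc in [0, 1]."""
    fc = np.clip(np.asarray(fc, dtype=np.float64), 0.0, 1.0)
    mixed = (1.0 - fc)[..., None] * RED.astype(float) + fc[..., None] * BLUE.astype(float)
    return np.rint(mixed).astype(np.uint8)


@dataclass
class Heatmap:
    cells: np.ndarray  # (rows, cols, 3) uint8
    values: pd.DataFrame  # row, col, status, fc

    def save_png(self, path: str | Path, scale: int = 16) -> Path:
        """Write the heatmap as a PNG, one ``scale``-pixel block per cell."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        img = np.kron(self.cells, np.ones((scale, scale, 1), dtype=np.uint8))
        Image.fromarray(img).save(path)
        return path


def render_heatmap(grid: PatchGrid, patch_fc: np.ndarray) -> Heatmap:
    """Color every grid cell: gradient for kept cells, purple for omitted.

    ``patch_fc`` holds one FC value in [0, 1] per *kept* cell, in grid
    order (row-major over kept entries).
    """
    patch_fc = np.asarray(patch_fc, dtype=np.float64)
    kept = grid.kept()
    if patch_fc.shape != (len(kept),):
        raise ValueError(
            f"got {patch_fc.shape[0] if patch_fc.ndim else 0} fc values for "
            f"{len(kept)} kept cells"
        )
    rows, cols = grid.shape
    cells = np.tile(PURPLE, (rows, cols, 1))
    records = []
    it = iter(patch_fc)
    for entry in grid.entries:
        if entry.status == "kept":
            fc = float(next(it))
            cells[entry.row, entry.col] = fc_to_color(np.array(fc))
        else:
            fc = float("nan")
        records.append((entry.row, entry.col, entry.status, fc))
    values = pd.DataFrame(records, columns=["row", "col", "status", "fc"])
    return Heatmap(cells=cells, values=values)


def representative_patches(
    patch_scores: np.ndarray,
    coords: np.ndarray,
    k: int = 100,
) -> pd.DataFrame:
    """Locations of the ``min(k, P)`` highest and lowest scoring patches.

    Each side is sorted by extremity (rank 1 = most extreme); ties prefer
    the lower patch index. When ``P < 2k`` the two sides may overlap.
    Columns: rank, side (high/low), row, col, x0, y0, score.
    """
    scores = np.asarray(patch_scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("patch_scores must be a non-empty vector")
    coords = np.asarray(coords)
    if coords.shape != (scores.size, 4):
        raise ValueError("coords must be (P, 4) aligned with patch_scores")
    m = min(k, scores.size)
    order_desc = np.argsort(-scores, kind="stable")
    order_asc = np.argsort(scores, kind="stable")
    records = []
    for side, order in (("high", order_desc[:m]), ("low", order_asc[:m])):
        for rank, i in enumerate(order, start=1):
            r, c, x0, y0 = coords[i]
            records.append((rank, side, int(r), int(c), int(x0), int(y0), float(scores[i])))
    return pd.DataFrame(records, columns=["rank", "side", "row", "col", "x0", "y0", "score"])
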