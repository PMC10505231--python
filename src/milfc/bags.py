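"""Core containers shared across the pipeline.

A slide is represented as a *bag* of patch feature vectors plus the grid
coordinates the patches came from; all downstream models (patch scorer,
min-max aggregator, fusion classifier) operate on bags, never on pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ARMS = ("1p", "19q")

#: column order of the per-patch coordinate table carried with every bag
COORD_COLUMNS = ("row", "col", "x0", "y0")


@dataclass
class FeatureBag:
    """Per-slide matrix of patch feature vectors with patch grid coordinates.

    Parameters
    ----------
    slide_id : str
        Identifier of the slide the patches came from.
    features : ndarray of shape (P, D)
        One fixed-length feature vector per kept patch.
    coords : ndarray of shape (P, 4)
        ``(row, col, x0, y0)`` per patch: grid indices and pixel offsets of
        the patch's top-left corner in the source image.
    extractor_id : str
        Name of the (frozen) feature extractor that produced the rows.
    normalization_id : str
        Name of the pixel normalization applied before extraction.
    """

    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    extractor_id: str = "unknown"
    normalization_id: str = "none"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a (P, D) matrix with P >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"bag {self.slide_id!r} contains non-finite features")
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.coords.shape != (self.features.shape[0], 4):
            raise ValueError("coords must align 1:1 with feature rows as (P, 4)")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.features.shape[1]

    def save(self, path: str | Path) -> Path:
        """Write the bag as a keyed-array ``.npz`` file (features + coords)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path,
            features=self.features,
            coords=self.coords,
            slide_id=np.array(self.slide_id),
            extractor_id=np.array(self.extractor_id),
            normalization_id=np.array(self.normalization_id),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureBag":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                slide_id=str(z["slide_id"]),
                features=z["features"],
                coords=z["coords"],
                extractor_id=str(z["extractor_id"]),
                normalization_id=str(z["normalization_id"]),
            )


@dataclass
class SlidePrediction:
    """Model output for one slide: two arm-level FC estimates, per-patch
    scores (kept for visualization) and, once fused, an oligodendroglioma
    probability."""

    slide_id: str
    fc_1p_hat: float
    fc_19q_hat: float
    patch_scores_1p: np.ndarray = field(repr=False)
    patch_scores_19q: np.ndarray = field(repr=False)
    prob_oligo: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("fc_1p_hat", "fc_19q_hat"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside the open interval (0, 1)")


def predictions_to_frame(preds: list[SlidePrediction]) -> pd.DataFrame:
    """Tabulate slide predictions in the on-disk CSV layout."""
    return pd.DataFrame(
        {
            "slide_id": [p.slide_id for p in preds],
            "fc_1p_hat": [p.fc_1p_hat for p in preds],
            "fc_19q_hat": [p.fc_19q_hat for p in preds],
            "prob_oligo": [p.prob_oligo for p in preds],
        }
    )


def sigmoid(x):
    """Numerically stable logistic function (scalar in, scalar out)."""
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out[0]) if scalar else out
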