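"""Frozen patch feature extraction with offline caching.

Feature extraction is the expensive, pretrained part of the pipeline and
is treated as a frozen black box behind :class:`ExtractorSpec`: pixels in,
a fixed-length vector per patch out, never updated during training.
Features are extracted once and cached to disk keyed by
``(slide_id, extractor_id)`` so downstream training never touches pixels.

Because pretrained histopathology encoder weights are not distributed with
this package, a deterministic *stub* extractor (seeded Gaussian random
projection of the downsampled, channel-normalized patch, followed by tanh)
stands in for the encoder so the full pipeline is runnable and testable
end to end. A real encoder can be registered as a plugin with the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from skimage.transform import resize

from .bags import FeatureBag

#: conventional ImageNet per-channel normalization constants
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_SD = (0.229, 0.224, 0.225)

_STUB_DOWNSAMPLE = 32  # stub works on 32x32 thumbnails


@dataclass(frozen=True)
class ExtractorSpec:
    """Identity and configuration of a frozen feature extractor."""

    name: str = "stub"
    output_dim: int = 2048
    input_mean: tuple[float, float, float] = IMAGENET_MEAN
    input_sd: tuple[float, float, float] = IMAGENET_SD
    seed: int = 0
    frozen: bool = True

    def __post_init__(self) -> None:
        if self.output_dim < 2:
            raise ValueError("output_dim must be >= 2")
        if not self.frozen:
            raise ValueError("extractors are frozen by contract")

    @property
    def extractor_id(self) -> str:
        return f"{self.name}-d{self.output_dim}-s{self.seed}"


def normalize_patch(patch: np.ndarray, spec: ExtractorSpec) -> np.ndarray:
    """Scale 8-bit pixels to [0, 1] then apply per-channel normalization."""
    x = np.asarray(patch, dtype=np.float64) / 255.0
    return (x - np.asarray(spec.input_mean)) / np.asarray(spec.input_sd)


def _stub_projection(seed: int, output_dim: int) -> np.ndarray:
    n_in = _STUB_DOWNSAMPLE * _STUB_DOWNSAMPLE * 3
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_in, output_dim)) / np.sqrt(n_in)


def stub_extractor(patch: np.ndarray, seed: int = 0, output_dim: int = 2048) -> np.ndarray:
    """Deterministic stand-in feature vector for one normalized patch.

    The patch is downsampled to 32x32, flattened, passed through a fixed
    seed-generated Gaussian projection to ``output_dim`` dimensions, and
    squashed elementwise with tanh. Deterministic in ``(patch, seed)``.
    """
    patch = np.asarray(patch, dtype=np.float64)
    small = resize(patch, (_STUB_DOWNSAMPLE, _STUB_DOWNSAMPLE, 3), anti_aliasing=True)
    return np.tanh(small.reshape(-1) @ _stub_projection(seed, output_dim))


# plugin registry for real encoders; values map a normalized patch to a vector
_EXTRACTORS: dict[str, Callable[[np.ndarray, ExtractorSpec], np.ndarray]] = {}


def register_extractor(name: str, fn: Callable[[np.ndarray, ExtractorSpec], np.ndarray]) -> None:
    _EXTRACTORS[name] = fn


def _apply_extractor(patch: np.ndarray, spec: ExtractorSpec) -> np.ndarray:
    normalized = normalize_patch(patch, spec)
    if spec.name == "stub":
        return stub_extractor(normalized, seed=spec.seed, output_dim=spec.output_dim)
    if spec.name in _EXTRACTORS:
        return _EXTRACTORS[spec.name](normalized, spec)
    raise KeyError(
        f"extractor {spec.name!r} is not registered; known: "
        f"{['stub', *sorted(_EXTRACTORS)]}"
    )


def extract_features(
    patches: list[np.ndarray],
    spec: ExtractorSpec,
    slide_id: str = "slide",
    coords: np.ndarray | None = None,
    cache_dir: str | Path | None = None,
) -> FeatureBag:
    """Extract one feature vector per patch, hitting the cache when possible.

    The cache key is ``(slide_id, extractor_id)``; repeat calls return
    bit-identical matrices read back from disk.
    """
    if not patches:
        raise ValueError("no patches to extract")
    shapes = {p.shape for p in patches}
    if len(shapes) != 1:
        raise ValueError(f"patches must share one shape, got {sorted(shapes)}")
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"{slide_id}__{spec.extractor_id}.npz"
        if cache_path.exists():
            return FeatureBag.load(cache_path)

    feats = np.stack([_apply_extractor(p, spec) for p in patches])
    bad = np.nonzero(~np.isfinite(feats).all(axis=1))[0]
    if bad.size:
        raise ArithmeticError(
            f"extractor {spec.extractor_id!r} produced non-finite features for "
            f"patch index {int(bad[0])} of slide {slide_id!r}"
        )
    if coords is None:
        coords = np.zeros((len(patches), 4), dtype=np.int64)
        coords[:, 0] = np.arange(len(patches))
    bag = FeatureBag(
        slide_id=slide_id,
        features=feats,
        coords=coords,
        extractor_id=spec.extractor_id,
        normalization_id="imagenet",
    )
    if cache_dir is not None:
        bag.save(cache_path)
    return bag
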