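"""Synthetic slides with known ground truth.

Real cohorts for arm-level copy-number work are private, so every
downstream module here is exercised on simulated data with a known
generative recipe:

* **Feature bags** — isotropic Gaussian patch features in which a deleted
  chromosome arm plants a rank-1 mean shift on the tumor-cell patches.
  The two arms (1p, 19q) use orthogonal signal directions so the two
  estimators can learn independently.
* **Slide labels** — fold change (FC) of an arm is 1.0 in normal tissue.
  Hemizygous loss removes one of two copies in tumor cells only, so at
  tumor purity ``t`` the bulk FC of a deleted arm is ``1 - 0.5 t``: 0.5
  at full purity, 0.8 at purity 0.4, matching the range seen in
  sequencing of codeleted tumors.
* **Test images** — small RGB fixtures (textured H&E-like tissue, blank
  background, saturated blood) for the patch filters.

Everything is deterministic in the provided seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .bags import FeatureBag


class TumorType(str, Enum):
    ASTROCYTOMA = "astrocytoma"
    OLIGODENDROGLIOMA = "oligodendroglioma"


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Generative recipe for one synthetic slide.

    ``effect_size`` is the separation of the deleted-tumor patch mean from
    the background mean, in units of ``feature_noise_sd``.
    """

    n_patches: int
    tumor_purity: float
    deleted_1p: bool
    deleted_19q: bool
    feature_dim: int = 64
    effect_size: float = 2.0
    feature_noise_sd: float = 1.0
    label_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if not (0.0 <= self.tumor_purity <= 1.0):
            raise ValueError("tumor_purity must lie in [0, 1]")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if self.feature_noise_sd <= 0:
            raise ValueError("feature_noise_sd must be positive")
        if self.label_noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and label_noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    fc_1p: float
    fc_19q: float
    tumor_type: TumorType
    tumor_patch_indices: frozenset[int]
    deleted_1p: bool = False
    deleted_19q: bool = False


def signal_direction(arm: str, feature_dim: int) -> np.ndarray:
    """Unit signal direction for an arm; the two arms are orthogonal."""
    u = np.zeros(feature_dim)
    if arm == "1p":
        u[0] = 1.0
    elif arm == "19q":
        u[1] = 1.0
    else:
        raise ValueError(f"unknown arm {arm!r}")
    return u


def _noiseless_fc(deleted: bool, purity: float) -> float:
    # one of two alleles lost in tumor cells only
    return 1.0 - 0.5 * purity if deleted else 1.0


def simulate_slide(spec: SyntheticSlideSpec, slide_id: str = "synthetic") -> tuple[FeatureBag, GroundTruth]:
    """Draw one slide's feature bag and its ground-truth labels.

    ``round(t * n_patches)`` patches are tumor; when an arm is deleted their
    mean is shifted by ``effect_size * feature_noise_sd`` along that arm's
    signal direction (downwards, mirroring copy-number loss). The slide FC
    label is ``1 - 0.5 t`` for a deleted arm (1.0 otherwise) plus Gaussian
    label noise, clipped to (0, 1.5].
    """
    rng = np.random.default_rng(spec.seed)
    P, D = spec.n_patches, spec.feature_dim
    n_tumor = round(spec.tumor_purity * P)
    tumor_idx = rng.choice(P, size=n_tumor, replace=False)

    features = rng.normal(0.0, spec.feature_noise_sd, size=(P, D))
    shift = spec.effect_size * spec.feature_noise_sd
    for arm, deleted in (("1p", spec.deleted_1p), ("19q", spec.deleted_19q)):
        if deleted and n_tumor:
            features[tumor_idx] -= shift * signal_direction(arm, D)

    side = max(1, int(np.ceil(np.sqrt(P))))
    rows, cols = np.divmod(np.arange(P), side)
    coords = np.column_stack([rows, cols, cols * 224, rows * 224])

    fc = {}
    for arm, deleted in (("1p", spec.deleted_1p), ("19q", spec.deleted_19q)):
        v = _noiseless_fc(deleted, spec.tumor_purity)
        v += rng.normal(0.0, spec.label_noise_sd) if spec.label_noise_sd else 0.0
        fc[arm] = float(np.clip(v, np.finfo(float).tiny, 1.5))

    tumor_type = (
        TumorType.OLIGODENDROGLIOMA
        if (spec.deleted_1p and spec.deleted_19q)
        else TumorType.ASTROCYTOMA
    )
    bag = FeatureBag(
        slide_id=slide_id,
        features=features,
        coords=coords,
        extractor_id="synthetic",
        normalization_id="none",
    )
    truth = GroundTruth(
        fc_1p=fc["1p"],
        fc_19q=fc["19q"],
        tumor_type=tumor_type,
        tumor_patch_indices=frozenset(int(i) for i in tumor_idx),
        deleted_1p=spec.deleted_1p,
        deleted_19q=spec.deleted_19q,
    )
    return bag, truth


def _child_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0])


def simulate_cohort(
    n_slides: int,
    purity_range: tuple[float, float] = (0.4, 1.0),
    n_patches_range: tuple[int, int] = (200, 600),
    feature_dim: int = 64,
    effect_size: float = 2.0,
    feature_noise_sd: float = 1.0,
    label_noise_sd: float = 0.02,
    seed: int = 0,
) -> list[tuple[FeatureBag, GroundTruth]]:
    """Simulate a balanced cohort of oligodendroglioma / astrocytoma slides.

    Tumor types alternate (balanced to within one slide): oligodendroglioma
    slides have both arms deleted, astrocytoma slides both intact. Purities
    are uniform over ``purity_range``, bag sizes uniform over
    ``n_patches_range``; per-slide seeds derive deterministically from the
    master seed so the cohort is reproducible bit-identically.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    lo, hi = purity_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"invalid purity range {purity_range}")
    p_lo, p_hi = n_patches_range
    if not (1 <= p_lo <= p_hi):
        raise ValueError(f"invalid n_patches range {n_patches_range}")

    rng = np.random.default_rng(_child_seed(seed, n_slides))
    purities = rng.uniform(lo, hi, size=n_slides)
    sizes = rng.integers(p_lo, p_hi + 1, size=n_slides)

    cohort = []
    for i in range(n_slides):
        oligo = i % 2 == 0
        spec = SyntheticSlideSpec(
            n_patches=int(sizes[i]),
            tumor_purity=float(purities[i]),
            deleted_1p=oligo,
            deleted_19q=oligo,
            feature_dim=feature_dim,
            effect_size=effect_size,
            feature_noise_sd=feature_noise_sd,
            label_noise_sd=label_noise_sd,
            seed=_child_seed(seed, i),
        )
        cohort.append(simulate_slide(spec, slide_id=f"slide_{i:04d}"))
    return cohort


def cohort_labels(cohort: list[tuple[FeatureBag, GroundTruth]]) -> pd.DataFrame:
    """Cohort-level label table (slide_id, fc_1p, fc_19q, tumor_type)."""
    return pd.DataFrame(
        {
            "slide_id": [bag.slide_id for bag, _ in cohort],
            "fc_1p": [t.fc_1p for _, t in cohort],
            "fc_19q": [t.fc_19q for _, t in cohort],
            "tumor_type": [t.tumor_type.value for _, t in cohort],
        }
    )


def write_cohort(cohort: list[tuple[FeatureBag, GroundTruth]], out_dir: str | Path) -> Path:
    """Write one ``.npz`` feature container per slide plus a labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for bag, _ in cohort:
        bag.save(out_dir / f"{bag.slide_id}.npz")
    cohort_labels(cohort).to_csv(out_dir / "labels.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# RGB image fixtures for the patch filters
# ---------------------------------------------------------------------------

_IMAGE_KINDS = ("tissue", "background", "blood")


def simulate_test_image(kind: str, size: int = 224, seed: int = 0) -> np.ndarray:
    """Small RGB fixture of one of three kinds.

    * ``tissue`` — high-frequency texture in H&E-like purple/pink hues;
      passes both filters (kept).
    * ``background`` — near-uniform bright field; caught by the
      edge-pixel background filter.
    * ``blood`` — saturated red with strong brightness speckle (so it is
      textured, not background) caught by the HSV blood filter.
    """
    if kind not in _IMAGE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {_IMAGE_KINDS}")
    if size < 224:
        raise ValueError("size must be >= 224")
    rng = np.random.default_rng(seed)

    if kind == "background":
        base = np.full((size, size, 3), 238.0)
        img = base + rng.normal(0.0, 1.0, size=(size, size, 3))
    elif kind == "blood":
        # hue ~0 (red), high saturation; cell-scale brightness speckle plus
        # sparse bright fibrin flecks so the field is textured, not blank
        speckle = rng.uniform(0.45, 1.0, size=(size // 8, size // 8))
        speckle = np.kron(speckle, np.ones((8, 8)))[:size, :size]
        img = np.empty((size, size, 3))
        img[..., 0] = 205.0 * speckle
        img[..., 1] = 30.0 * speckle
        img[..., 2] = 30.0 * speckle
        fleck = rng.random((size // 2, size // 2)) < 0.015
        fleck = np.kron(fleck, np.ones((2, 2), dtype=bool))[:size, :size]
        img[fleck] = np.array([235.0, 225.0, 225.0])
        img += rng.normal(0.0, 3.0, size=img.shape)
    else:  # tissue
        # blotchy mix of hematoxylin purple and eosin pink with sharp nuclei
        field = rng.uniform(0.0, 1.0, size=(size // 8, size // 8))
        field = np.kron(field, np.ones((8, 8)))[:size, :size]
        purple = np.array([150.0, 100.0, 190.0])
        pink = np.array([235.0, 180.0, 215.0])
        img = field[..., None] * purple + (1.0 - field[..., None]) * pink
        nuclei = rng.random((size, size)) < 0.03
        img[nuclei] = np.array([90.0, 60.0, 130.0])
        img += rng.normal(0.0, 4.0, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
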