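"""Shared test helpers: tiny constructors and independent brute-force
oracles kept deliberately separate from the implementation paths they
check."""

import numpy as np

from milfc.bags import FeatureBag
from milfc.wsi import PatchGrid, PatchGridEntry


def make_bag(features, slide_id="t"):
    features = np.asarray(features, dtype=float)
    coords = np.zeros((features.shape[0], 4), dtype=int)
    coords[:, 0] = np.arange(features.shape[0])
    return FeatureBag(slide_id=slide_id, features=features, coords=coords)


def brute_force_extremes(scores, N):
    """Oracle for min-max selection: full stable sort, top and bottom
    blocks, cyclic recycling for short bags."""
    P = len(scores)
    desc = sorted(range(P), key=lambda i: (-scores[i], i))
    asc = sorted(range(P), key=lambda i: (scores[i], i))
    top = [scores[desc[i % P]] for i in range(N)]
    bottom = [scores[asc[i % P]] for i in range(N)][::-1]
    return np.array(top + bottom)


def auc_pair_counting_oracle(labels, scores):
    """Oracle for ROC AUC: count positive-negative pairs, ties half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def grid_with_statuses(statuses, cols=3):
    grid = PatchGrid(slide_id="s", patch_size=224)
    for i, status in enumerate(statuses):
        r, c = divmod(i, cols)
        grid.entries.append(
            PatchGridEntry(row=r, col=c, x0=c * 224, y0=r * 224, status=status)
        )
    return grid
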