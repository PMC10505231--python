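"""Render an interpretability heatmap from a trained estimator.

Trains a quick 1p estimator, scores every patch of one slide, and writes
a red/blue heatmap (red = low patch FC, i.e. evidence of 1p loss; blue =
intact; purple = patches the filters discarded). Also lists the most
extreme "representative" patches a pathologist would review first.
"""

import warnings

import numpy as np

from milfc import (
    TrainConfig,
    patch_fc_values,
    render_heatmap,
    representative_patches,
    score_patches,
    simulate_cohort,
    train_fc_estimator,
)
from milfc.pipeline import _grid_from_coords

warnings.simplefilter("ignore")

cohort = simulate_cohort(40, n_patches_range=(80, 140), seed=3)
bags = [bag for bag, _ in cohort]
fc = np.array([truth.fc_1p for _, truth in cohort])
params, _ = train_fc_estimator(
    bags[:30], fc[:30], bags[30:34], fc[30:34],
    TrainConfig(N=10, max_epochs=30, seed=0), arm="1p",
)

bag, truth = cohort[34]
scores = score_patches(bag, params)
heatmap = render_heatmap(_grid_from_coords(bag), patch_fc_values(scores))
path = heatmap.save_png("scratch/heatmap_1p.png")
print(f"slide {bag.slide_id}: true fc_1p = {truth.fc_1p:.3f}, "
      f"{'deleted' if truth.deleted_1p else 'intact'} 1p")
print(f"heatmap written to {path} ({heatmap.cells.shape[0]}x{heatmap.cells.shape[1]} cells)")

top = representative_patches(scores, bag.coords, k=3)
print("\nmost extreme patches (side, grid row/col, raw score):")
for _, r in top.iterrows():
    print(f"  {r['side']:>4}  ({r['row']},{r['col']})  {r['score']:+.3f}")
print("low-side patches are the model's strongest evidence of arm loss")
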