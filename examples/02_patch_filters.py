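"""Tile a small synthetic slide and discard background and blood patches.

Builds a 224x672 strip of three fixture patches (tissue, blank
background, blood), tiles it, and applies the two filter rules: edge-pixel
count < 23 flags background, and a >= 50% saturated-red HSV pixel fraction
flags blood. Only the tissue patch survives.
"""

import numpy as np

from milfc import count_edge_pixels, filter_patches, simulate_test_image, tile_slide

strip = np.concatenate(
    [
        simulate_test_image("tissue", seed=0),
        simulate_test_image("background", seed=0),
        simulate_test_image("blood", seed=0),
    ],
    axis=1,
)
grid, patches = tile_slide(strip, slide_id="demo")
filter_patches(grid, patches)

print("col  status      edge pixels")
for entry, patch in zip(grid.entries, patches):
    print(f"{entry.col:>3}  {entry.status:<10}  {count_edge_pixels(patch):>6}")
counts = grid.status_counts()
print(f"\nkept {counts['kept']} of {len(grid.entries)} patches "
      f"({counts['background']} background, {counts['blood']} blood discarded)")
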