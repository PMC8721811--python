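"""Tile a 320x320 image with the Cropped Gaussian Pyramid with Overlapping.

Shows the 10-tile decomposition at overlap factor alpha = 0.3: one
downsampled full view plus a 3x3 grid of overlapping 160x160 crops.
"""

import numpy as np

from microres import CgpoConfig, cgpo_tiles, generate_subject_face, grid_positions

img = generate_subject_face(subject_seed=3, size=320)
tiles = cgpo_tiles(img, CgpoConfig(alpha=0.3))

print(f"{len(tiles)} tiles from a {img.shape[1]}x{img.shape[0]} input")
print(f"grid offsets at alpha=0.3: {grid_positions(320, 160, 0.3)} "
      "(stride 112 -> adjacent tiles share 48 px = 30% of a tile)")
for t in tiles.tiles:
    kind = "downsampled full image" if t.level == 1 else "level-0 crop"
    print(f"  tile {t.index}: level {t.level}, offset "
          f"({t.x_offset:3d}, {t.y_offset:3d}), {t.image.shape[1]}x"
          f"{t.image.shape[0]} — {kind}")

mask = np.zeros((320, 320), bool)
for t in tiles.tiles[1:]:
    mask[t.y_offset:t.y_offset + 160, t.x_offset:t.x_offset + 160] = True
print(f"level-0 crops cover {mask.mean():.0%} of the input pixels")
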