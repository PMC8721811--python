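"""Cropped Gaussian Pyramid with Overlapping (CGPO).

A two-level Gaussian pyramid of the preprocessed image is cut into fixed-size
overlapping tiles so the network can attend to individual facial regions at
two scales.  For the reference geometry — a 320x320 input, 160x160 tiles and
overlap factor alpha = 0.3 — the module emits exactly 10 tiles: the full
downsampled (level-1) image first, then the 3x3 row-major grid of overlapping
level-0 crops.

Grid rule: stride = round(tile_size * (1 - alpha)); offsets advance by the
stride and the last offset is clamped so the final tile ends exactly at the
image border (hence it overlaps its neighbour by more than alpha).  Tile
ordering is fixed — position embeddings downstream are ordinal and must be
stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["CgpoConfig", "Tile", "TileSet", "pyramid_downsample", "grid_positions", "cgpo_tiles"]

#: Classical 5-tap binomial approximation of a Gaussian, sums to 1 exactly.
_BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class CgpoConfig:
    input_size: int = 320
    tile_size: int = 160
    alpha: float = 0.3
    levels: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.input_size != 2 * self.tile_size:
            raise ValueError(
                f"input_size ({self.input_size}) must be twice tile_size "
                f"({self.tile_size}) for the two-level geometry"
            )
        if self.levels != 2:
            raise ValueError("only the two-level pyramid is supported")


@dataclass(frozen=True)
class Tile:
    index: int
    level: int  # 0 = native resolution, 1 = downsampled
    x_offset: int
    y_offset: int
    image: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class TileSet:
    tiles: tuple[Tile, ...]

    def __post_init__(self) -> None:
        for i, t in enumerate(self.tiles):
            if t.index != i:
                raise ValueError("tile indices must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.tiles)

    def stack(self) -> np.ndarray:
        """All tile images as one (n_tiles, H, W, 3) array."""
        return np.stack([t.image for t in self.tiles])


def pyramid_downsample(image: np.ndarray) -> np.ndarray:
    """One Gaussian-pyramid reduction: 5-tap binomial blur, then decimate by 2.

    The blur is separable with reflect-padded borders; decimation keeps the
    even-indexed rows and columns.  Constant images are preserved exactly.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h % 2 or w % 2:
        raise ValueError(f"image sides must be even, got {h}x{w}")
    blurred = image.astype(np.float64)
    blurred = correlate1d(blurred, _BINOMIAL5, axis=0, mode="reflect")
    blurred = correlate1d(blurred, _BINOMIAL5, axis=1, mode="reflect")
    out = blurred[::2, ::2]
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out).clip(0, 255).astype(image.dtype)
    return out


def grid_positions(image_size: int, tile_size: int, alpha: float) -> list[int]:
    """Tile offsets along one axis for overlap factor ``alpha``.

    stride = round(tile_size * (1 - alpha)); offsets step by the stride and
    any offset whose tile would overrun the image is clamped to
    ``image_size - tile_size`` (duplicates dropped, order kept).
    """
    if tile_size > image_size:
        raise ValueError(f"tile_size {tile_size} exceeds image_size {image_size}")
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    stride = round(tile_size * (1 - alpha))
    stride = max(stride, 1)
    offsets: list[int] = []
    off = 0
    while off + tile_size < image_size + stride:
        offsets.append(min(off, image_size - tile_size))
        off += stride
    seen: set[int] = set()
    unique = [o for o in offsets if not (o in seen or seen.add(o))]
    return unique


def cgpo_tiles(image: np.ndarray, config: CgpoConfig = CgpoConfig()) -> TileSet:
    """Split a preprocessed image into the ordered CGPO tile set.

    Tile 0 is the level-1 (downsampled) full image; the remaining tiles are
    the level-0 overlapping crops in row-major order (y outer, x inner).  At
    the reference geometry (320 -> 160, alpha = 0.3) this yields 10 tiles.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h != config.input_size or w != config.input_size:
        raise ValueError(
            f"expected {config.input_size}x{config.input_size} input, got {h}x{w}"
        )
    ts = config.tile_size
    tiles = [Tile(index=0, level=1, x_offset=0, y_offset=0,
                  image=pyramid_downsample(image))]
    offsets = grid_positions(config.input_size, ts, config.alpha)
    idx = 1
    for y in offsets:
        for x in offsets:
            tiles.append(
                Tile(index=idx, level=0, x_offset=x, y_offset=y,
                     image=image[y:y + ts, x:x + ts].copy())
            )
            idx += 1
    return TileSet(tiles=tuple(tiles))
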