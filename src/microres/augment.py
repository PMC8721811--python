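"""Stochastic training-time augmentation.

Four stages applied in a fixed order to the residual image before tiling
(so all tiles of one sample see a consistent transform):

1. photometric jitter — brightness, contrast and saturation each scaled by an
   independent uniform draw from ``jitter_range`` (default [0.2, 1.8]) and the
   hue shifted by a uniform draw from ``hue_range`` (default [-0.5, 0.5] on a
   [0, 1] hue wheel);
2. grayscale conversion with probability 0.2 (replicated to three channels);
3. horizontal flip with probability 0.5;
4. rotation by a uniform draw from ``rotation_degrees`` (default [-15, 15])
   about the image centre, bilinear resampling, replicated borders.

All draws come from the caller's numpy Generator, so a fixed seed reproduces
the augmentation stream exactly.  Degenerate settings (unit factors, zero
probabilities and angles) short-circuit to the identity transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import rotate as _nd_rotate
from skimage.color import hsv2rgb, rgb2hsv

__all__ = ["AugmentConfig", "augment_image"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AugmentConfig:
    jitter_range: tuple[float, float] = (0.2, 1.8)
    hue_range: tuple[float, float] = (-0.5, 0.5)
    grayscale_prob: float = 0.2
    hflip_prob: float = 0.5
    rotation_degrees: tuple[float, float] = (-15.0, 15.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.jitter_range, self.hue_range, self.rotation_degrees):
            if lo > hi:
                raise ValueError("augmentation ranges must be ordered (lo <= hi)")
        for p in (self.grayscale_prob, self.hflip_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


def _grayscale(img: np.ndarray) -> np.ndarray:
    g = img @ _LUMA
    return np.stack([g] * 3, axis=-1)


def augment_image(
    image: np.ndarray, config: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply the four augmentation stages to an H x W x 3 uint8 image."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 image, got {img.shape}")
    x = img.astype(np.float64)

    # Stage 1: photometric jitter.  Draw order is fixed for reproducibility.
    b, c, s = rng.uniform(*config.jitter_range, size=3)
    hue = rng.uniform(*config.hue_range)
    if b != 1.0:
        x = x * b
    if c != 1.0:
        mean = _grayscale(np.clip(x, 0, 255)).mean()
        x = c * x + (1.0 - c) * mean
    if s != 1.0:
        gray = _grayscale(np.clip(x, 0, 255))
        x = s * x + (1.0 - s) * gray
    if hue != 0.0:
        hsv = rgb2hsv(np.clip(x, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
        x = hsv2rgb(hsv) * 255.0

    # Stage 2: grayscale with probability grayscale_prob.
    if config.grayscale_prob > 0 and rng.uniform() < config.grayscale_prob:
        x = _grayscale(np.clip(x, 0, 255))

    # Stage 3: horizontal flip.
    if config.hflip_prob > 0 and rng.uniform() < config.hflip_prob:
        x = x[:, ::-1, :]

    # Stage 4: rotation about the centre, bilinear, replicated borders.
    angle = rng.uniform(*config.rotation_degrees)
    if angle != 0.0:
        x = _nd_rotate(x, angle, axes=(1, 0), reshape=False, order=1, mode="nearest")

    return np.rint(np.clip(x, 0, 255)).astype(np.uint8)
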