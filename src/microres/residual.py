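"""Pixel residual-sum preprocessing: ARS and RRS.

Both methods collapse a key-frame set into a single 3-channel image that
encodes, per pixel, the accumulated absolute intensity change relative to the
window's start frame:

    diff(x, y, z) = sum over key frames f of |Q_f(x, y, z) - Q_start(x, y, z)|

ARS (absolute residual sum) takes ``diff`` modulo 256 — small and large
displacements both remain visible, with frequently-moving regions wrapping
around.  RRS (relative residual sum) instead min-max rescales ``diff`` to
[gmin, gmax] (default [0, 255]), emphasising the regions of largest relative
displacement.

The sum is computed in unbounded integer arithmetic; for ARS the modulus is
applied once, to the final sum, not per term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .clipio import Clip
from .keyframe import KeyframeSet

__all__ = ["ResidualImage", "residual_sum_map", "ars_image", "rrs_image"]


@dataclass
class ResidualImage:
    """An H x W x 3 uint8 residual image plus the method that produced it."""

    pixels: np.ndarray
    method: Literal["ars", "rrs", "apex"]
    gmin: int = 0
    gmax: int = 255

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("residual image must be uint8")
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError(f"expected H x W x 3 image, got {self.pixels.shape}")


def _check_indices(clip: Clip, kf: KeyframeSet) -> None:
    n = len(clip)
    for idx in (kf.start, *kf.frames):
        if not (0 <= idx < n):
            raise IndexError(
                f"clip {clip.annotation.clip_id}: key frame index {idx} "
                f"out of range for {n} frames"
            )


def residual_sum_map(clip: Clip, kf: KeyframeSet) -> np.ndarray:
    """Accumulated absolute residuals against the start frame (int64 map).

    The reference frame is the frame at ``kf.start``; every key frame
    (duplicates included) contributes one |difference| term, so the output
    scale is n_key * 255 at most.
    """
    _check_indices(clip, kf)
    ref = clip.frames[kf.start].astype(np.int64)
    diff = np.zeros_like(ref)
    for f in kf.frames:
        diff += np.abs(clip.frames[f].astype(np.int64) - ref)
    return diff


def ars_image(clip: Clip, kf: KeyframeSet) -> ResidualImage:
    """Absolute residual sum: the diff map modulo 256, as an 8-bit image."""
    diff = residual_sum_map(clip, kf)
    return ResidualImage(pixels=(diff % 256).astype(np.uint8), method="ars")


def rrs_image(
    clip: Clip, kf: KeyframeSet, gmin: int = 0, gmax: int = 255,
    per_channel: bool = False,
) -> ResidualImage:
    """Relative residual sum: the diff map min-max rescaled to [gmin, gmax].

    The minimum and maximum are global over all pixels and channels
    (``per_channel=True`` switches to per-channel extrema for ablation).
    Values are rounded half-to-even.  A constant diff map (a static clip)
    degenerates to an all-``gmin`` image.
    """
    if gmin >= gmax:
        raise ValueError(f"gmin ({gmin}) must be < gmax ({gmax})")
    diff = residual_sum_map(clip, kf).astype(np.float64)
    axis = (0, 1) if per_channel else None
    lo = diff.min(axis=axis, keepdims=per_channel)
    hi = diff.max(axis=axis, keepdims=per_channel)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (diff - lo) / np.where(span > 0, span, 1), 0.0)
    pixels = np.rint(scaled * (gmax - gmin) + gmin).astype(np.uint8)
    return ResidualImage(pixels=pixels, method="rrs", gmin=gmin, gmax=gmax)
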