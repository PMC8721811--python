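"""Landmark-driven face cropping.

The face region is located from 68 facial landmarks (pluggable detector or
precomputed CSV), expanded by a margin and cropped-and-resized to the network
input resolution.  One crop box is computed from the onset frame and applied
to every frame of a clip, so residual sums reflect facial motion rather than
crop jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from skimage.transform import resize as _sk_resize

from .clipio import Clip, LandmarkSet

__all__ = ["CropSpec", "LandmarkDetector", "landmarks_to_box", "crop_and_resize", "crop_clip"]

DEFAULT_MARGIN = 0.1
DEFAULT_OUTPUT_SIZE = (320, 320)


class LandmarkDetector(Protocol):
    """Anything that maps an RGB frame to a 68-point LandmarkSet."""

    def __call__(self, frame: np.ndarray) -> LandmarkSet: ...


@dataclass(frozen=True)
class CropSpec:
    """A half-open pixel box (left, top, right, bottom) plus output size."""

    box: tuple[int, int, int, int]
    margin: float = DEFAULT_MARGIN
    output_size: tuple[int, int] = DEFAULT_OUTPUT_SIZE  # (width, height)

    def __post_init__(self) -> None:
        left, top, right, bottom = self.box
        if right <= left or bottom <= top:
            raise ValueError(f"empty crop box {self.box}")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def landmarks_to_box(
    landmarks: LandmarkSet,
    margin: float = DEFAULT_MARGIN,
    frame_shape: tuple[int, int] | None = None,
    output_size: tuple[int, int] = DEFAULT_OUTPUT_SIZE,
) -> CropSpec:
    """Bounding box of the 68 landmarks, expanded by ``margin`` per side.

    The expansion is ``margin * max(box width, box height)`` on each of the
    four sides, then clamped to the frame when ``frame_shape`` (H, W) is given.
    """
    pts = landmarks.points
    if pts.shape != (68, 2):
        raise ValueError(f"need 68 landmarks, got {pts.shape}")
    left, top = pts.min(axis=0)
    right, bottom = pts.max(axis=0)
    pad = margin * max(right - left, bottom - top)
    left, top = left - pad, top - pad
    right, bottom = right + pad, bottom + pad
    if frame_shape is not None:
        h, w = frame_shape
        left, top = max(left, 0.0), max(top, 0.0)
        right, bottom = min(right, float(w)), min(bottom, float(h))
    box = (int(np.floor(left)), int(np.floor(top)),
           int(np.ceil(right)), int(np.ceil(bottom)))
    return CropSpec(box=box, margin=margin, output_size=output_size)


def crop_and_resize(frame: np.ndarray, spec: CropSpec) -> np.ndarray:
    """Crop ``spec.box`` from the frame and bilinearly resample to output_size.

    When the box already has the output size the pixels are returned
    bit-exactly (no resampling).
    """
    left, top, right, bottom = spec.box
    h, w = frame.shape[:2]
    left, top = max(left, 0), max(top, 0)
    right, bottom = min(right, w), min(bottom, h)
    if right <= left or bottom <= top:
        raise ValueError(f"crop box {spec.box} empty after clamping to {h}x{w} frame")
    patch = frame[top:bottom, left:right]
    out_w, out_h = spec.output_size
    if patch.shape[0] == out_h and patch.shape[1] == out_w:
        return patch.copy()
    resized = _sk_resize(
        patch.astype(np.float64), (out_h, out_w), order=1,
        preserve_range=True, anti_aliasing=False,
    )
    return np.rint(resized).clip(0, 255).astype(np.uint8)


def crop_clip(
    clip: Clip,
    landmarks: LandmarkSet | None = None,
    detector: Callable[[np.ndarray], LandmarkSet] | None = None,
    margin: float = DEFAULT_MARGIN,
    output_size: tuple[int, int] = DEFAULT_OUTPUT_SIZE,
) -> Clip:
    """Crop every frame of a clip with one box derived from the onset frame.

    Landmarks may be supplied directly (e.g. from a CSV) or produced by a
    detector applied to the onset frame; exactly one of the two is required.
    """
    if (landmarks is None) == (detector is None):
        raise ValueError("provide exactly one of landmarks or detector")
    if landmarks is None:
        landmarks = detector(clip.frames[clip.annotation.onset])
    spec = landmarks_to_box(
        landmarks, margin=margin, frame_shape=clip.frame_shape,
        output_size=output_size,
    )
    frames = np.stack([crop_and_resize(f, spec) for f in clip.frames])
    return Clip(annotation=clip.annotation, frames=frames)
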