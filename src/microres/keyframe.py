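"""Analysis-window selection and key-frame sampling.

Micro-expression clips are highly redundant: consecutive frames are nearly
identical.  The method therefore restricts attention to the onset-to-apex
window and samples ``n_key`` key frames at a fixed integer gap inside it.

The window is

    start = onset
    end   = min(onset + 10, offset)   if apex - onset < 10
          = min(apex, offset)         otherwise

and the key frames are

    gap       = ceil((end - start) / (n_key + 1))
    frames[k] = min(start + (k + 1) * gap, end)   for k = 0 .. n_key - 2
    frames[n_key - 1] = end

Clamping on very short windows can produce duplicate indices; the list is
deliberately kept at length ``n_key`` so the residual-sum magnitude does not
depend on clip length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .clipio import ClipAnnotation, resolve_apex

__all__ = ["KeyframeSet", "select_window", "select_keyframes", "DEFAULT_N_KEY"]

DEFAULT_N_KEY = 5


@dataclass(frozen=True)
class KeyframeSet:
    start: int
    end: int
    gap: int
    n_key: int
    frames: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.n_key < 1:
            raise ValueError("n_key must be positive")
        if len(self.frames) != self.n_key:
            raise ValueError(
                f"expected {self.n_key} key frames, got {len(self.frames)}"
            )
        if self.frames and self.frames[-1] != self.end:
            raise ValueError("last key frame must equal end")
        for f in self.frames:
            if not (self.start <= f <= self.end):
                raise ValueError(f"key frame {f} outside [{self.start}, {self.end}]")


def select_window(annotation: ClipAnnotation) -> tuple[int, int]:
    """Choose the [start, end] analysis window from the temporal annotation.

    The onset frame is always the start.  When the apex is at least 10 frames
    after the onset, the window runs to the apex; for shorter expressions it
    is padded to 10 frames, capped at the offset in both cases.
    """
    onset, offset = annotation.onset, annotation.offset
    apex = resolve_apex(annotation)
    if apex - onset < 10:
        end = min(onset + 10, offset)
    else:
        end = min(apex, offset)
    return onset, end


def select_keyframes(start: int, end: int, n_key: int = DEFAULT_N_KEY) -> KeyframeSet:
    """Sample ``n_key`` key frames at equal integer gaps in [start, end]."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    if n_key < 1:
        raise ValueError("n_key must be positive")
    gap = math.ceil((end - start) / (n_key + 1))
    frames = [min(start + (k + 1) * gap, end) for k in range(n_key - 1)]
    frames.append(end)
    return KeyframeSet(start=start, end=end, gap=gap, n_key=n_key, frames=tuple(frames))
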