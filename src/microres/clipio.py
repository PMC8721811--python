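"""Clip, annotation and landmark I/O.

A micro-expression sample is a short video clip stored as a directory of
numbered 8-bit RGB frames, annotated with its subject, an emotion label and
three temporal indices: onset (first frame of the expression), apex (frame of
maximal intensity, possibly unlabeled) and offset (last frame).  This module
reads and writes that representation and implements the composite-dataset
(MEGC2019-style) three-class label merging and the mid-frame apex fallback
used when a dataset ships no apex annotation.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ABSENT",
    "ClipAnnotation",
    "Clip",
    "LandmarkSet",
    "read_clip",
    "write_clip",
    "read_annotations",
    "write_annotations",
    "read_landmarks",
    "write_landmarks",
    "merge_to_three_classes",
    "resolve_apex",
    "THREE_CLASSES",
]

#: Sentinel for a missing apex annotation (SMIC-HS ships none).
ABSENT = None

THREE_CLASSES = ("negative", "positive", "surprise")

# Composite-dataset evaluation merges the source emotions into three classes:
# the five "negative" emotions plus an already-merged "negative", happiness
# (or an already-merged "positive"), and surprise.  Labels outside this set
# ("others", "repression") are not part of the composite protocol.
_CDE_MAP = {
    "disgust": "negative",
    "contempt": "negative",
    "fear": "negative",
    "sadness": "negative",
    "anger": "negative",
    "negative": "negative",
    "happiness": "positive",
    "positive": "positive",
    "surprise": "surprise",
}


@dataclass(frozen=True)
class ClipAnnotation:
    """Temporal annotation of one clip.

    Frame indices are 0-based positions in the clip's sorted frame list.
    ``apex`` may be :data:`ABSENT` when the dataset does not label it.
    """

    subject_id: str
    clip_id: str
    onset: int
    apex: int | None
    offset: int
    label: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"clip {self.clip_id}: onset must be >= 0")
        if self.onset > self.offset:
            raise ValueError(
                f"clip {self.clip_id}: onset {self.onset} > offset {self.offset}"
            )
        if self.apex is not ABSENT and not (self.onset <= self.apex <= self.offset):
            raise ValueError(
                f"clip {self.clip_id}: apex {self.apex} outside "
                f"[onset={self.onset}, offset={self.offset}]"
            )


@dataclass
class Clip:
    """An annotated clip: an ordered stack of same-shape H x W x 3 uint8 frames."""

    annotation: ClipAnnotation
    frames: np.ndarray  # (T, H, W, 3) uint8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"clip {self.annotation.clip_id}: frames must be (T, H, W, 3), "
                f"got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError(f"clip {self.annotation.clip_id}: empty clip")
        if self.frames.dtype != np.uint8:
            raise ValueError(f"clip {self.annotation.clip_id}: frames must be uint8")
        if self.annotation.offset >= len(self.frames):
            raise ValueError(
                f"clip {self.annotation.clip_id}: offset {self.annotation.offset} "
                f"out of range for {len(self.frames)} frames"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class LandmarkSet:
    """68 facial landmark (x, y) coordinates for a reference frame."""

    points: np.ndarray  # (68, 2) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) landmarks, got {self.points.shape}")


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path) -> tuple:
    m = _NUM_RE.search(path.stem)
    return (int(m.group(1)), path.stem) if m else (1 << 60, path.stem)


def read_clip(frame_dir: str | Path, annotation: ClipAnnotation) -> Clip:
    """Read a clip from a directory of numbered PNG/JPEG frames.

    Frames are sorted by the numeric value embedded in the filename, so
    ``9.png`` precedes ``10.png`` regardless of zero padding.
    """
    frame_dir = Path(frame_dir)
    if not frame_dir.is_dir():
        raise FileNotFoundError(
            f"clip {annotation.clip_id}: frame directory {frame_dir} not found"
        )
    paths = sorted(
        (p for p in frame_dir.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}),
        key=_numeric_key,
    )
    if not paths:
        raise FileNotFoundError(f"clip {annotation.clip_id}: no frames in {frame_dir}")
    frames = []
    shape = None
    for p in paths:
        try:
            img = np.asarray(iio.imread(p))
        except Exception as exc:  # noqa: BLE001 - rewrap with clip context
            raise OSError(f"clip {annotation.clip_id}: unreadable frame {p}") from exc
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[-1] == 4:
            img = img[..., :3]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"clip {annotation.clip_id}: inconsistent frame shape "
                f"({p.name} is {img.shape}, expected {shape})"
            )
        frames.append(img.astype(np.uint8))
    stack = np.stack(frames)
    if annotation.offset >= len(stack):
        raise ValueError(
            f"clip {annotation.clip_id}: offset {annotation.offset} out of range "
            f"for {len(stack)} frames"
        )
    return Clip(annotation=annotation, frames=stack)


def write_clip(clip: Clip, frame_dir: str | Path) -> list[Path]:
    """Write a clip's frames as zero-padded PNGs; returns the written paths."""
    frame_dir = Path(frame_dir)
    frame_dir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(len(clip) - 1)))
    paths = []
    for i, frame in enumerate(clip.frames):
        p = frame_dir / f"{i:0{width}d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_annotations(csv_path: str | Path, index_base: int = 0) -> list[ClipAnnotation]:
    """Read the annotation table (columns subject,clip,onset,apex,offset,label).

    ``index_base=1`` converts 1-based dataset conventions to the 0-based
    indices used internally.  An empty apex field becomes :data:`ABSENT`.
    """
    csv_path = Path(csv_path)
    if index_base not in (0, 1):
        raise ValueError("index_base must be 0 or 1")
    out: list[ClipAnnotation] = []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"subject", "clip", "onset", "apex", "offset", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{csv_path}: header must contain {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                apex_raw = (row["apex"] or "").strip()
                apex = ABSENT if apex_raw == "" else int(apex_raw) - index_base
                out.append(
                    ClipAnnotation(
                        subject_id=row["subject"].strip(),
                        clip_id=row["clip"].strip(),
                        onset=int(row["onset"]) - index_base,
                        apex=apex,
                        offset=int(row["offset"]) - index_base,
                        label=row["label"].strip(),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{csv_path}: malformed row {lineno}: {exc}") from exc
    return out


def write_annotations(annotations: Sequence[ClipAnnotation], csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject", "clip", "onset", "apex", "offset", "label"])
        for a in annotations:
            writer.writerow(
                [a.subject_id, a.clip_id, a.onset,
                 "" if a.apex is ABSENT else a.apex, a.offset, a.label]
            )


def read_landmarks(csv_path: str | Path) -> LandmarkSet:
    """Read a 68-row x,y landmark CSV (no header)."""
    pts = np.loadtxt(csv_path, delimiter=",", dtype=float)
    if pts.shape != (68, 2):
        raise ValueError(f"{csv_path}: expected 68 x,y rows, got shape {pts.shape}")
    return LandmarkSet(points=pts)


def write_landmarks(landmarks: LandmarkSet, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(csv_path, landmarks.points, delimiter=",", fmt="%.3f")


def merge_to_three_classes(label: str) -> str:
    """Map a source emotion label to {negative, positive, surprise}.

    The composite-dataset protocol folds disgust, contempt, fear, sadness and
    anger into ``negative``, happiness into ``positive`` and keeps surprise.
    Labels outside the protocol (e.g. "others", "repression") raise.
    """
    key = label.strip().lower()
    try:
        return _CDE_MAP[key]
    except KeyError:
        raise ValueError(
            f"label {label!r} is not mappable under the CDE protocol"
        ) from None


def resolve_apex(annotation: ClipAnnotation) -> int:
    """Return the apex index, falling back to the floor midpoint of the clip.

    Datasets without apex labels (SMIC-HS) conventionally use the middle frame
    of the clip; the same rule is applied to any apex-less annotation.
    """
    if annotation.apex is not ABSENT:
        return annotation.apex
    return (annotation.onset + annotation.offset) // 2
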