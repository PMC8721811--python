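"""Synthetic annotated micro-expression clips.

The real spontaneous micro-expression corpora are access-restricted, so this
module generates clips with the statistical structure the recognition method
relies on: a short video of a (schematic) face in which a *localized*
intensity perturbation ramps linearly from zero at the onset frame to its
maximum at the apex frame and decays toward the offset, on top of per-frame
sensor noise and a small multiplicative illumination drift.  Each emotion
class perturbs a different, fixed facial region:

    class 0 ("negative")  -> left mouth corner
    class 1 ("positive")  -> left brow
    class 2 ("surprise")  -> nose tip

Subjects differ in face geometry and coloration (drawn from the subject
seed) but share the class-region semantics, so leave-one-subject-out
generalization is meaningful.  Motion is modeled as additive localized
intensity change rather than geometric warping: that exercises every
pipeline stage, is cheap, and is exactly reproducible.

Faces are schematic (background, elliptical face, eyes, brows, nose, mouth)
with a consistent synthetic 68-point landmark set; no photorealism and no
action-unit modeling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clipio import (
    Clip, ClipAnnotation, LandmarkSet, THREE_CLASSES,
    write_annotations, write_clip, write_landmarks,
)

__all__ = [
    "SynthConfig", "SubjectFace", "SynthDataset",
    "generate_subject_face", "subject_model", "generate_clip",
    "generate_dataset", "write_dataset", "class_region_center",
]


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 6
    clips_per_subject: int = 6
    n_classes: int = 3
    frame_size: int = 320
    clip_length: int = 24
    onset_frac: float = 0.1    # onset = round(onset_frac * clip_length)
    apex_frac: float = 0.6
    offset_frac: float = 0.9
    motion_amplitude: float = 50.0   # peak intensity delta, 8-bit units
    bump_sigma_frac: float = 0.05    # bump radius as a fraction of frame size
    noise_sigma: float = 2.0         # per-pixel Gaussian noise, 8-bit units
    illumination_drift: tuple[float, float] = (0.99, 1.01)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motion_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("amplitude and noise_sigma must be >= 0")
        if not (1 <= self.n_classes <= 3):
            raise ValueError("n_classes must be in 1..3 (three regions defined)")
        onset, apex, offset = self.timeline()
        if not (0 <= onset < apex <= offset < self.clip_length):
            raise ValueError(
                f"invalid timeline onset={onset} apex={apex} offset={offset} "
                f"for clip_length={self.clip_length}"
            )

    def timeline(self) -> tuple[int, int, int]:
        L = self.clip_length
        onset = round(self.onset_frac * L)
        apex = round(self.apex_frac * L)
        offset = min(round(self.offset_frac * L), L - 1)
        return onset, apex, offset


@dataclass
class SubjectFace:
    """A subject's neutral schematic face, its geometry and landmarks."""

    image: np.ndarray          # (size, size, 3) uint8
    geometry: dict
    landmarks: LandmarkSet


def _geometry(rng: np.random.Generator, size: int) -> dict:
    """Per-subject face geometry in pixel units, jittered around a template."""
    j = lambda lo, hi: rng.uniform(lo, hi)  # noqa: E731
    cx = size * (0.50 + j(-0.03, 0.03))
    cy = size * (0.52 + j(-0.03, 0.03))
    ax = size * (0.30 + j(-0.02, 0.02))
    ay = size * (0.38 + j(-0.02, 0.02))
    return {
        "size": size,
        "background": j(150, 200),
        "skin": np.array([205 + j(-20, 20), 175 + j(-20, 20), 150 + j(-20, 20)]),
        "cx": cx, "cy": cy, "ax": ax, "ay": ay,
        "eye_dx": 0.42 * ax, "eye_y": cy - 0.35 * ay,
        "eye_w": 0.18 * ax, "eye_h": 0.10 * ay,
        "brow_y": cy - 0.52 * ay,
        "nose_y": cy + 0.08 * ay, "nose_w": 0.14 * ax, "nose_h": 0.18 * ay,
        "mouth_y": cy + 0.55 * ay, "mouth_w": 0.42 * ax, "mouth_h": 0.10 * ay,
    }


def _paint_ellipse(img: np.ndarray, cx: float, cy: float, ax: float, ay: float,
                   color: np.ndarray) -> None:
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    img[mask] = color


def _render(geom: dict) -> np.ndarray:
    size = geom["size"]
    img = np.full((size, size, 3), geom["background"], dtype=float)
    _paint_ellipse(img, geom["cx"], geom["cy"], geom["ax"], geom["ay"], geom["skin"])
    dark = geom["skin"] * 0.35
    for sgn in (-1, 1):
        ex = geom["cx"] + sgn * geom["eye_dx"]
        _paint_ellipse(img, ex, geom["eye_y"], geom["eye_w"], geom["eye_h"], dark)
        _paint_ellipse(img, ex, geom["brow_y"], 1.2 * geom["eye_w"],
                       0.4 * geom["eye_h"], dark * 0.8)
    _paint_ellipse(img, geom["cx"], geom["nose_y"], geom["nose_w"],
                   geom["nose_h"], geom["skin"] * 0.8)
    _paint_ellipse(img, geom["cx"], geom["mouth_y"], geom["mouth_w"],
                   geom["mouth_h"], np.array([150.0, 70.0, 70.0]))
    return np.clip(img, 0, 255).astype(np.uint8)


def _landmarks(geom: dict) -> LandmarkSet:
    """Synthetic 68-point landmark layout consistent with the schematic face."""
    cx, cy, ax, ay = geom["cx"], geom["cy"], geom["ax"], geom["ay"]
    pts: list[tuple[float, float]] = []
    # 17 jaw points along the lower face ellipse, left ear to right ear
    for i in range(17):
        t = np.pi * i / 16
        pts.append((cx - ax * np.cos(t), cy + ay * np.sin(t)))
    # 5 + 5 brow points
    for sgn in (-1, 1):
        ex = cx + sgn * geom["eye_dx"]
        for k in np.linspace(-1.2, 1.2, 5):
            pts.append((ex + k * geom["eye_w"], geom["brow_y"]))
    # 9 nose points: 4 bridge + 5 base
    for k in np.linspace(geom["eye_y"], geom["nose_y"], 4):
        pts.append((cx, k))
    for k in np.linspace(-1, 1, 5):
        pts.append((cx + k * geom["nose_w"], geom["nose_y"] + geom["nose_h"] * 0.6))
    # 6 + 6 eye points
    for sgn in (-1, 1):
        ex = cx + sgn * geom["eye_dx"]
        for t in np.linspace(0, 2 * np.pi, 6, endpoint=False):
            pts.append((ex + geom["eye_w"] * np.cos(t),
                        geom["eye_y"] + geom["eye_h"] * np.sin(t)))
    # 20 mouth points: 12 outer + 8 inner
    for t in np.linspace(0, 2 * np.pi, 12, endpoint=False):
        pts.append((cx + geom["mouth_w"] * np.cos(t),
                    geom["mouth_y"] + geom["mouth_h"] * np.sin(t)))
    for t in np.linspace(0, 2 * np.pi, 8, endpoint=False):
        pts.append((cx + 0.6 * geom["mouth_w"] * np.cos(t),
                    geom["mouth_y"] + 0.6 * geom["mouth_h"] * np.sin(t)))
    arr = np.clip(np.array(pts), 0, geom["size"] - 1)
    return LandmarkSet(points=arr)


def subject_model(subject_seed: int, size: int = 320) -> SubjectFace:
    """Deterministic schematic face + geometry + landmarks for one subject."""
    rng = np.random.default_rng(subject_seed)
    geom = _geometry(rng, size)
    return SubjectFace(image=_render(geom), geometry=geom, landmarks=_landmarks(geom))


def generate_subject_face(subject_seed: int, size: int = 320) -> np.ndarray:
    """The schematic face image alone (see :func:`subject_model`)."""
    return subject_model(subject_seed, size).image


def class_region_center(geometry: dict, class_id: int) -> tuple[float, float]:
    """Pixel (x, y) centre of the facial region perturbed by ``class_id``."""
    if class_id == 0:      # left mouth corner
        return geometry["cx"] - geometry["mouth_w"], geometry["mouth_y"]
    if class_id == 1:      # left brow
        return geometry["cx"] - geometry["eye_dx"], geometry["brow_y"]
    if class_id == 2:      # nose tip
        return geometry["cx"], geometry["nose_y"]
    raise ValueError(f"no region defined for class {class_id}")


def _ramp(t: int, onset: int, apex: int, offset: int, length: int) -> float:
    """Motion amplitude profile: 0 at onset, 1 at apex, decaying after."""
    if t <= onset:
        return 0.0
    if t <= apex:
        return (t - onset) / (apex - onset)
    if t <= offset:
        return 1.0 - 0.7 * (t - apex) / max(offset - apex, 1)
    tail = max(length - 1 - offset, 1)
    return max(0.3 * (1.0 - (t - offset) / tail), 0.0)


def generate_clip(
    face: SubjectFace,
    class_id: int,
    config: SynthConfig,
    rng: np.random.Generator,
    clip_id: str = "c00",
) -> tuple[Clip, LandmarkSet]:
    """One annotated clip for a subject: localized class-specific motion.

    Frame t adds a Gaussian intensity bump of amplitude
    ``motion_amplitude * ramp(t)`` at the class region centre, then i.i.d.
    Gaussian noise and a per-frame multiplicative illumination factor; pixel
    values are clipped to 8 bits.
    """
    if class_id >= config.n_classes:
        raise ValueError(f"class_id {class_id} >= n_classes {config.n_classes}")
    size = config.frame_size
    onset, apex, offset = config.timeline()
    bx, by = class_region_center(face.geometry, class_id)
    sigma = config.bump_sigma_frac * size
    yy, xx = np.mgrid[0:size, 0:size]
    bump = np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sigma ** 2))
    base = face.image.astype(float)

    lo, hi = config.illumination_drift
    frames = []
    for t in range(config.clip_length):
        factor = rng.uniform(lo, hi)
        frame = base * factor
        amp = config.motion_amplitude * _ramp(t, onset, apex, offset, config.clip_length)
        if amp > 0:
            frame = frame + amp * bump[..., None]
        if config.noise_sigma > 0:
            frame = frame + rng.normal(0.0, config.noise_sigma, frame.shape)
        frames.append(np.clip(np.rint(frame), 0, 255).astype(np.uint8))

    label = THREE_CLASSES[class_id] if config.n_classes <= 3 else f"class{class_id}"
    ann = ClipAnnotation(
        subject_id="s00", clip_id=clip_id,
        onset=onset, apex=apex, offset=offset, label=label,
    )
    return Clip(annotation=ann, frames=np.stack(frames)), face.landmarks


@dataclass
class SynthDataset:
    config: SynthConfig
    clips: list[Clip] = field(default_factory=list)
    landmarks: list[LandmarkSet] = field(default_factory=list)

    @property
    def annotations(self) -> list[ClipAnnotation]:
        return [c.annotation for c in self.clips]


def generate_dataset(config: SynthConfig = SynthConfig()) -> SynthDataset:
    """A balanced multi-subject dataset: classes round-robin within subject."""
    master = np.random.SeedSequence(config.seed)
    subject_seqs = master.spawn(config.n_subjects)
    ds = SynthDataset(config=config)
    for s, sseq in enumerate(subject_seqs):
        subject_id = f"s{s + 1:02d}"
        face = subject_model(int(sseq.generate_state(1)[0] % (2 ** 31)),
                             size=config.frame_size)
        clip_rng = np.random.default_rng(sseq.spawn(1)[0])
        for k in range(config.clips_per_subject):
            class_id = k % config.n_classes
            clip, lms = generate_clip(
                face, class_id, config, clip_rng, clip_id=f"c{k + 1:02d}"
            )
            clip.annotation = ClipAnnotation(
                subject_id=subject_id, clip_id=clip.annotation.clip_id,
                onset=clip.annotation.onset, apex=clip.annotation.apex,
                offset=clip.annotation.offset, label=clip.annotation.label,
            )
            ds.clips.append(clip)
            ds.landmarks.append(lms)
    return ds


def write_dataset(dataset: SynthDataset, out_dir: str | Path) -> Path:
    """Write frames, annotations.csv and landmark CSVs in the clip I/O layout."""
    out_dir = Path(out_dir)
    (out_dir / "landmarks").mkdir(parents=True, exist_ok=True)
    for clip, lms in zip(dataset.clips, dataset.landmarks):
        a = clip.annotation
        write_clip(clip, out_dir / "frames" / a.subject_id / a.clip_id)
        write_landmarks(lms, out_dir / "landmarks" / f"{a.subject_id}_{a.clip_id}.csv")
    write_annotations(dataset.annotations, out_dir / "annotations.csv")
    return out_dir
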