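"""End-to-end pipeline: preprocess clips, train and evaluate under LOSO.

Per clip the preprocessing chain is: resolve the apex, select the analysis
window, crop the face with one onset-frame landmark box, sample the key
frames, and collapse them to a single residual image (ARS or RRS).  A
``raw-apex`` mode that simply uses the cropped apex frame is included as the
natural no-temporal-information baseline for ablations.

Evaluation is leave-one-subject-out: one CropNet is trained per fold and the
predictions of all folds are pooled before computing UF1/UAR/accuracy.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .augment import AugmentConfig
from .cgpo import CgpoConfig
from .clipio import (
    Clip, ClipAnnotation, LandmarkSet, read_annotations, read_clip,
    read_landmarks,
)
from .facecrop import crop_clip
from .keyframe import DEFAULT_N_KEY, select_keyframes, select_window
from .metrics import evaluation_report, loso_splits
from .model import TrainConfig, predict, train
from .residual import ResidualImage, ars_image, rrs_image
from .synthdata import SynthConfig, generate_dataset

__all__ = [
    "PreprocessConfig", "RunConfig", "preprocess_clip", "load_dataset",
    "run_pipeline", "run_loso",
]

Method = Literal["ars", "rrs", "apex"]


@dataclass(frozen=True)
class PreprocessConfig:
    method: Method = "ars"
    n_key: int = DEFAULT_N_KEY
    gmin: int = 0
    gmax: int = 255
    margin: float = 0.1
    output_size: int = 320  # face-crop side; must equal the CGPO input size

    def __post_init__(self) -> None:
        if self.method not in ("ars", "rrs", "apex"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")


def preprocess_clip(
    clip: Clip, landmarks: LandmarkSet, config: PreprocessConfig = PreprocessConfig()
) -> ResidualImage:
    """Window -> crop -> key frames -> residual image for one clip."""
    cropped = crop_clip(
        clip, landmarks=landmarks, margin=config.margin,
        output_size=(config.output_size, config.output_size),
    )
    if config.method == "apex":
        from .clipio import resolve_apex

        return ResidualImage(
            pixels=cropped.frames[resolve_apex(clip.annotation)].copy(),
            method="apex",
        )
    start, end = select_window(clip.annotation)
    kf = select_keyframes(start, end, config.n_key)
    if config.method == "ars":
        return ars_image(cropped, kf)
    return rrs_image(cropped, kf, gmin=config.gmin, gmax=config.gmax)


@dataclass
class RunConfig:
    """Whole-run configuration; defaults follow the method's stated values."""

    data_dir: str | None = None        # directory with annotations.csv etc.
    synth: SynthConfig | None = None   # generate data instead of reading it
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cgpo: CgpoConfig = field(default_factory=CgpoConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig | None = None
    merge_three_classes: bool = False  # composite-protocol label merging
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "data" in raw:
            kwargs["data_dir"] = raw["data"].get("dir")
        if "synth" in raw:
            kwargs["synth"] = SynthConfig(**raw["synth"])
        if "preprocess" in raw:
            kwargs["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "cgpo" in raw:
            kwargs["cgpo"] = CgpoConfig(**raw["cgpo"])
        if "train" in raw:
            kwargs["train"] = TrainConfig(**raw["train"])
        if "augment" in raw:
            a = raw["augment"]
            for key in ("jitter_range", "hue_range", "rotation_degrees"):
                if key in a:
                    a[key] = tuple(a[key])
            kwargs["augment"] = AugmentConfig(**a)
        for key in ("merge_three_classes", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def load_dataset(data_dir: str | Path) -> tuple[list[Clip], list[LandmarkSet]]:
    """Read a dataset laid out as frames/<subject>/<clip>/, annotations.csv,
    landmarks/<subject>_<clip>.csv."""
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"data directory {data_dir} not found")
    annotations = read_annotations(data_dir / "annotations.csv")
    clips, landmark_sets = [], []
    for a in annotations:
        clip = read_clip(data_dir / "frames" / a.subject_id / a.clip_id, a)
        lms = read_landmarks(data_dir / "landmarks" / f"{a.subject_id}_{a.clip_id}.csv")
        clips.append(clip)
        landmark_sets.append(lms)
    return clips, landmark_sets


def run_loso(
    images: Sequence[ResidualImage],
    annotations: Sequence[ClipAnnotation],
    train_config: TrainConfig,
    cgpo: CgpoConfig,
    classes: Sequence[str] | None = None,
) -> dict:
    """Train per LOSO fold, pool predictions, and score once over the pool."""
    labels = [a.label for a in annotations]
    classes = sorted(set(labels)) if classes is None else list(classes)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in labels])
    pixel_sets = [img.pixels for img in images]

    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    fold_of: list[str] = []
    fold_logs = {}
    for fold in loso_splits(annotations):
        train_set = [(pixel_sets[i], int(y[i])) for i in fold.train_indices]
        cfg = replace(train_config, cgpo=cgpo, n_classes=len(classes))
        t0 = time.perf_counter()
        model, log = train(train_set, cfg)
        preds = predict(model, [pixel_sets[i] for i in fold.test_indices], cgpo)
        fold_logs[fold.subject_id] = {
            "train_seconds": round(time.perf_counter() - t0, 2),
            "final_train_loss": log[-1]["loss"] if log else None,
        }
        pooled_true.extend(labels[i] for i in fold.test_indices)
        pooled_pred.extend(classes[p] for p in preds)
        fold_of.extend([fold.subject_id] * len(fold.test_indices))

    report = evaluation_report(pooled_true, pooled_pred, classes, fold_of=fold_of)
    for subj, extra in fold_logs.items():
        report["folds"][subj].update(extra)
    report["classes"] = classes
    report["pooled_true"] = pooled_true
    report["pooled_pred"] = pooled_pred
    return report


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the full preprocess -> LOSO train/evaluate pipeline.

    Returns the evaluation report; when ``config.out_dir`` is set, also
    writes report.json and a confusion CSV there.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if config.synth is not None:
        ds = generate_dataset(config.synth)
        clips, landmark_sets = ds.clips, ds.landmarks
    elif config.data_dir is not None:
        clips, landmark_sets = load_dataset(config.data_dir)
    else:
        raise ValueError("config must provide either data_dir or synth")
    timings["data"] = time.perf_counter() - t0

    annotations = [c.annotation for c in clips]
    if config.merge_three_classes:
        from .clipio import merge_to_three_classes

        annotations = [
            replace(a, label=merge_to_three_classes(a.label)) for a in annotations
        ]
        for clip, a in zip(clips, annotations):
            clip.annotation = a

    if dry_run:
        subjects = sorted({a.subject_id for a in annotations})
        return {
            "dry_run": True, "n_clips": len(clips), "n_subjects": len(subjects),
            "classes": sorted({a.label for a in annotations}),
        }

    t0 = time.perf_counter()
    images = [
        preprocess_clip(clip, lms, config.preprocess)
        for clip, lms in zip(clips, landmark_sets)
    ]
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train_config = replace(config.train, seed=config.seed, augment=config.augment)
    report = run_loso(images, annotations, train_config, config.cgpo)
    timings["train_eval"] = time.perf_counter() - t0
    report["timings_seconds"] = {k: round(v, 2) for k, v in timings.items()}
    report["method"] = config.preprocess.method

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        slim = {k: v for k, v in report.items()
                if k not in ("pooled_true", "pooled_pred")}
        (out / "report.json").write_text(json.dumps(slim, indent=2))
        _write_confusion_csv(report, out / "confusion.csv")
    return report


def _write_confusion_csv(report: dict, path: Path) -> None:
    classes = report["classes"]
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(report["pooled_true"], report["pooled_pred"]):
        mat[idx[t], idx[p]] += 1
    lines = ["true\\pred," + ",".join(classes)]
    for c, row in zip(classes, mat):
        lines.append(c + "," + ",".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
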