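# Methods

## Problem setting

A micro-expression sample is a short clip of a face annotated with three
temporal indices — onset (expression begins), apex (maximal intensity),
offset (expression ends) — and an emotion label, grouped by subject. The task
is subject-independent classification: train on some subjects, predict the
clips of an unseen subject. Frames are 8-bit RGB; indices are 0-based
positions in the clip's sorted frame list (annotation files using 1-based
conventions are converted at ingest via `index_base=1`).

## Pipeline

### Window and key frames (`keyframe`)

The analysis window starts at the onset. When the apex follows the onset by
at least 10 frames the window ends at the apex; shorter expressions are
padded to `onset + 10`; both cases are capped at the offset. Inside the
window, `n_key = 5` key frames are sampled at integer gap
`⌈(end − start)/(n_key + 1)⌉`, each clamped to `end`, with the final element
pinned to `end` so the apex-adjacent frame is always present. The key-frame
list keeps duplicates on very short windows: downstream residual sums always
accumulate exactly `n_key` terms, so their magnitude scale is independent of
clip length. When a dataset ships no apex annotation the floor midpoint
`⌊(onset + offset)/2⌋` is used — the convention for mid-frame apex proxies —
generalized here to any apex-less clip.

### Residual-sum preprocessing (`residual`)

`diff(x,y,z) = Σ_{f∈𝔽} |Q_f − Q_start|` is accumulated in int64, so no 8-bit
overflow can occur before the final transform. Two images are derived:

- **ARS** — `diff mod 256`. The modulus is applied once, to the final sum,
  not per term (the formula places it outside the summation). Wraparound is
  implemented as printed; a saturating variant would be the obvious
  alternative but is not what the formula states.
- **RRS** — min–max rescale of `diff` to `[gmin, gmax] = [0, 255]`. The
  extrema are global over pixels *and* channels (the defining expression
  carries no channel subscript); a per-channel variant is available behind
  `per_channel=True` for ablation. Values are rounded half-to-even (no
  rounding rule is stated anywhere; banker's rounding is numpy's default and
  bias-free). A constant `diff` map — possible on synthetic static clips —
  maps to all-`gmin`.

A `raw-apex` preprocessing mode (the cropped apex frame, no temporal
information) is included purely as the natural ablation baseline.

### Face cropping (`facecrop`)

The crop box is the tight bounding box of 68 facial landmarks expanded by
`margin × max(box width, box height)` per side (default margin 0.1, a
conventional loose-crop value; nothing in the method constrains it) and
clamped to the frame. One box, computed from the **onset** frame, is applied
to every frame of the clip: per-frame boxes would inject crop jitter into the
residual sums, which must reflect facial motion only. Resampling to the
network input size (default 320×320) is bilinear; when the box already has
the target size the pixels pass through bit-exactly. The landmark source is
pluggable — any callable `frame → LandmarkSet` — and all tests inject
landmarks from CSVs or the synthetic generator, so no detector model is ever
downloaded. No alignment or rotation normalization is performed beyond the
crop.

### CGPO tiling (`cgpo`)

Two pyramid levels: the input (320×320) and one Gaussian reduction (160×160)
using the classical separable 5-tap binomial kernel (1,4,6,4,1)/16 with
reflect-padded borders and decimation by 2. The grid rule for the native
level is `stride = round(tile_size · (1 − α))`, offsets advancing by the
stride with the final offset clamped to `image − tile`; at α = 0.3 this gives
offsets {0, 112, 160} per axis, hence 1 + 3×3 = **10 tiles** of 160×160.
This grid rule is a reconstruction: the method is specified only by α = 0.3
and the 10-tile count, and one downsampled view plus a clamped 3×3 grid is
the unique simple geometry that produces it. Only the native level is
multi-cropped (consistent with tile 0 receiving no position embedding);
adjacent tiles share 30% of their width, the clamped last tile slightly more.
Tile order — downsampled first, then row-major (y outer, x inner) — is fixed,
because position embeddings are ordinal and must be stable across runs. The
same geometry scales to any input with `input = 2 × tile` (e.g. 128 → 64
tiles in the reference study) and still yields 10 tiles.

### Augmentation (`augment`)

Four stages in fixed order, all draws from one seeded generator: (1)
brightness/contrast/saturation each scaled by an independent uniform factor
from [0.2, 1.8] and hue shifted uniformly in [−0.5, 0.5] of the hue wheel
(the conventional [0, 1] parameterization); (2) grayscale with probability
0.2; (3) horizontal flip with probability 0.5; (4) rotation uniform in
[−15°, 15°], bilinear, replicated borders. Jitter factors are drawn
independently per property; contrast and saturation blend against the mean
gray and per-pixel gray respectively (the standard photometric-jitter
semantics). Augmentation is applied to the residual image *before* tiling so
all 10 tiles of a sample see one consistent transform; applying it per tile
would decorrelate overlapping crops. It is training-only and disabled in the
reference study (the synthetic task does not need it and determinism is
simpler to audit without it).

### CropNet (`model`)

The shared extractor is a stem convolution (3×3, stride 2) followed by one
MB6 inverted-bottleneck block (1×1 expand ×6 → depthwise 3×3 → 1×1 project,
batch norm + ReLU6) per step of a strictly increasing channel schedule, then
the head conv → batch norm → global average pooling → fully connected to 24
dimensions. The default schedule is a desk-scale (16, 32, 64, 96); the
reference study uses (8, 16, 32). Weight sharing across tiles is assumed
throughout — separate extractors would multiply parameters tenfold. The nine
cropped tiles get trainable position embeddings initialized i.i.d. normal
with mean 0 and variance 0.2 (σ ≈ 0.447); fusion is elementwise addition
(the embedding has the same dimension as the feature, and the subsequent
"mix by splicing" is the concatenation, so ⊕ cannot itself be
concatenation), followed by concatenation to a 240-d vector and one linear
layer to the class logits. The classifier is a single linear map — no hidden
structure is specified beyond "fully connected".

The loss is label-smoothing cross-entropy with target
`q_k = (1−ε)·1[k = true] + ε/C`; ε defaults to 0.1 (unstated in the source
method; 0.1 is the community default) and ε = 0 recovers plain
cross-entropy. The optimizer is Adam (lr 1e-2 in the reference study); the
optimizer slot is deliberately generic — any adaptive first-order method
fits, and no projection-step variant is reproduced. The whole stack
(im2col convolutions, tap-loop depthwise convolutions, batch norm with
running statistics, backprop, Adam) is float32 numpy, single-threaded and
deterministic for a fixed seed. ImageNet pretraining / transfer is out of
scope; all training here is from random initialization.

### Metrics and protocol (`metrics`)

UF1 = mean over classes of `2TP_i / (2TP_i + FP_i + FN_i)`; UAR = mean of
`TP_i / N_i`; accuracy = `ΣTP_i / N`. A class with TP = FP = FN = 0 has an
undefined (0/0) F1 term, which is defined as 0; UAR raises for a class with
zero support rather than silently dropping it. LOSO folds are ordered by
subject id and partition the clips. Composite scoring **pools** the
predictions of all folds and computes the metrics once over the pool
(averaging per-fold scores is the rejected alternative — it overweights
small subjects). Per-dataset scores can be obtained by restricting the
pooled predictions to a subset of clips.

## Synthetic data (`synthdata`)

The generator emulates exactly the statistical structure the method exploits:

- a schematic per-subject face (background, elliptical face, eyes, brows,
  nose, mouth) with subject-seeded jitter of geometry and coloration, plus a
  consistent synthetic 68-point landmark set;
- per clip, a localized Gaussian intensity bump (σ = 0.05 × frame size)
  whose amplitude ramps linearly from 0 at onset to `motion_amplitude` at
  apex and decays toward the offset, centred in a class-specific region —
  class 0 left mouth corner, class 1 left brow, class 2 nose tip;
- i.i.d. Gaussian pixel noise (σ = 2 grey levels) and a per-frame
  multiplicative illumination factor uniform in [0.99, 1.01].

Defaults: 24-frame clips with onset/apex/offset at 10% / 60% / 90% of the
clip, amplitude 50. The amplitude is chosen so a typical key-frame residual
sum (≈ 2.7 × amplitude at the bump centre under the linear ramp) stays below
the ARS wraparound point of 256 — matching the regime in which ARS is meant
to operate — while remaining far above the noise floor. Motion is additive
intensity change, not geometric warping: it exercises every pipeline stage
(window, key frames, residuals, cropping, tiling, learning) and is exactly
reproducible. What it does **not** emulate: real facial texture, geometric
muscle deformation, FACS action-unit structure, head pose, or camera noise
statistics. Passing the end-to-end tests therefore shows the pipeline
recovers localized ramped intensity signals under LOSO — a necessary
correctness property — not that it reaches any particular accuracy on real
micro-expression corpora.

## The reference study (`experiments`)

6 subjects × 6 clips × 3 balanced classes at 128-px frames (CGPO 128 → 64-px
tiles, still 10 of them), tiny (8, 16, 32) backbone, 20 epochs of Adam at
lr 1e-2, batch 8, label smoothing 0.1, augmentation off, LOSO with pooled
scoring. These problem sizes were fixed once so that one study (six trained
networks) completes in ~2.5 minutes on a single CPU core; the geometry and
all method constants (α, n_key, gmin/gmax, embedding variance) are the
reference values. Four arms: ARS, RRS, the raw-apex baseline, and an ARS
control with `motion_amplitude = 0` (no class signal, so pooled UAR should
sit in the 3σ chance band around 1/3 for n = 36). The expected ordering —
both residual methods above the apex baseline — reflects the generator's
design: residuals subtract the static face, leaving an almost clean class
signal, while the apex baseline must find a subtle bump on top of
subject-varying face structure.

## Degenerate inputs and tie-breaks

- Single-frame windows (`start = end`) give five identical key frames and a
  zero residual map; ARS is then all-zero and RRS all-`gmin`.
- `round()` in the CGPO stride uses Python's banker's rounding; offsets are
  deduplicated preserving order, so `tile = image` always yields `[0]`.
- Batch-norm evaluation before any training step uses the initialized
  running statistics (mean 0, variance 1).
- Clips are validated eagerly (shape consistency, index ranges) with errors
  naming the clip id.

## Known limitations

- No optical-flow baselines, no apex spotting, no video-container decoding,
  no face detector bundled (landmarks are injected or precomputed).
- The numpy network trains small models on small images; it is a CPU
  research implementation, not a GPU training framework, and no attempt is
  made to reproduce published benchmark accuracies on the restricted
  corpora.
- The exact full-size channel schedule of the original extractor is not
  reproduced; `BackboneSpec` accepts any strictly increasing schedule.
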