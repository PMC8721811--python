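# microres

Micro-expression recognition from **pixel residual sums**.

Micro-expressions are involuntary facial expressions lasting roughly 1/25 to
1/3 of a second. Recognizing them from video is hard for three reasons: the
motion is subtle, consecutive frames are highly redundant, and illumination
changes easily swamp the signal. `microres` implements a complete recognition
pipeline for annotated clips (onset / apex / offset frame indices plus an
emotion label) built around two temporal preprocessing operators, a
multi-scale tiling module, and a position-embedded convolutional classifier —
together with a synthetic clip generator, because the spontaneous
micro-expression corpora (CASME II, SMIC-HS, SAMM) are access-restricted.

## The method

**1. Analysis window and key frames.** With `start = onset` and

```
end = min(onset + 10, offset)   if apex − onset < 10
      min(apex, offset)         otherwise
```

five key frames 𝔽 are sampled at `gap = ⌈(end − start)/(N_key + 1)⌉`:
`F_k = min(start + k·gap, end)` with the last element pinned to `end`
(`N_key = 5` by default).

**2. Residual-sum images.** Per pixel and channel,

```
diff(x,y,z) = Σ_{f∈𝔽} |Q_f(x,y,z) − Q_start(x,y,z)|
ARS = diff mod 256
RRS = (diff − min diff) / (max diff − min diff) · (gmax − gmin) + gmin
```

with `gmin = 0, gmax = 255`. ARS keeps absolute accumulated displacement
(wrapping at 256); RRS min–max rescales it, emphasising the regions of
largest relative motion. Either collapses a clip to a single H×W×3 image.

**3. CGPO tiling.** The 320×320 preprocessed image is reduced once with a
Gaussian pyramid (5-tap binomial kernel) and both scales are cut into 160×160
tiles with overlap factor α = 0.3 (stride `round(160·(1−α)) = 112`, last tile
clamped to the border): 1 downsampled full view + 3×3 overlapping crops =
**10 tiles**.

**4. CropNet.** One weight-shared extractor (MB6 inverted-bottleneck blocks
with progressively increasing channels, then conv → batch norm → adaptive
average pooling → fully connected) maps each tile to a feature `z_i ∈ ℝ²⁴`.
The nine cropped tiles receive trainable position embeddings
(`z'_i = z_i ⊕ p_i`, `p_i` initialized N(0, 0.2)); the fused features are
concatenated and classified by a linear layer under a label-smoothing
cross-entropy loss. The network stack (convolutions, batch norm, Adam,
backprop) is implemented in numpy and runs on a single CPU core.

**5. Evaluation.** Leave-one-subject-out cross-validation with pooled
scoring: UF1 (macro F1), UAR (balanced accuracy), accuracy. Composite-dataset
label merging (negative / positive / surprise) and the mid-clip apex fallback
for apex-less datasets are included.

## Worked example

```bash
python examples/01_residual_preprocessing.py
```

```
clip: 24 frames, onset=2 apex=14 offset=22, label='surprise'
analysis window [2, 14], gap=2, key frames (4, 6, 8, 10, 14)
ARS image: max=160, mean=13.29
RRS image: min=0, max=255 (rescaled to [0, 255])
peak residual at (x=66, y=73) — the perturbed facial region; ...
```

The 12-frame onset-to-apex window is subsampled to five key frames; the
accumulated residual peaks at the synthetically perturbed facial region (the
nose for the "surprise" class), which is exactly the signal the classifier
consumes. `examples/02_cgpo_tiling.py` prints the 10-tile decomposition,
`examples/03_loso_recognition.py` trains end-to-end on a small synthetic set
(pooled UF1/UAR/accuracy = 1.000 over 12 held-out predictions, chance 0.5),
and `examples/04_protocol_metrics.py` walks through the scoring formulas
(UF1 = UAR = 0.625, accuracy = 0.667 on a 6-example confusion case).

A thin CLI mirrors the pipeline stages:

```bash
microres synth --out data/ --subjects 6 --seed 0
microres preprocess --data data/ --out pre/ --method ars
microres cgpo pre/s01_c01_ars.png --out-dir tiles/
microres run --config run.yaml --out results/
```

## Layout

```
src/microres/
  clipio.py      clips, annotations, landmarks, label merging, apex fallback
  keyframe.py    analysis window + key-frame sampling
  residual.py    ARS / RRS residual-sum images
  facecrop.py    landmark-driven face cropping (detector pluggable)
  cgpo.py        Gaussian-pyramid overlapping tiling
  augment.py     four-stage stochastic training augmentation
  model/         CropNet, position embeddings, loss, numpy NN stack
  metrics.py     UF1 / UAR / accuracy, LOSO splits, pooled reports
  synthdata.py   synthetic annotated clip generator
  pipeline.py    end-to-end preprocess → train → evaluate
  experiments.py the reference synthetic study
  cli.py         `microres` command-line entry points
```

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
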