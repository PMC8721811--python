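"""CropNet: shared tile feature extractor + position-embedded fusion.

Each of the CGPO tiles passes through one weight-shared convolutional
extractor built from inverted-bottleneck blocks with expansion ratio 6 (the
MobileNetV2-style "MB6" block) whose stage channels increase progressively.
The extractor head is conv -> batch norm -> adaptive average pooling -> fully
connected, producing one 24-dimensional vector z_i per tile.

Tile 0 is the full downsampled image and keeps its raw feature; tiles 1..n-1
are local crops whose position has been destroyed by cropping, so each
receives a trainable position embedding p_i of the same dimension:

    z'_i = z_i + p_i      (i >= 1)

The embeddings are initialized i.i.d. normal with mean 0 and variance 0.2.
The fused features [z_0, z'_1, ..., z'_{n-1}] are concatenated and classified
by a single linear layer under a label-smoothing cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..augment import AugmentConfig, augment_image
from ..cgpo import CgpoConfig, TileSet, cgpo_tiles, grid_positions
from .nn import (
    Adam, BatchNorm2d, Conv2d, DepthwiseConv2d, GlobalAvgPool, Layer, Linear,
    Param, ReLU6, Sequential,
)

__all__ = [
    "BackboneSpec", "TrainConfig", "CropNet", "init_position_embeddings",
    "fuse", "label_smoothing_loss", "train", "predict",
    "FEATURE_DIM", "POSITION_EMBED_VARIANCE",
]

FEATURE_DIM = 24
#: Variance of the normal initializer for position embeddings.
POSITION_EMBED_VARIANCE = 0.2


@dataclass(frozen=True)
class BackboneSpec:
    """Stage channels of the shared extractor; must increase progressively."""

    channel_schedule: tuple[int, ...] = (16, 32, 64, 96)
    expansion: int = 6

    def __post_init__(self) -> None:
        sched = tuple(self.channel_schedule)
        if len(sched) < 1:
            raise ValueError("channel schedule must be non-empty")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError(
                f"channel schedule must be strictly increasing, got {sched}"
            )


class MB6Block(Layer):
    """Inverted bottleneck: 1x1 expand (x6) -> depthwise 3x3 -> 1x1 project.

    A skip connection is used when the block is stride 1 with equal in/out
    channels, as in MobileNetV2.
    """

    def __init__(self, cin: int, cout: int, stride: int, expansion: int,
                 rng: np.random.Generator, name: str) -> None:
        mid = cin * expansion
        self.use_skip = stride == 1 and cin == cout
        self.body = Sequential(
            Conv2d(cin, mid, k=1, stride=1, pad=0, rng=rng, name=f"{name}.expand"),
            BatchNorm2d(mid, name=f"{name}.bn1"),
            ReLU6(),
            DepthwiseConv2d(mid, k=3, stride=stride, rng=rng, name=f"{name}.dw"),
            BatchNorm2d(mid, name=f"{name}.bn2"),
            ReLU6(),
            Conv2d(mid, cout, k=1, stride=1, pad=0, rng=rng, name=f"{name}.project"),
            BatchNorm2d(cout, name=f"{name}.bn3"),
        )

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = self.body.forward(x, train)
        return y + x if self.use_skip else y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = self.body.backward(gy)
        return gx + gy if self.use_skip else gx


def init_position_embeddings(
    dim: int = FEATURE_DIM, count: int = 9, seed: int = 0
) -> np.ndarray:
    """Draw ``count`` embeddings i.i.d. N(0, 0.2) componentwise."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(POSITION_EMBED_VARIANCE),
                      size=(count, dim)).astype(np.float32)


def fuse(z: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Add position embeddings to the cropped tiles' features and concatenate.

    ``z`` is (n_tiles, dim) or (batch, n_tiles, dim); ``p`` is
    (n_tiles - 1, dim).  Tile 0 (the downsampled full image) passes through
    unchanged; the output is the flat concatenation in tile order.
    """
    z = np.asarray(z)
    p = np.asarray(p)
    squeeze = z.ndim == 2
    if squeeze:
        z = z[None]
    if p.shape != (z.shape[1] - 1, z.shape[2]):
        raise ValueError(
            f"embedding shape {p.shape} does not match features {z.shape[1:]} "
            f"(need {(z.shape[1] - 1, z.shape[2])})"
        )
    fused = z.copy()
    fused[:, 1:, :] += p
    out = fused.reshape(z.shape[0], -1)
    return out[0] if squeeze else out


def label_smoothing_loss(
    logits: np.ndarray, true_class: np.ndarray | int, epsilon: float = 0.1
) -> tuple[float, np.ndarray]:
    """Label-smoothing cross-entropy; returns (mean loss, d loss / d logits).

    The target distribution is q_k = (1 - eps) * [k == true] + eps / C; at
    eps = 0 this is ordinary cross-entropy.
    """
    if not (0 <= epsilon < 1):
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    logits = np.asarray(logits, dtype=np.float64)
    squeeze = logits.ndim == 1
    if squeeze:
        logits = logits[None]
    targets = np.atleast_1d(np.asarray(true_class, dtype=int))
    b, c = logits.shape
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_p = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    q = np.full((b, c), epsilon / c)
    q[np.arange(b), targets] += 1.0 - epsilon
    loss = float(-(q * log_p).sum(axis=1).mean())
    grad = ((np.exp(log_p) - q) / b).astype(np.float32)
    return loss, grad[0] if squeeze else grad


class CropNet:
    """Weight-shared tile extractor + position embeddings + linear classifier."""

    def __init__(
        self,
        n_classes: int,
        backbone: BackboneSpec = BackboneSpec(),
        n_tiles: int = 10,
        feature_dim: int = FEATURE_DIM,
        seed: int = 0,
    ) -> None:
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self.n_classes = n_classes
        self.n_tiles = n_tiles
        self.feature_dim = feature_dim
        self.backbone_spec = backbone
        self.seed = seed
        rng = np.random.default_rng(seed)

        sched = tuple(backbone.channel_schedule)
        layers: list[Layer] = [
            Conv2d(3, sched[0], k=3, stride=2, rng=rng, name="stem"),
            BatchNorm2d(sched[0], name="stem.bn"),
            ReLU6(),
        ]
        for i, (cin, cout) in enumerate(zip(sched, sched[1:])):
            layers.append(MB6Block(cin, cout, stride=2,
                                   expansion=backbone.expansion,
                                   rng=rng, name=f"block{i}"))
        # Extractor head: conv -> BN -> adaptive average pool -> FC to 24-d.
        layers += [
            Conv2d(sched[-1], sched[-1], k=1, stride=1, pad=0, rng=rng, name="head"),
            BatchNorm2d(sched[-1], name="head.bn"),
            GlobalAvgPool(),
            Linear(sched[-1], feature_dim, rng=rng, name="head.fc"),
        ]
        self.extractor = Sequential(*layers)
        self.pos = Param(
            rng.normal(0.0, np.sqrt(POSITION_EMBED_VARIANCE),
                       size=(n_tiles - 1, feature_dim)),
            "pos_embed",
        )
        self.classifier = Linear(n_tiles * feature_dim, n_classes,
                                 rng=rng, name="classifier")

    # -- plumbing ---------------------------------------------------------
    def params(self) -> list[Param]:
        return self.extractor.params() + [self.pos] + self.classifier.params()

    @staticmethod
    def tiles_to_array(tiles: TileSet) -> np.ndarray:
        """(n_tiles, 3, H, W) float32 in [0, 1] from a TileSet."""
        stack = tiles.stack().astype(np.float32) / 255.0
        return stack.transpose(0, 3, 1, 2)

    # -- forward / backward ----------------------------------------------
    def extract_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-tile 24-d features for x of shape (B, n_tiles, 3, H, W)."""
        b, nt = x.shape[:2]
        if nt != self.n_tiles:
            raise ValueError(f"expected {self.n_tiles} tiles, got {nt}")
        flat = x.reshape(b * nt, *x.shape[2:])
        z = self.extractor.forward(flat, train)
        return z.reshape(b, nt, self.feature_dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = self.extract_features(x, train)
        fused = fuse(z, self.pos.value)
        return self.classifier.forward(fused, train)

    def backward(self, dlogits: np.ndarray) -> None:
        gfeat = self.classifier.backward(dlogits)
        b = gfeat.shape[0]
        g = gfeat.reshape(b, self.n_tiles, self.feature_dim)
        self.pos.grad += g[:, 1:, :].sum(axis=0)
        self.extractor.backward(
            g.reshape(b * self.n_tiles, self.feature_dim).astype(np.float32)
        )

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False).argmax(axis=1)


@dataclass
class TrainConfig:
    epochs: int = 20
    lr: float = 1e-2
    batch_size: int = 8
    epsilon: float = 0.1          # label smoothing
    seed: int = 0
    n_classes: int | None = None  # inferred from labels when None
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    cgpo: CgpoConfig = field(default_factory=CgpoConfig)
    augment: AugmentConfig | None = None  # None disables augmentation


def _image_to_tiles(image: np.ndarray, cfg: CgpoConfig) -> np.ndarray:
    return CropNet.tiles_to_array(cgpo_tiles(image, cfg))


def train(
    dataset: list[tuple[np.ndarray, int]], config: TrainConfig
) -> tuple[CropNet, list[dict]]:
    """Train CropNet on (H x W x 3 uint8 image, class index) pairs.

    Runs the augment -> tile -> extract -> fuse -> classify graph under the
    label-smoothing loss.  Deterministic for a fixed seed (single-threaded).
    Returns the model and a per-epoch log of mean loss and accuracy.
    """
    if not dataset:
        raise ValueError("empty dataset")
    labels = np.array([y for _, y in dataset], dtype=int)
    n_classes = config.n_classes or int(labels.max()) + 1
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least two distinct classes")

    n_tiles = 1 + len(grid_positions(config.cgpo.input_size,
                                     config.cgpo.tile_size, config.cgpo.alpha)) ** 2
    model = CropNet(n_classes=n_classes, backbone=config.backbone,
                    n_tiles=n_tiles, seed=config.seed)
    opt = Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    aug_rng = np.random.default_rng(config.seed + 2)

    # Tiles are deterministic without augmentation, so cache them once.
    cached = None
    if config.augment is None:
        cached = np.stack([_image_to_tiles(img, config.cgpo) for img, _ in dataset])

    log: list[dict] = []
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if cached is not None:
                xb = cached[idx]
            else:
                xb = np.stack([
                    _image_to_tiles(
                        augment_image(dataset[i][0], config.augment, aug_rng),
                        config.cgpo,
                    )
                    for i in idx
                ])
            yb = labels[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = label_smoothing_loss(logits, yb, config.epsilon)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            total_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        log.append({"epoch": epoch, "loss": total_loss / n, "accuracy": correct / n})
    return model, log


def predict(
    model: CropNet, images: list[np.ndarray], cgpo: CgpoConfig, batch_size: int = 16
) -> np.ndarray:
    """Predicted class indices for a list of preprocessed uint8 images."""
    tiles = np.stack([_image_to_tiles(img, cgpo) for img in images])
    out = []
    for lo in range(0, len(tiles), batch_size):
        out.append(model.predict(tiles[lo:lo + batch_size]))
    return np.concatenate(out)
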