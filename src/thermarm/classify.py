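"""Four-class activation classification from difference heat maps.

Each session contributes one labeled image per difference pair (by default
(S1,E3) and (S1,S3)): the difference heat map with missing cells imputed to
0 Δ°C, min-max normalized.  The training set is expanded by a full factorial
augmentation (small rotations x scalings x optional Gaussian noise) and
resized to a square classifier resolution; a compact convolutional network
is then trained with Adam and cross-entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import transform as sktf

from .errors import ConfigError, RegionUndefinedError, ThermArmError
from .heatmap import DifferenceHeatMap, HeatMapSet, diff_heatmap, region_means
from .nn import Adam, SmallCNN
from .protocol import MuscleClass

logger = logging.getLogger(__name__)

#: Fixed class order for labels, confusion matrices and probability columns.
CLASS_ORDER = (
    MuscleClass.BICEPS,
    MuscleClass.TRICEPS,
    MuscleClass.DELTOID,
    MuscleClass.VAGUE,
)

DEFAULT_PAIRS = (("S1", "E3"), ("S1", "S3"))


@dataclass(frozen=True)
class LabeledMap:
    """One normalized difference-heat-map image with its activation label."""

    image: np.ndarray
    label: MuscleClass
    session_id: str = ""
    pair: tuple[str, str] = ("S1", "E3")


@dataclass(frozen=True)
class AugmentationConfig:
    """Factorial training-set augmentation.

    Every training image yields ``len(rotations_deg) * len(scales) * 2``
    variants (noise off/on), including the identity combination, each resized
    to ``out_size`` x ``out_size``.
    """

    rotations_deg: tuple[float, ...] = (-1.0, 0.0, 1.0)
    scales: tuple[float, ...] = (0.9, 1.0, 1.1)
    noise_mean: float = 0.07
    noise_sd: float = 0.07
    out_size: int = 244

    def __post_init__(self) -> None:
        if not self.rotations_deg or not self.scales:
            raise ConfigError("rotation and scale lists must be nonempty")
        if self.out_size <= 0:
            raise ConfigError("out_size must be positive")

    @property
    def variants_per_image(self) -> int:
        return len(self.rotations_deg) * len(self.scales) * 2


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe: Adam, cross-entropy, lr 1e-4, batch 16, 50 epochs."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 50
    in_size: int = 64          # square input resolution of the network
    channels: tuple[int, ...] = (8, 16, 32, 32)
    hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ConfigError("hyperparameters must be positive")


@dataclass
class ClassifierModel:
    """Trained network plus its input normalization and training history."""

    net: SmallCNN
    classes: tuple[MuscleClass, ...]
    norm_mean: float
    norm_sd: float
    config: TrainConfig
    history: pd.DataFrame  # columns: epoch, loss, train_accuracy


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set metrics: accuracy, per-item probabilities, confusion counts."""

    accuracy: float
    per_item: pd.DataFrame     # true, predicted + one probability column per class
    confusion: np.ndarray      # rows true class, columns predicted, CLASS_ORDER


def _normalize_map(dm: DifferenceHeatMap) -> np.ndarray:
    """Impute missing cells to 0 Δ°C, then min-max normalize to [0, 1]."""
    img = np.nan_to_num(dm.cells, nan=0.0)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def build_dataset(
    sessions: list[tuple[HeatMapSet, MuscleClass]],
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> list[LabeledMap]:
    """One labeled map per session x pair.

    A map whose difference grid cannot be formed or whose every muscle
    region is missing is excluded (quality flag) with a logged warning.
    """
    out: list[LabeledMap] = []
    for hm_set, label in sessions:
        for pair in pairs:
            try:
                dm = diff_heatmap(hm_set, pair)
                region_means(dm)  # quality flag: all three regions defined
            except (ThermArmError, RegionUndefinedError) as e:
                logger.warning(
                    "skipping session %s pair %s: %s", hm_set.session_id, pair, e
                )
                continue
            out.append(
                LabeledMap(
                    image=_normalize_map(dm),
                    label=MuscleClass(label),
                    session_id=hm_set.session_id,
                    pair=pair,
                )
            )
    return out


def split(
    dataset: list[LabeledMap], test_fraction: float = 0.1, seed: int = 0
) -> tuple[list[LabeledMap], list[LabeledMap]]:
    """Random disjoint train/test partition; test size = floor(fraction * N).

    134 maps at 10% give 121 training and 13 test items.
    """
    if not dataset:
        raise ThermArmError("cannot split an empty dataset")
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError("test_fraction must be in (0, 1)")
    n = len(dataset)
    n_test = int(np.floor(test_fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    test = [dataset[i] for i in order[:n_test]]
    train = [dataset[i] for i in order[n_test:]]
    return train, test


def _rescale_about_center(img: np.ndarray, scale: float) -> np.ndarray:
    """Zoom in/out about the image center, keeping the original shape."""
    if scale == 1.0:
        return img
    h, w = img.shape
    scaled = sktf.rescale(img, scale, mode="edge", anti_aliasing=scale < 1.0)
    sh, sw = scaled.shape
    if scale > 1.0:  # center crop
        r0, c0 = (sh - h) // 2, (sw - w) // 2
        return scaled[r0 : r0 + h, c0 : c0 + w]
    out = np.zeros_like(img)
    r0, c0 = (h - sh) // 2, (w - sw) // 2
    out[r0 : r0 + sh, c0 : c0 + sw] = scaled
    return out


def augment(
    train: list[LabeledMap], config: AugmentationConfig = AugmentationConfig(), seed: int = 0
) -> list[LabeledMap]:
    """Full factorial augmentation: rotations x scales x noise off/on.

    Exactly ``len(train) * config.variants_per_image`` outputs, each resized
    to ``out_size`` x ``out_size``; labels preserved.  The default 3 x 3 x 2
    factorial turns 121 training maps into 2178 images.
    """
    rng = np.random.default_rng(seed)
    out: list[LabeledMap] = []
    for item in train:
        for rot in config.rotations_deg:
            rotated = (
                item.image if rot == 0.0 else sktf.rotate(item.image, rot, mode="edge")
            )
            for scale in config.scales:
                scaled = _rescale_about_center(rotated, scale)
                for noise_on in (False, True):
                    img = scaled
                    if noise_on:
                        img = img + rng.normal(config.noise_mean, config.noise_sd, img.shape)
                    resized = sktf.resize(
                        img.astype(np.float32),
                        (config.out_size, config.out_size),
                        anti_aliasing=False,
                    ).astype(np.float32)
                    out.append(
                        LabeledMap(resized, item.label, item.session_id, item.pair)
                    )
    return out


def _prepare_images(maps: list[LabeledMap], in_size: int) -> np.ndarray:
    """Stack images as (N, 1, in_size, in_size) float32, resizing as needed."""
    imgs = []
    for m in maps:
        img = m.image
        if img.shape != (in_size, in_size):
            img = sktf.resize(img, (in_size, in_size), anti_aliasing=False)
        imgs.append(img.astype(np.float32))
    return np.stack(imgs)[:, None, :, :]


def _encode_labels(maps: list[LabeledMap]) -> np.ndarray:
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    return np.array([index[m.label] for m in maps], dtype=np.int64)


def train_classifier(train: list[LabeledMap], config: TrainConfig = TrainConfig()) -> ClassifierModel:
    """Train the small CNN on labeled maps; deterministic under config.seed.

    Inputs are standardized with the training set's mean/sd (stored on the
    model).  Per-epoch mean batch loss and full-train accuracy are logged to
    the training history.
    """
    if not train:
        raise ThermArmError("training set is empty")
    y = _encode_labels(train)
    if np.unique(y).size < 2:
        raise ThermArmError("training set must contain at least 2 classes")
    x = _prepare_images(train, config.in_size)
    mean, sd = float(x.mean()), float(x.std())
    sd = sd if sd > 1e-12 else 1.0
    x = (x - mean) / sd

    net = SmallCNN(
        in_size=config.in_size,
        n_classes=len(CLASS_ORDER),
        channels=config.channels,
        hidden=config.hidden,
        seed=config.seed,
    )
    opt = Adam(net.layers, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    n = len(train)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            losses.append(net.train_step(x[idx], y[idx], opt))
        preds = net.predict_proba(x).argmax(axis=1)
        acc = float((preds == y).mean())
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": acc})
    return ClassifierModel(
        net=net,
        classes=CLASS_ORDER,
        norm_mean=mean,
        norm_sd=sd,
        config=config,
        history=pd.DataFrame(history),
    )


def evaluate(model: ClassifierModel, test: list[LabeledMap]) -> EvaluationReport:
    """Per-item class probabilities, predictions, accuracy and confusion."""
    if not test:
        raise ThermArmError("test set is empty")
    x = _prepare_images(test, model.config.in_size)
    x = (x - model.norm_mean) / model.norm_sd
    probs = model.net.predict_proba(x)
    preds = probs.argmax(axis=1)
    y = _encode_labels(test)
    k = len(CLASS_ORDER)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y, preds):
        confusion[t, p] += 1
    rows = []
    for i, item in enumerate(test):
        row = {
            "session_id": item.session_id,
            "pair": f"{item.pair[0]}-{item.pair[1]}",
            "true": item.label.value,
            "predicted": CLASS_ORDER[preds[i]].value,
        }
        row.update({f"p_{c.value}": float(probs[i, j]) for j, c in enumerate(CLASS_ORDER)})
        rows.append(row)
    return EvaluationReport(
        accuracy=float((preds == y).mean()),
        per_item=pd.DataFrame(rows),
        confusion=confusion,
    )
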