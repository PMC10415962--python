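"""Stage 2: single-slice skeletal-muscle segmentation and its quality metrics.

The segmenter is a compact U-Net producing a per-pixel muscle probability;
pixels at or above 0.5 are foreground. Evaluation covers the Dice similarity
coefficient, precision, recall (with the empty-vs-empty convention fixed to 1),
the two-way random-effects absolute-agreement single-measure ICC, and Pearson
correlation — the agreement statistics used to compare predicted and manual
cross-sectional areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nn import UNet2d, augment_pair, dice_bce_loss, run_epochs
from .types import AgreementContinuous, MuscleMask, SegmentationMetrics


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters shared by both pipeline stages.

    Defaults mirror the development protocol (100 epochs, initial learning rate
    0.005, 5-fold cross-validation, small random translations/rotations);
    ``model_scale`` widens the network toward full-size variants.
    """

    epochs: int = 100
    initial_lr: float = 0.005
    batch_size: int = 16
    folds: int = 5
    augmentation: tuple[float, float] = (2.0, 3.0)  # (max shift mm, max rotation deg)
    seed: int = 0
    model_scale: float = 1.0

    def validate(self, cross_validating: bool = False) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if cross_validating and self.folds < 2:
            raise ValueError("folds must be >= 2 when cross-validating")


@dataclass
class SegModel:
    """A trained segmentation network plus the context needed to apply it."""

    net: UNet2d
    config: TrainingConfig
    history: list[float] = field(default_factory=list)

    def save(self, path):
        self.net.save(path)

    @classmethod
    def load(cls, path, config: TrainingConfig | None = None):
        return cls(UNet2d.load(path), config or TrainingConfig())


def _make_augment(cfg: TrainingConfig, pixel_mm: float):
    max_shift_px = cfg.augmentation[0] / pixel_mm
    max_rot = cfg.augmentation[1]
    if max_shift_px == 0 and max_rot == 0:
        return None

    def aug(img, mask, rng):
        return augment_pair(img, mask, max_shift_px, max_rot, rng)

    return aug


def train_segmenter(dataset: list[tuple[np.ndarray, MuscleMask]],
                    cfg: TrainingConfig | None = None,
                    base_filters: int = 16,
                    pixel_mm: float = 1.0) -> SegModel:
    """Train the U-Net on (slice image, mask) pairs; deterministic given cfg.seed."""
    cfg = cfg if cfg is not None else TrainingConfig()
    cfg.validate()
    if len(dataset) < 2:
        raise ValueError("need at least 2 training pairs")
    shapes = {img.shape for img, _ in dataset}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent image shapes: {sorted(shapes)}")
    for img, mask in dataset:
        if mask.pixels.shape != img.shape:
            raise ValueError(f"mask shape {mask.pixels.shape} does not match "
                             f"image shape {img.shape}")

    images = np.stack([img for img, _ in dataset]).astype(np.float32)
    masks = np.stack([m.pixels for _, m in dataset]).astype(np.float32)

    nf = max(4, int(round(base_filters * cfg.model_scale)))
    rng = np.random.default_rng(cfg.seed)
    net = UNet2d(base_filters=nf, rng=rng)
    history = run_epochs(net, images, masks, loss_fn=dice_bce_loss,
                         epochs=cfg.epochs, lr=cfg.initial_lr,
                         batch_size=cfg.batch_size, rng=rng,
                         augment=_make_augment(cfg, pixel_mm))
    return SegModel(net=net, config=cfg, history=history)


def segment_muscle(model: SegModel, image: np.ndarray,
                   spacing: tuple[float, float], slice_index: int = 0) -> MuscleMask:
    """Threshold the probability map at 0.5 (inclusive) into a binary mask."""
    if image.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {image.shape}")
    proba = model.net.predict_proba(image.astype(np.float32))
    return MuscleMask(proba >= 0.5, slice_index, spacing)


def segmentation_metrics(pred: MuscleMask, truth: MuscleMask) -> SegmentationMetrics:
    """DSC, precision and recall between two masks on the same grid.

    Conventions: both masks empty -> all metrics 1; prediction empty with
    non-empty truth (or vice versa) -> all 0.
    """
    if pred.pixels.shape != truth.pixels.shape:
        raise ValueError(f"shape mismatch: {pred.pixels.shape} vs {truth.pixels.shape}")
    p, t = pred.pixels, truth.pixels
    tp = int(np.logical_and(p, t).sum())
    fp = int(p.sum()) - tp
    fn = int(t.sum()) - tp
    if tp + fp + fn == 0:
        return SegmentationMetrics(dsc=1.0, precision=1.0, recall=1.0)
    dsc = 2 * tp / (2 * tp + fp + fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return SegmentationMetrics(dsc=dsc, precision=precision, recall=recall)


def icc_absolute_agreement(pairs) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares for n subjects rated by k=2
    methods (here: predicted vs ground-truth areas).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) table")
    n, k = arr.shape
    if n < 3:
        raise ValueError("need at least 3 pairs for the ICC")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_total = ((arr - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise ValueError("zero total variance; ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc)


def pearson_correlation(pairs) -> AgreementContinuous:
    """Sample Pearson r with its two-sided t-based p-value."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) table")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: a coordinate is constant")
    res = stats.pearsonr(x, y)
    return AgreementContinuous(pearson_r=float(res.statistic),
                               pearson_p=float(res.pvalue))
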