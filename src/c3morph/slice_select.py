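"""Stage 1: locate the mid-C3 axial slice with a per-slice regression network.

A densely-connected CNN maps each preprocessed axial slice to its signed
physical distance (mm) from the mid-C3 level — regressing millimetres rather
than slice counts keeps the target meaningful across heterogeneous slice
thicknesses. At inference the per-slice offsets are median-smoothed (window 3)
and the slice with the smallest absolute smoothed offset is selected, ties
going to the inferior (smaller) index.

Localization quality is summarized by Δh = (predicted - truth) x dz in mm,
reported as mean and SD (n-1 denominator) over cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_prep import PreprocessedVolume
from .nn import DenseNetRegressor, augment_pair, mse_loss, run_epochs
from .segment import TrainingConfig
from .types import SliceSelection, SliceSelectionMetrics

#: offsets are divided by this before regression so targets sit near unit scale
OFFSET_SCALE_MM = 50.0
#: slices farther than this from the truth level are left out of training
TRAIN_WINDOW_MM = 45.0


@dataclass
class SliceModel:
    """A trained slice-offset regressor."""

    net: DenseNetRegressor
    config: TrainingConfig
    history: list[float] = field(default_factory=list)

    def save(self, path):
        self.net.save(path)

    @classmethod
    def load(cls, path, config: TrainingConfig | None = None):
        return cls(DenseNetRegressor.load(path), config or TrainingConfig())


def _training_slices(volumes, rng, slices_per_volume):
    images, offsets = [], []
    for pvol, truth_idx in volumes:
        if not (0 <= truth_idx < pvol.voxels.shape[0]):
            raise ValueError(f"truth index {truth_idx} outside volume with "
                             f"{pvol.voxels.shape[0]} slices")
        dz = pvol.spacing[0]
        all_idx = np.arange(pvol.voxels.shape[0])
        offs = (all_idx - truth_idx) * dz
        eligible = all_idx[np.abs(offs) <= TRAIN_WINDOW_MM]
        if slices_per_volume is not None and len(eligible) > slices_per_volume:
            eligible = rng.choice(eligible, size=slices_per_volume, replace=False)
        for z in eligible:
            images.append(pvol.voxels[z])
            offsets.append((z - truth_idx) * dz)
    return (np.stack(images).astype(np.float32),
            np.asarray(offsets, dtype=np.float32) / OFFSET_SCALE_MM)


def train_slice_selector_from_slices(images: np.ndarray, offsets_mm: np.ndarray,
                                     cfg: TrainingConfig | None = None,
                                     growth_rate: int = 8,
                                     pixel_mm: float = 1.0) -> SliceModel:
    """Train the regressor on pre-extracted (slice, signed mm offset) pairs."""
    cfg = cfg if cfg is not None else TrainingConfig()
    cfg.validate()
    if len(images) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    g = max(2, int(round(growth_rate * cfg.model_scale)))
    net = DenseNetRegressor(growth_rate=g, rng=rng)

    aug = None
    if cfg.augmentation != (0.0, 0.0):
        max_shift_px = cfg.augmentation[0] / pixel_mm
        max_rot = cfg.augmentation[1]

        def aug(img, target, rng_):
            img2, _ = augment_pair(img, None, max_shift_px, max_rot, rng_)
            return img2, target

    targets = np.asarray(offsets_mm, dtype=np.float32) / OFFSET_SCALE_MM
    history = run_epochs(net, np.asarray(images, dtype=np.float32), targets,
                         loss_fn=mse_loss, epochs=cfg.epochs, lr=cfg.initial_lr,
                         batch_size=cfg.batch_size, rng=rng, augment=aug)
    return SliceModel(net=net, config=cfg, history=history)


def train_slice_selector(volumes: list[tuple[PreprocessedVolume, int]],
                         cfg: TrainingConfig | None = None,
                         growth_rate: int = 8,
                         slices_per_volume: int | None = None) -> SliceModel:
    """Train the offset regressor; deterministic given cfg.seed.

    ``slices_per_volume`` caps how many axial slices per volume enter the
    training set (sampled without replacement near the landmark); None uses
    every slice within the training window.
    """
    cfg = cfg if cfg is not None else TrainingConfig()
    cfg.validate()
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(cfg.seed)
    images, targets_scaled = _training_slices(volumes, rng, slices_per_volume)
    return train_slice_selector_from_slices(
        images, targets_scaled * OFFSET_SCALE_MM, cfg,
        growth_rate=growth_rate, pixel_mm=volumes[0][0].spacing[1])


def _median3(values: np.ndarray) -> np.ndarray:
    padded = np.pad(values, 1, mode="edge")
    stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
    return np.median(stacked, axis=0)


def predict_mid_c3(model: SliceModel, vol: PreprocessedVolume) -> SliceSelection:
    """Evaluate every axial slice and pick the zero crossing of the offsets."""
    n = vol.voxels.shape[0]
    if n < 3:
        raise ValueError(f"volume has only {n} slices; need at least 3")
    offsets = model.net.predict_offsets(vol.voxels.astype(np.float32),
                                        scale=OFFSET_SCALE_MM)
    smoothed = _median3(offsets)
    predicted = int(np.argmin(np.abs(smoothed)))  # ties -> smaller index
    lo, hi = max(0, predicted - 2), min(n, predicted + 3)
    confidence = float(np.std(offsets[lo:hi] - smoothed[lo:hi]))
    return SliceSelection(predicted_index=predicted, per_slice_offsets=offsets,
                          confidence=confidence)


def evaluate_slice_selection(pairs) -> SliceSelectionMetrics:
    """Δh statistics over (predicted_index, truth_index, dz) triples."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty input")
    deltas = []
    for pred, truth, dz in pairs:
        if dz <= 0:
            raise ValueError(f"dz must be positive, got {dz}")
        deltas.append((pred - truth) * dz)
    deltas = np.asarray(deltas, dtype=float)
    sd = float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0
    return SliceSelectionMetrics(delta_h_mean=float(deltas.mean()),
                                 delta_h_sd=sd, delta_h_values=deltas)


def kfold_indices(n: int, folds: int, seed: int,
                  strata: np.ndarray | None = None) -> list[np.ndarray]:
    """Seeded k-fold split, optionally stratified (e.g. by mid-C3 tercile)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    if strata is None:
        order = rng.permutation(n)
        return [order[i::folds] for i in range(folds)]
    strata = np.asarray(strata)
    fold_lists: list[list[int]] = [[] for _ in range(folds)]
    for value in np.unique(strata):
        members = rng.permutation(np.flatnonzero(strata == value))
        for i, idx in enumerate(members):
            fold_lists[i % folds].append(idx)
    return [np.sort(np.array(f, dtype=int)) for f in fold_lists]
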