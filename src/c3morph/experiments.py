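"""Scaled-down phantom experiments: reduced networks on synthetic neck CT.

These are the package's reference experiments: a 500-train / 100-test phantom
study for each pipeline stage, sized for a single CPU. The segmentation
experiment trains the reduced U-Net (16 base filters, 96x96 grid at 2 mm) and
reports mean Dice and the Pearson correlation of predicted vs truth
cross-sectional areas on the held-out phantoms; the slice-selection experiment
trains the reduced offset regressor and reports the fraction of held-out
phantoms localized within one slice plus the Δh summary.

Phantoms are streamed (generated, preprocessed, and discarded one at a time),
so memory stays flat in the number of phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_prep import PreprocessConfig, conform_mask, preprocess
from .morphometry import csa_from_mask
from .phantom import PhantomSpec, iter_phantom_set
from .segment import (TrainingConfig, segment_muscle, segmentation_metrics,
                      pearson_correlation, train_segmenter)
from .slice_select import (TRAIN_WINDOW_MM, evaluate_slice_selection,
                           predict_mid_c3, train_slice_selector_from_slices)
from .types import CTVolume

#: coarse grid used by the reduced experiments: 2 mm pixels on a 96x96 crop
REDUCED_PREPROCESS = PreprocessConfig(hu_window=(-1024.0, 1024.0),
                                      target_inplane_spacing=(2.0, 2.0),
                                      crop_shape=(96, 96))


def reduced_training_config(seed: int, epochs: int, lr: float = 3e-3,
                            batch_size: int = 8) -> TrainingConfig:
    """Reduced-run hyperparameters; augmentation off (the phantom set already
    randomizes geometry, spacing and noise)."""
    return TrainingConfig(epochs=epochs, initial_lr=lr, batch_size=batch_size,
                          augmentation=(0.0, 0.0), seed=seed)


@dataclass
class SegmentationExperimentResult:
    mean_dsc: float
    median_dsc: float
    pearson_r: float
    pearson_p: float
    dsc_values: np.ndarray
    csa_truth: np.ndarray
    csa_pred: np.ndarray
    history: list[float]
    n_train: int
    n_test: int
    model: object = None


def _mid_slice_pair(ph, cfg: PreprocessConfig):
    """Preprocessed mid-C3 slice image and conformed truth mask for one phantom."""
    mid = ph.truth_mid_c3
    vol1 = CTVolume(ph.volume.voxels[mid:mid + 1], ph.volume.spacing,
                    source_id=ph.volume.source_id)
    pre = preprocess(vol1, cfg)
    mask = conform_mask(ph.truth_mask, pre)
    return pre.voxels[0], mask


def segmentation_experiment(seed: int = 42, n_train: int = 500,
                            n_test: int = 100, epochs: int = 11,
                            base_filters: int = 16) -> SegmentationExperimentResult:
    """Train the reduced U-Net on phantom mid-C3 slices and score the held-out set."""
    base = PhantomSpec()
    cfg = REDUCED_PREPROCESS
    train_pairs, test_pairs = [], []
    for i, ph in enumerate(iter_phantom_set(base, n_train + n_test, seed)):
        pair = _mid_slice_pair(ph, cfg)
        (train_pairs if i < n_train else test_pairs).append(pair)

    tc = reduced_training_config(seed=seed, epochs=epochs)
    model = train_segmenter(train_pairs, tc, base_filters=base_filters,
                            pixel_mm=cfg.target_inplane_spacing[0])

    dscs, csa_t, csa_p = [], [], []
    for image, truth in test_pairs:
        pred = segment_muscle(model, image, truth.pixel_spacing, truth.slice_index)
        dscs.append(segmentation_metrics(pred, truth).dsc)
        csa_t.append(csa_from_mask(truth))
        csa_p.append(csa_from_mask(pred))
    dscs = np.asarray(dscs)
    csa_t = np.asarray(csa_t)
    csa_p = np.asarray(csa_p)
    corr = pearson_correlation(np.column_stack([csa_t, csa_p]))
    return SegmentationExperimentResult(
        mean_dsc=float(dscs.mean()), median_dsc=float(np.median(dscs)),
        pearson_r=corr.pearson_r, pearson_p=corr.pearson_p,
        dsc_values=dscs, csa_truth=csa_t, csa_pred=csa_p,
        history=model.history, n_train=n_train, n_test=n_test, model=model)


@dataclass
class SliceSelectionExperimentResult:
    within_one_slice: float
    delta_h_mean: float
    delta_h_sd: float
    predictions: list[tuple[int, int, float]]
    history: list[float]
    n_train: int
    n_test: int
    model: object = None


def slice_selection_experiment(seed: int = 42, n_train: int = 500,
                               n_test: int = 100, epochs: int = 8,
                               slices_per_volume: int = 4
                               ) -> SliceSelectionExperimentResult:
    """Train the reduced offset regressor and localize held-out phantoms."""
    base = PhantomSpec()
    cfg = REDUCED_PREPROCESS
    rng = np.random.default_rng(seed)
    images, targets = [], []
    test_volumes = []
    for i, ph in enumerate(iter_phantom_set(base, n_train + n_test, seed)):
        if i < n_train:
            # preprocess only the sampled slices; the in-plane geometry is
            # z-independent so the conformed grid matches the full-volume one
            dz = ph.volume.spacing[0]
            all_idx = np.arange(ph.volume.n_slices)
            offs = (all_idx - ph.truth_mid_c3) * dz
            eligible = all_idx[np.abs(offs) <= TRAIN_WINDOW_MM]
            chosen = rng.choice(eligible, size=min(slices_per_volume, len(eligible)),
                                replace=False)
            sub = CTVolume(ph.volume.voxels[np.sort(chosen)], ph.volume.spacing,
                           source_id=ph.volume.source_id)
            pre = preprocess(sub, cfg)
            for j, z in enumerate(np.sort(chosen)):
                images.append(pre.voxels[j])
                targets.append((z - ph.truth_mid_c3) * dz)
        else:
            pre = preprocess(ph.volume, cfg)
            test_volumes.append((pre, ph.truth_mid_c3))

    tc = reduced_training_config(seed=seed, epochs=epochs, batch_size=16)
    model = train_slice_selector_from_slices(
        np.stack(images), np.asarray(targets, dtype=np.float32), tc)

    predictions = []
    for pre, truth in test_volumes:
        sel = predict_mid_c3(model, pre)
        predictions.append((sel.predicted_index, truth, pre.spacing[0]))
    metrics = evaluate_slice_selection(predictions)
    within = float(np.mean([abs(p - t) <= 1 for p, t, _ in predictions]))
    return SliceSelectionExperimentResult(
        within_one_slice=within, delta_h_mean=metrics.delta_h_mean,
        delta_h_sd=metrics.delta_h_sd, predictions=predictions,
        history=model.history, n_train=n_train, n_test=n_test, model=model)
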