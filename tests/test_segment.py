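"""Segmentation metrics and agreement statistics, each cross-checked against an
independent brute-force oracle, plus smoke/determinism contracts of the trainer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from c3morph import MuscleMask, TrainingConfig, train_segmenter, segment_muscle
from c3morph.segment import (icc_absolute_agreement, pearson_correlation,
                             segmentation_metrics)


def _mask(px, spacing=(1.0, 1.0)):
    return MuscleMask(np.asarray(px, dtype=bool), 0, spacing)


def _metrics_oracle(p, t):
    """Direct pixel-count evaluation, independent of the implementation."""
    p, t = np.asarray(p, bool), np.asarray(t, bool)
    tp = np.sum(p & t); fp = np.sum(p & ~t); fn = np.sum(~p & t)
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0
    dsc = 2 * tp / (2 * tp + fp + fn)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return dsc, prec, rec


class TestSegmentationMetrics:
    def test_identity_masks(self, rng):
        px = rng.random((20, 20)) > 0.5
        m = segmentation_metrics(_mask(px), _mask(px))
        assert (m.dsc, m.precision, m.recall) == (1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool); a[:2] = True
        b = np.zeros((10, 10), bool); b[5:] = True
        assert segmentation_metrics(_mask(a), _mask(b)).dsc == 0.0

    def test_hand_counted_overlap(self):
        # |pred| = 4, |truth| = 6, overlap 3
        pred = np.zeros((10, 10), bool); pred.ravel()[[0, 1, 2, 50]] = True
        truth = np.zeros((10, 10), bool); truth.ravel()[[0, 1, 2, 60, 61, 62]] = True
        m = segmentation_metrics(_mask(pred), _mask(truth))
        assert m.dsc == pytest.approx(0.6)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.5)

    def test_empty_conventions(self):
        empty = np.zeros((5, 5), bool)
        full = ~empty
        both = segmentation_metrics(_mask(empty), _mask(empty))
        assert (both.dsc, both.precision, both.recall) == (1.0, 1.0, 1.0)
        miss = segmentation_metrics(_mask(empty), _mask(full))
        assert (miss.dsc, miss.precision, miss.recall) == (0.0, 0.0, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_metrics(_mask(np.zeros((4, 4), bool)),
                                 _mask(np.zeros((5, 5), bool)))

    def test_symmetry_identity_and_monotone_recall_fuzz(self, rng):
        for _ in range(50):
            p = rng.random((12, 12)) > rng.uniform(0.2, 0.8)
            t = rng.random((12, 12)) > rng.uniform(0.2, 0.8)
            m = segmentation_metrics(_mask(p), _mask(t))
            assert m.dsc == segmentation_metrics(_mask(t), _mask(p)).dsc
            assert (m.dsc, m.precision, m.recall) == _metrics_oracle(p, t)
            if m.precision + m.recall > 0:
                assert m.dsc == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall))
            grown = p | (rng.random((12, 12)) > 0.7)
            assert segmentation_metrics(_mask(grown), _mask(t)).recall >= m.recall

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pred=arrays(bool, (8, 8), elements=st.booleans()),
           truth=arrays(bool, (8, 8), elements=st.booleans()))
    def test_dice_bounds_symmetry_and_fscore_identity(self, pred, truth):
        m = segmentation_metrics(_mask(pred), _mask(truth))
        assert 0.0 <= m.dsc <= 1.0
        assert m.dsc == segmentation_metrics(_mask(truth), _mask(pred)).dsc
        if m.precision + m.recall > 0:
            assert m.dsc == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))
        if np.array_equal(pred, truth):
            assert m.dsc == 1.0


def _icc_oracle(pairs):
    """ICC(2,1) via the full two-way ANOVA table, written independently."""
    y = np.asarray(pairs, float)
    n, k = y.shape
    subj = y.mean(1); meth = y.mean(0); g = y.mean()
    ms_subj = k * np.sum((subj - g) ** 2) / (n - 1)
    ms_meth = n * np.sum((meth - g) ** 2) / (k - 1)
    resid = y - subj[:, None] - meth[None, :] + g
    ms_err = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return (ms_subj - ms_err) / (
        ms_subj + (k - 1) * ms_err + k / n * (ms_meth - ms_err))


class TestIcc:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert icc_absolute_agreement(np.column_stack([x, x])) \
            == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        x = np.arange(10.0)
        icc = icc_absolute_agreement(np.column_stack([x, x + 50.0]))
        assert icc < 0.5

    def test_matches_anova_oracle(self, rng):
        for _ in range(50):
            pairs = rng.normal(50, 10, size=(10, 2))
            assert icc_absolute_agreement(pairs) == pytest.approx(
                _icc_oracle(pairs), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        pairs = rng.normal(40, 8, size=(12, 2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "score": pairs.ravel()})
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        # two-way random, absolute agreement, single measure; pingouin labels
        # this ICC2 or ICC(A,1) depending on version
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]
        icc2 = float(row["ICC"].iloc[0])
        assert icc_absolute_agreement(pairs) == pytest.approx(icc2, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([(1.0, 1.0), (2.0, 2.0)])
        with pytest.raises(ValueError):
            icc_absolute_agreement([(3.0, 3.0)] * 5)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(5.0)
        assert pearson_correlation(np.column_stack([x, 2 * x + 1])).pearson_r \
            == pytest.approx(1.0)
        assert pearson_correlation(np.column_stack([x, -x])).pearson_r \
            == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        for _ in range(50):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            expected = (np.sum((x - x.mean()) * (y - y.mean())) /
                        np.sqrt(np.sum((x - x.mean()) ** 2)
                                * np.sum((y - y.mean()) ** 2)))
            got = pearson_correlation(np.column_stack([x, y])).pearson_r
            assert got == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])


def _tiny_dataset(rng, n=6, shape=(16, 16)):
    imgs, masks = [], []
    for _ in range(n):
        img = rng.random(shape).astype(np.float32) * 0.1
        px = np.zeros(shape, bool)
        cy, cx = rng.integers(5, 11, 2)
        px[cy - 3:cy + 3, cx - 3:cx + 3] = True
        img[px] += 0.5
        imgs.append(img)
        masks.append(MuscleMask(px, 0, (1.0, 1.0)))
    return list(zip(imgs, masks))


class TestTrainer:
    def test_defaults_mirror_development_protocol(self):
        cfg = TrainingConfig()
        assert cfg.epochs == 100
        assert cfg.initial_lr == pytest.approx(0.005)
        assert cfg.folds == 5

    def test_smoke_two_epochs_loss_improves(self, rng):
        data = _tiny_dataset(rng)
        cfg = TrainingConfig(epochs=2, initial_lr=1e-3, batch_size=3,
                             augmentation=(0.0, 0.0), seed=0)
        model = train_segmenter(data, cfg, base_filters=4)
        assert len(model.history) == 2
        assert min(model.history) <= model.history[0]
        assert all(np.isfinite(model.history))

    def test_same_seed_is_bit_identical(self, rng):
        data = _tiny_dataset(rng)
        cfg = TrainingConfig(epochs=2, initial_lr=1e-3, batch_size=3,
                             augmentation=(1.0, 2.0), seed=7)
        m1 = train_segmenter(data, cfg, base_filters=4)
        m2 = train_segmenter(data, cfg, base_filters=4)
        assert m1.history == m2.history
        img = data[0][0]
        assert np.array_equal(m1.net.predict_proba(img), m2.net.predict_proba(img))

    def test_shape_mismatch_rejected(self, rng):
        img = rng.random((16, 16)).astype(np.float32)
        bad = MuscleMask(np.zeros((8, 8), bool), 0, (1.0, 1.0))
        with pytest.raises(ValueError):
            train_segmenter([(img, bad)] * 2, TrainingConfig(epochs=1))

    def test_threshold_convention_inclusive_at_half(self, rng):
        """probability exactly 0.5 (logit 0) is foreground."""
        data = _tiny_dataset(rng, n=2)
        cfg = TrainingConfig(epochs=1, initial_lr=1e-4, batch_size=2,
                             augmentation=(0.0, 0.0), seed=0)
        model = train_segmenter(data, cfg, base_filters=4)

        class ZeroNet:
            def predict_proba(self, image):
                return np.full(image.shape, 0.5)

        model.net = ZeroNet()
        mask = segment_muscle(model, data[0][0], (1.0, 1.0))
        assert mask.pixels.all()

    def test_all_zero_probability_gives_empty_mask(self, rng):
        data = _tiny_dataset(rng, n=2)
        cfg = TrainingConfig(epochs=1, initial_lr=1e-4, batch_size=2,
                             augmentation=(0.0, 0.0), seed=0)
        model = train_segmenter(data, cfg, base_filters=4)

        class NoNet:
            def predict_proba(self, image):
                return np.zeros(image.shape)

        model.net = NoNet()
        assert segment_muscle(model, data[0][0], (1.0, 1.0)).n_pixels == 0
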