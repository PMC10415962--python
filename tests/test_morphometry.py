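"""The morphometric chain: CSA unit conversion, the published C3->L3
regression, SMI, and the sex-specific sarcopenia / BMI classifications."""

import numpy as np
import pytest

from c3morph import Biometrics, MuscleMask
from c3morph.morphometry import (CoefficientConfigError, FlaggedValueWarning,
                                 SWARTZ_2016_COEFFICIENTS, SarcopeniaConfig,
                                 c3_to_l3_csa, classify_bmi, classify_sarcopenia,
                                 compute_smi, csa_from_mask, measure)


def _mask(n_pixels, spacing=(1.0, 1.0), shape=(40, 40)):
    px = np.zeros(shape, dtype=bool)
    px.ravel()[:n_pixels] = True
    return MuscleMask(px, 0, spacing)


class TestCsaFromMask:
    def test_unit_conversion(self):
        assert csa_from_mask(_mask(100)) == pytest.approx(1.00)

    def test_empty_mask_is_zero(self):
        assert csa_from_mask(_mask(0)) == 0.0

    def test_anisotropic_spacing(self):
        # 250 px at 0.977 x 0.977 mm -> 250 * 0.977^2 / 100 cm²
        expected = 250 * 0.977 * 0.977 / 100.0
        assert csa_from_mask(_mask(250, spacing=(0.977, 0.977))) \
            == pytest.approx(expected, abs=1e-12)

    def test_additive_over_disjoint_masks(self, rng):
        px = rng.random((30, 30)) > 0.6
        a = px.copy(); a[15:] = False
        b = px.copy(); b[:15] = False
        total = csa_from_mask(MuscleMask(px, 0, (1.1, 0.9)))
        assert csa_from_mask(MuscleMask(a, 0, (1.1, 0.9))) + \
            csa_from_mask(MuscleMask(b, 0, (1.1, 0.9))) == pytest.approx(total)


class TestC3ToL3:
    def test_intercept_only_config_returns_intercept(self):
        cfg = SarcopeniaConfig(c3_to_l3_coefficients={
            "intercept": 12.5, "csa_c3": 0.0, "age": 0.0, "weight": 0.0,
            "sex": 0.0, "sex_coding": {"male": 2.0, "female": 1.0}})
        bio = Biometrics(age=50, sex="male", weight=80, height=1.8)
        assert c3_to_l3_csa(40.0, bio, cfg) == pytest.approx(12.5)

    def test_linearity_in_csa_coefficient(self):
        base = dict(SWARTZ_2016_COEFFICIENTS)
        doubled = dict(base, csa_c3=2 * base["csa_c3"])
        bio = Biometrics(age=60, sex="female", weight=65, height=1.6)
        v1 = c3_to_l3_csa(30.0, bio, SarcopeniaConfig(c3_to_l3_coefficients=base))
        v2 = c3_to_l3_csa(30.0, bio,
                          SarcopeniaConfig(c3_to_l3_coefficients=doubled))
        assert v2 - v1 == pytest.approx(base["csa_c3"] * 30.0, abs=1e-9)

    def test_published_coefficients_on_fixed_vector(self):
        """Independent hand evaluation of the transcribed regression."""
        bio = Biometrics(age=58, sex="male", weight=70, height=1.75)
        c = SWARTZ_2016_COEFFICIENTS
        expected = (c["intercept"] + c["csa_c3"] * 40.0 + c["age"] * 58
                    + c["weight"] * 70 + c["sex"] * c["sex_coding"]["male"])
        assert c3_to_l3_csa(40.0, bio) == pytest.approx(expected, abs=1e-12)
        # the formula must distinguish the sexes through the coding term
        bio_f = Biometrics(age=58, sex="female", weight=70, height=1.75)
        assert c3_to_l3_csa(40.0, bio_f) == pytest.approx(
            expected - c["sex"], abs=1e-9)

    def test_missing_coefficients_refuse_to_run(self):
        incomplete = {"intercept": 1.0, "csa_c3": None, "age": 0.1,
                      "weight": 0.1, "sex": 0.1,
                      "sex_coding": {"male": 2.0, "female": 1.0}}
        cfg = SarcopeniaConfig(c3_to_l3_coefficients=incomplete)
        bio = Biometrics(age=50, sex="male", weight=80, height=1.8)
        with pytest.raises(CoefficientConfigError, match="csa_c3"):
            c3_to_l3_csa(40.0, bio, cfg)
        with pytest.raises(CoefficientConfigError):
            c3_to_l3_csa(40.0, bio, SarcopeniaConfig(c3_to_l3_coefficients=None))

    def test_nonpositive_result_warns_but_preserves_value(self):
        cfg = SarcopeniaConfig(c3_to_l3_coefficients={
            "intercept": -5.0, "csa_c3": 0.0, "age": 0.0, "weight": 0.0,
            "sex": 0.0, "sex_coding": {"male": 2.0, "female": 1.0}})
        bio = Biometrics(age=50, sex="male", weight=80, height=1.8)
        with pytest.warns(FlaggedValueWarning):
            assert c3_to_l3_csa(40.0, bio, cfg) == pytest.approx(-5.0)


class TestSmi:
    @pytest.mark.parametrize("csa_l3,height,expected", [
        (50.0, 1.0, 50.0),
        (50.0, 2.0, 12.5),
        (48.3, 1.75, 48.3 / 1.75 ** 2),
    ])
    def test_values(self, csa_l3, height, expected):
        assert compute_smi(csa_l3, height) == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            compute_smi(50.0, 0.0)

    def test_strictly_decreasing_in_height(self):
        heights = np.linspace(1.4, 2.1, 20)
        smis = [compute_smi(45.0, h) for h in heights]
        assert all(a > b for a, b in zip(smis, smis[1:]))


class TestSarcopeniaClassification:
    def test_sex_specific_thresholds(self):
        assert classify_sarcopenia(45.0, "male") == "sarcopenia"
        assert classify_sarcopenia(45.0, "female") == "no_sarcopenia"

    def test_boundary_is_strict(self):
        assert classify_sarcopenia(52.4, "male") == "no_sarcopenia"
        assert classify_sarcopenia(38.5, "female") == "no_sarcopenia"
        cfg = SarcopeniaConfig(strict_threshold=False)
        assert classify_sarcopenia(52.4, "male", cfg) == "sarcopenia"

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError, match="unspecified"):
            classify_sarcopenia(40.0, "unspecified")

    def test_prevalence_non_increasing_as_thresholds_drop(self, rng):
        smis = rng.uniform(20, 70, size=300)
        prev = []
        for thr in (60.0, 52.4, 45.0, 38.5, 30.0):
            cfg = SarcopeniaConfig(smi_threshold_male=thr)
            prev.append(np.mean([classify_sarcopenia(s, "male", cfg)
                                 == "sarcopenia" for s in smis]))
        assert all(a >= b for a, b in zip(prev, prev[1:]))


class TestBmiClassification:
    def test_example_not_underweight(self):
        bio = Biometrics(age=50, sex="male", weight=70, height=1.70)
        out = classify_bmi(bio)
        assert out["bmi"] == pytest.approx(70 / 1.70 ** 2)
        assert out["underweight_class"] == "not_underweight"
        assert out["overweight_split"] == "under_25"

    def test_boundary_185_is_not_underweight(self):
        bio = Biometrics(age=50, sex="female", weight=18.5 * 1.6 ** 2, height=1.6)
        assert classify_bmi(bio)["underweight_class"] == "not_underweight"

    def test_bmi_17_is_underweight(self):
        bio = Biometrics(age=50, sex="female", weight=17.0 * 1.6 ** 2, height=1.6)
        assert classify_bmi(bio)["underweight_class"] == "underweight"

    def test_overweight_split_at_25(self):
        bio = Biometrics(age=40, sex="male", weight=25.0 * 1.8 ** 2, height=1.8)
        assert classify_bmi(bio)["overweight_split"] == "25_or_over"


class TestMeasureChain:
    def test_full_chain_matches_composition(self):
        mask = _mask(3800, shape=(70, 70))  # 38 cm² at 1 mm pixels
        bio = Biometrics(age=58, sex="male", weight=70, height=1.75)
        m = measure(mask, bio)
        assert m.csa_c3 == pytest.approx(38.0)
        assert m.csa_l3 == pytest.approx(c3_to_l3_csa(38.0, bio))
        assert m.smi == pytest.approx(compute_smi(m.csa_l3, 1.75))

    def test_empty_mask_yields_flagged_measurement(self):
        bio = Biometrics(age=58, sex="male", weight=70, height=1.75)
        m = measure(_mask(0), bio)
        assert m.csa_c3 == 0.0 and m.csa_l3 is None and m.smi is None

    def test_smi_correlation_near_perfect_at_high_mask_fidelity(self):
        """High-fidelity masks (Dice >= 0.95) across the full population area
        range yield near-collinear predicted vs truth SMI (r >= 0.99): the
        morphometric chain does not amplify small segmentation error."""
        from scipy import ndimage

        from c3morph import PhantomSpec, generate_neck_phantom
        from c3morph.segment import pearson_correlation, segmentation_metrics

        rng = np.random.default_rng(7)
        bio = Biometrics(age=60, sex="male", weight=75, height=1.75)
        smi_truth, smi_pred = [], []
        for i, area in enumerate(np.linspace(25.0, 55.0, 20)):
            ph = generate_neck_phantom(
                PhantomSpec(seed=300 + i, n_slices=3, mid_c3_index=1,
                            muscle_area_target=float(area)))
            t = ph.truth_mask.pixels
            inner = t & ~ndimage.binary_erosion(t)
            outer = ndimage.binary_dilation(t) & ~t
            p = (t & ~(inner & (rng.random(t.shape) < 0.25))) \
                | (outer & (rng.random(t.shape) < 0.25))
            pred = MuscleMask(p, 1, ph.truth_mask.pixel_spacing)
            assert segmentation_metrics(pred, ph.truth_mask).dsc >= 0.95
            smi_truth.append(measure(ph.truth_mask, bio).smi)
            smi_pred.append(measure(pred, bio).smi)
        r = pearson_correlation(np.column_stack([smi_truth, smi_pred])).pearson_r
        assert r >= 0.99
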