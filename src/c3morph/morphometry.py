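"""The diagnostic core: C3 muscle area -> L3-equivalent area -> SMI -> sarcopenia.

Routine head-and-neck CT does not reach the abdomen, so the L3 muscle area that
standard sarcopenia definitions rely on is estimated from the C3 cross-sectional
area with the published regression of Swartz et al. (Oral Oncol 2016):

    CSA_L3 = 27.304 + 1.363*CSA_C3 - 0.671*age + 0.640*weight + 26.442*sex

with sex coded female=1, male=2, CSA in cm², age in years, weight in kg. The
skeletal muscle index is SMI = CSA_L3 / height² (cm²/m²), and sarcopenia is
SMI strictly below the Prado et al. cut points (52.4 male / 38.5 female).
Both the coefficients and the sex coding ship as an explicit, versioned config
block; the conversion refuses to run if any piece is missing, because a silent
default here would corrupt every downstream number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .types import Biometrics, MuscleMask, MuscleMeasurement

log = logging.getLogger(__name__)

#: Published C3->L3 regression (Swartz et al. 2016), with its sex coding.
SWARTZ_2016_COEFFICIENTS = {
    "name": "swartz2016",
    "intercept": 27.304,
    "csa_c3": 1.363,
    "age": -0.671,
    "weight": 0.640,
    "sex": 26.442,
    "sex_coding": {"female": 1.0, "male": 2.0},
}

HEIGHT_PLAUSIBLE_M = (1.2, 2.2)


class CoefficientConfigError(ValueError):
    """The C3->L3 coefficient set is missing or incomplete."""


class FlaggedValueWarning(UserWarning):
    """A computed value is physiologically implausible; it is preserved, not dropped."""


@dataclass(frozen=True)
class SarcopeniaConfig:
    """Thresholds and conversion coefficients for the sarcopenia classification."""

    smi_threshold_male: float = 52.4
    smi_threshold_female: float = 38.5
    c3_to_l3_coefficients: dict = field(
        default_factory=lambda: dict(SWARTZ_2016_COEFFICIENTS))
    bmi_underweight: float = 18.5
    bmi_overweight: float = 25.0
    #: sarcopenia iff SMI strictly below threshold; set False for <= semantics
    strict_threshold: bool = True

    REQUIRED_COEFFS = ("intercept", "csa_c3", "age", "weight", "sex", "sex_coding")

    def validate_coefficients(self) -> None:
        coeffs = self.c3_to_l3_coefficients
        if coeffs is None:
            raise CoefficientConfigError(
                "no C3->L3 coefficient set configured; supply the published "
                "regression coefficients (intercept, csa_c3, age, weight, sex, "
                "sex_coding) before converting")
        missing = [k for k in self.REQUIRED_COEFFS if coeffs.get(k) is None]
        if missing:
            raise CoefficientConfigError(
                f"C3->L3 coefficient set incomplete, missing {missing}; supply "
                "them explicitly rather than relying on placeholders")
        coding = coeffs["sex_coding"]
        if not {"male", "female"} <= set(coding):
            raise CoefficientConfigError(
                "sex_coding must map both 'male' and 'female' to numeric codes")


def csa_from_mask(mask: MuscleMask) -> float:
    """Cross-sectional area of a mask in cm² (pixel count x dy x dx / 100)."""
    dy, dx = mask.pixel_spacing
    return mask.n_pixels * dy * dx / 100.0


def c3_to_l3_csa(csa_c3: float, bio: Biometrics,
                 cfg: SarcopeniaConfig | None = None) -> float:
    """Estimate L3-level muscle area (cm²) from the C3 area and biometrics."""
    cfg = cfg if cfg is not None else SarcopeniaConfig()
    cfg.validate_coefficients()
    if csa_c3 <= 0:
        raise ValueError(f"csa_c3 must be positive, got {csa_c3}")
    c = cfg.c3_to_l3_coefficients
    sex_code = c["sex_coding"][bio.sex]
    csa_l3 = (c["intercept"] + c["csa_c3"] * csa_c3 + c["age"] * bio.age
              + c["weight"] * bio.weight + c["sex"] * sex_code)
    if csa_l3 <= 0:
        warnings.warn(f"estimated L3 CSA is non-positive ({csa_l3:.2f} cm²); "
                      "value preserved and flagged", FlaggedValueWarning,
                      stacklevel=2)
    return float(csa_l3)


def compute_smi(csa_l3: float, height: float) -> float:
    """Skeletal muscle index (cm²/m²) = L3 area / height²."""
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    if not (HEIGHT_PLAUSIBLE_M[0] <= height <= HEIGHT_PLAUSIBLE_M[1]):
        warnings.warn(f"height {height:.2f} m outside the plausible range "
                      f"{HEIGHT_PLAUSIBLE_M}", FlaggedValueWarning, stacklevel=2)
    return float(csa_l3) / height ** 2


def classify_sarcopenia(smi: float, sex: str,
                        cfg: SarcopeniaConfig | None = None) -> str:
    """'sarcopenia' or 'no_sarcopenia' by the sex-specific SMI cut point."""
    cfg = cfg if cfg is not None else SarcopeniaConfig()
    if sex not in Biometrics.VALID_SEX:
        raise ValueError(f"unknown sex category {sex!r}; 'unspecified' rows must "
                         "be excluded upstream")
    if smi < 0:
        raise ValueError(f"smi must be non-negative, got {smi}")
    thr = cfg.smi_threshold_male if sex == "male" else cfg.smi_threshold_female
    below = smi < thr if cfg.strict_threshold else smi <= thr
    return "sarcopenia" if below else "no_sarcopenia"


def classify_bmi(bio: Biometrics, cfg: SarcopeniaConfig | None = None) -> dict:
    """WHO underweight stratum plus the overweight sensitivity split.

    Underweight is strict (< 18.5); not-underweight includes the boundary.
    The sensitivity stratum splits at 25 the same way.
    """
    cfg = cfg if cfg is not None else SarcopeniaConfig()
    bmi = bio.bmi
    return {
        "bmi": float(bmi),
        "underweight_class": "underweight" if bmi < cfg.bmi_underweight
                             else "not_underweight",
        "overweight_split": "under_25" if bmi < cfg.bmi_overweight else "25_or_over",
    }


def measure(mask: MuscleMask, bio: Biometrics,
            cfg: SarcopeniaConfig | None = None) -> MuscleMeasurement:
    """Run the full chain mask -> CSA_C3 -> CSA_L3 -> SMI."""
    cfg = cfg if cfg is not None else SarcopeniaConfig()
    csa_c3 = csa_from_mask(mask)
    if csa_c3 <= 0:
        log.warning("empty muscle mask on slice %d; measurement flagged",
                    mask.slice_index)
        return MuscleMeasurement(csa_c3=0.0)
    csa_l3 = c3_to_l3_csa(csa_c3, bio, cfg)
    smi = compute_smi(csa_l3, bio.height)
    return MuscleMeasurement(csa_c3=csa_c3, csa_l3=csa_l3, smi=smi)
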