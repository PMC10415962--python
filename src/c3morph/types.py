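"""Core value objects shared across the pipeline.

Axial convention: voxel arrays are indexed (z, y, x); the z index increases
toward the head. Spacings are millimetres, areas cm², SMI cm²/m². The signed
slice-localization error Δh follows the same axis (positive = predicted slice
superior to truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CTVolume:
    """A 3D CT image in Hounsfield units with voxel spacing (dz, dy, dx) mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "zyx-superior"
    source_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume.voxels must be 3D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class MuscleMask:
    """Binary muscle mask on one axial slice, with in-plane spacing (dy, dx) mm."""

    pixels: np.ndarray
    slice_index: int
    pixel_spacing: tuple[float, float]

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("MuscleMask.pixels must be 2D")
        if px.dtype != bool:
            uniq = np.unique(px)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("MuscleMask.pixels must be binary")
            px = px.astype(bool)
        self.pixels = px
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class Biometrics:
    """Patient biometrics; height in metres, weight in kg, age in years."""

    age: float
    sex: str
    weight: float
    height: float

    VALID_SEX = ("male", "female")

    def __post_init__(self):
        if self.sex not in self.VALID_SEX:
            raise ValueError(f"sex must be one of {self.VALID_SEX}, got {self.sex!r}")
        for name in ("age", "weight", "height"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def bmi(self) -> float:
        return self.weight / self.height ** 2


@dataclass
class MuscleMeasurement:
    """The morphometric chain for one patient: C3 CSA -> L3 CSA -> SMI."""

    csa_c3: float
    csa_l3: float | None = None
    smi: float | None = None


@dataclass
class EffectEstimate:
    """A hazard or odds ratio with its Wald 95% CI and two-sided p-value."""

    term: str
    ratio: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self):
        if not (self.ci_low <= self.ratio <= self.ci_high):
            raise ValueError(f"CI [{self.ci_low}, {self.ci_high}] does not bracket {self.ratio}")


@dataclass
class SegmentationMetrics:
    dsc: float
    precision: float
    recall: float


@dataclass
class AgreementContinuous:
    icc: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None


@dataclass
class SliceSelection:
    predicted_index: int
    per_slice_offsets: np.ndarray
    confidence: float


@dataclass
class SliceSelectionMetrics:
    delta_h_mean: float
    delta_h_sd: float
    delta_h_values: np.ndarray = field(repr=False, default=None)
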