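"""Synthetic neck-CT phantoms and synthetic clinical cohorts.

The phantom is a parametric stand-in for a contrast-free neck CT: an elliptical
soft-tissue body with a subcutaneous fat rim, an anterior airway, a posterior
vertebral column with alternating vertebral bodies and discs, and three bilateral
muscle compartments (paraspinal, scalene and sternocleidomastoid analogues).
Two properties make the mid-C3 level identifiable to a per-slice regressor, the
way the C3 vertebral body is on real scans: the body cross-section tapers
linearly toward the head, and the vertebral segment containing the target level
is the widest in the column. The combined muscle area at the target slice equals
``muscle_area_target`` (cm²) by construction.

Cohort simulation draws exponential survival times with a configurable
sarcopenia log-hazard, administrative censoring, and a logistic toxicity
outcome, so the outcome-model layer can be tested against known ground truth.

Every generator is a pure, seeded function of its spec: identical specs yield
bit-identical outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CTVolume, MuscleMask

# CT number palette (HU)
HU_AIR = -1000.0
HU_FAT = -80.0
HU_SOFT = 40.0
HU_MUSCLE = 50.0
HU_BONE = 700.0
HU_DISC = 150.0
HU_CLIP = (-1024.0, 3000.0)

# geometry constants (mm unless noted)
BODY_TAPER = 0.2          # body radius decrease per mm toward the head
BODY_ASPECT = 0.92        # rx / ry of the body ellipse
FAT_THICKNESS = 6.0
VERT_CENTER_FRAC = 0.40   # vertebra centre, fraction of body radius below centre
VERT_RADIUS = 9.0
VERT_PERIOD = 19.0        # vertebral body (15) + disc (4)
VERT_BODY_LEN = 15.0
VERT_MULT_C3 = 1.35       # the target level sits in the widest body
VERT_MULT_INFERIOR = 1.0
VERT_MULT_SUPERIOR = 0.9
AIRWAY_CENTER_FRAC = -0.55
AIRWAY_RADII = (8.0, 10.0)   # (ry, rx)
MUSCLE_AREA_FALLOFF = 0.004  # fractional area loss per mm away from the target slice
MUSCLE_AREA_FLOOR = 0.55

# (name, fraction of total area, centre-y and |centre-x| as fractions of body
#  radius, ry/rx aspect); each compartment is mirrored left/right
MUSCLE_LAYOUT = (
    ("paraspinal", 0.36, 0.47, 0.37, 1.6),
    ("scalene", 0.26, -0.05, 0.65, 1.5),
    ("sternocleidomastoid", 0.38, -0.47, 0.39, 1.05),
)

# sampling ranges used by generate_phantom_set
SET_RANGES = {
    "muscle_area_cm2": (25.0, 55.0),
    "dz_mm": (2.0, 3.0),
    "dxy_mm": (1.0, 1.4),
    "noise_sd_hu": (10.0, 18.0),
    "mid_margin_slices": 5,
}

# Bernoulli prevalences for the binary cohort covariates
COVARIATE_PREVALENCE = {
    "age65": 0.30,
    "smoking10py": 0.50,
    "ace27_high": 0.30,
    "nonoropharynx": 0.20,
    "t34": 0.40,
    "n23": 0.70,
    "stage34": 0.85,
}
# P(bmi_class != sarcopenia); 0.165 gives a phi correlation near 0.67 at
# balanced prevalence, matching the observed SMI-BMI coupling strength
BMI_FLIP_PROB = 0.165
PEG_BASE_RATE = 1.0 / 140.0   # per day; median removal ~100-160 days
PEG_LOG_HR_SARCOPENIA = -0.4  # removal hazard; <0 means longer dependency
PEG_CENSOR_DAYS = 1500.0
TOXICITY_BASE_RATE = 0.25


class PhantomGeometryError(ValueError):
    """Requested phantom geometry is infeasible (e.g. muscle exceeds the body)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic neck volume."""

    seed: int = 0
    n_slices: int = 40
    in_plane_shape: tuple[int, int] = (160, 160)
    spacing: tuple[float, float, float] = (2.4, 1.2, 1.2)
    mid_c3_index: int = 20
    muscle_area_target: float = 38.0
    noise_sd: float = 15.0
    body_radius: float = 72.0

    def validate(self) -> None:
        if not (0 <= self.mid_c3_index < self.n_slices):
            raise ValueError(
                f"mid_c3_index {self.mid_c3_index} outside [0, {self.n_slices})")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.muscle_area_target <= 0:
            raise ValueError("muscle_area_target must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.body_radius <= 0:
            raise ValueError("body_radius must be positive")


@dataclass
class PhantomVolume:
    volume: CTVolume
    truth_mid_c3: int
    truth_mask: MuscleMask
    spec: PhantomSpec


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Ground-truth description of a simulated clinical cohort."""

    seed: int = 0
    n: int = 500
    true_log_hr_sarcopenia: float = float(np.log(2.0))
    baseline_hazard: float = 0.004      # events per month
    censor_horizon: float = 72.0        # months
    sarcopenia_prevalence: float = 0.5
    covariate_effects: dict = field(default_factory=lambda: {
        "age65": 0.3, "smoking10py": 0.3, "ace27_high": 0.5,
        "nonoropharynx": 0.8, "t34": 0.5, "n23": 0.0, "stage34": 0.1,
    })
    toxicity_log_or: float = float(np.log(2.25))

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 < self.sarcopenia_prevalence < 1):
            raise ValueError("sarcopenia_prevalence must lie in (0, 1)")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        unknown = set(self.covariate_effects) - set(COVARIATE_PREVALENCE)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


def _body_radius_at(spec: PhantomSpec, z: int) -> float:
    _, dy, dx = spec.spacing
    u = (z - spec.mid_c3_index) * spec.spacing[0]
    fov = min(spec.in_plane_shape[0] * dy, spec.in_plane_shape[1] * dx)
    r = spec.body_radius - BODY_TAPER * u
    return float(np.clip(r, 30.0, 0.47 * fov / BODY_ASPECT))


def _vertebra_width(u: float) -> tuple[float, float]:
    """(radius mm, HU) of the vertebral column at signed offset u from mid-C3."""
    pos = (u + VERT_BODY_LEN / 2) % VERT_PERIOD
    seg = int(np.floor((u + VERT_BODY_LEN / 2) / VERT_PERIOD))
    if seg == 0:
        mult = VERT_MULT_C3
    elif seg < 0:
        mult = VERT_MULT_INFERIOR
    else:
        mult = VERT_MULT_SUPERIOR
    if pos < VERT_BODY_LEN:
        return VERT_RADIUS * mult, HU_BONE
    return 0.45 * VERT_RADIUS * mult, HU_DISC


def _muscle_ellipses(spec: PhantomSpec, z: int) -> list[tuple[float, float, float, float]]:
    """(cy, cx, ry, rx) in mm, centred coordinates, for the six muscle bellies."""
    u = (z - spec.mid_c3_index) * spec.spacing[0]
    r = _body_radius_at(spec, z)
    factor = max(MUSCLE_AREA_FLOOR, 1.0 - MUSCLE_AREA_FALLOFF * abs(u))
    total_mm2 = spec.muscle_area_target * 100.0 * factor
    out = []
    for _, frac, fy, fx, aspect in MUSCLE_LAYOUT:
        a_side = frac / 2.0 * total_mm2
        rx = np.sqrt(a_side / (np.pi * aspect))
        ry = aspect * rx
        for sign in (-1.0, 1.0):
            out.append((fy * r, sign * fx * r, ry, rx))
    return out


def _check_feasible(spec: PhantomSpec) -> None:
    r = spec.body_radius
    iry, irx = r - FAT_THICKNESS, BODY_ASPECT * r - FAT_THICKNESS
    if iry <= 0 or irx <= 0:
        raise PhantomGeometryError("body too small for the fat rim")
    inner_area_cm2 = np.pi * iry * irx / 100.0
    if spec.muscle_area_target > 0.55 * inner_area_cm2:
        raise PhantomGeometryError(
            f"muscle_area_target {spec.muscle_area_target:.1f} cm² exceeds the "
            f"usable body cross-section ({inner_area_cm2:.1f} cm²)")
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    for cy, cx, ry, rx in _muscle_ellipses(spec, spec.mid_c3_index):
        by = cy + ry * np.sin(theta)
        bx = cx + rx * np.cos(theta)
        if np.any((by / iry) ** 2 + (bx / irx) ** 2 > 1.0):
            raise PhantomGeometryError(
                "muscle compartment extends outside the soft-tissue body; "
                "reduce muscle_area_target or enlarge body_radius")


def _render_slice(spec: PhantomSpec, z: int, yy: np.ndarray, xx: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free HU image and muscle mask for one axial slice."""
    u = (z - spec.mid_c3_index) * spec.spacing[0]
    r = _body_radius_at(spec, z)
    img = np.full(yy.shape, HU_AIR, dtype=np.float32)

    body = (yy / r) ** 2 + (xx / (BODY_ASPECT * r)) ** 2 <= 1.0
    img[body] = HU_FAT
    iry, irx = r - FAT_THICKNESS, BODY_ASPECT * r - FAT_THICKNESS
    inner = (yy / iry) ** 2 + (xx / irx) ** 2 <= 1.0
    img[inner] = HU_SOFT

    vr, v_hu = _vertebra_width(u)
    vc = VERT_CENTER_FRAC * r
    vert = ((yy - vc) / vr) ** 2 + (xx / vr) ** 2 <= 1.0
    img[vert & inner] = v_hu

    ac = AIRWAY_CENTER_FRAC * r
    airway = ((yy - ac) / AIRWAY_RADII[0]) ** 2 + (xx / AIRWAY_RADII[1]) ** 2 <= 1.0
    img[airway & inner] = HU_AIR

    muscle = np.zeros(yy.shape, dtype=bool)
    for cy, cx, ry, rx in _muscle_ellipses(spec, z):
        muscle |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    muscle &= inner
    img[muscle] = HU_MUSCLE
    return img, muscle


def generate_neck_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Render a seeded synthetic neck volume with its ground-truth mask.

    Raises :class:`PhantomGeometryError` when the requested muscle area cannot
    be placed inside the body cross-section, and when rasterization misses the
    area target by more than 5%.
    """
    spec.validate()
    _check_feasible(spec)
    dz, dy, dx = spec.spacing
    rows, cols = spec.in_plane_shape
    y = (np.arange(rows) - (rows - 1) / 2.0) * dy
    x = (np.arange(cols) - (cols - 1) / 2.0) * dx
    yy, xx = np.meshgrid(y.astype(np.float32), x.astype(np.float32), indexing="ij")

    vol = np.empty((spec.n_slices, rows, cols), dtype=np.float32)
    truth_mask_px = None
    for z in range(spec.n_slices):
        img, muscle = _render_slice(spec, z, yy, xx)
        vol[z] = img
        if z == spec.mid_c3_index:
            truth_mask_px = muscle

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        vol += rng.standard_normal(vol.shape, dtype=np.float32) * np.float32(spec.noise_sd)
    np.clip(vol, *HU_CLIP, out=vol)

    area_cm2 = truth_mask_px.sum() * dy * dx / 100.0
    if abs(area_cm2 - spec.muscle_area_target) > 0.05 * spec.muscle_area_target:
        raise PhantomGeometryError(
            f"rasterized muscle area {area_cm2:.2f} cm² deviates more than 5% "
            f"from target {spec.muscle_area_target:.2f} cm²")

    volume = CTVolume(vol, spec.spacing, source_id=f"phantom-{spec.seed}")
    mask = MuscleMask(truth_mask_px, spec.mid_c3_index, (dy, dx))
    return PhantomVolume(volume, spec.mid_c3_index, mask, spec)


def _sample_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    margin = min(SET_RANGES["mid_margin_slices"], (base.n_slices - 1) // 2)
    mid = int(rng.integers(margin, max(margin + 1, base.n_slices - margin)))
    area = float(rng.uniform(*SET_RANGES["muscle_area_cm2"]))
    dz = float(rng.uniform(*SET_RANGES["dz_mm"]))
    dxy = float(rng.uniform(*SET_RANGES["dxy_mm"]))
    noise = float(rng.uniform(*SET_RANGES["noise_sd_hu"]))
    seed = int(rng.integers(0, 2**31 - 1))
    return replace(base, seed=seed, mid_c3_index=mid, muscle_area_target=area,
                   spacing=(dz, dxy, dxy), noise_sd=noise)


def iter_phantom_set(base: PhantomSpec, n: int, seed: int):
    """Stream ``n`` randomized phantoms; deterministic given ``seed``."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield generate_neck_phantom(_sample_spec(base, rng))


def generate_phantom_set(base: PhantomSpec, n: int, seed: int) -> list[PhantomVolume]:
    """Materialize :func:`iter_phantom_set` as a list (use the iterator for large n)."""
    return list(iter_phantom_set(base, n, seed))


def sample_phantom_specs(base: PhantomSpec, n: int, seed: int) -> list[PhantomSpec]:
    """The specs :func:`iter_phantom_set` would render, without rendering them."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return [_sample_spec(base, rng) for _ in range(n)]


def generate_clinical_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Simulate a cohort with known sarcopenia effects on survival and toxicity.

    Overall-survival times are exponential with per-patient hazard
    ``baseline_hazard * exp(lp)`` where the linear predictor sums the sarcopenia
    log-HR and the configured covariate log-HRs; administrative censoring at
    ``censor_horizon`` months. PEG-tube duration uses removal as the event, with
    sarcopenia slowing removal (log-HR -0.4), mirroring the convention that a
    removal HR below 1 means longer tube dependency. ``bmi_class`` is a noisy
    binary correlate of sarcopenia used by the model-comparison analyses.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    cols: dict[str, np.ndarray] = {"id": np.array([f"S{i:05d}" for i in range(n)])}
    sarc = (rng.random(n) < spec.sarcopenia_prevalence).astype(np.int64)
    cols["sarcopenia"] = sarc
    flip = rng.random(n) < BMI_FLIP_PROB
    cols["bmi_class"] = np.where(flip, 1 - sarc, sarc).astype(np.int64)
    for name, prev in COVARIATE_PREVALENCE.items():
        cols[name] = (rng.random(n) < prev).astype(np.int64)

    lp = spec.true_log_hr_sarcopenia * sarc
    for name, eff in spec.covariate_effects.items():
        lp = lp + eff * cols[name]
    rate = spec.baseline_hazard * np.exp(lp)
    t = rng.exponential(1.0 / rate)
    event = t <= spec.censor_horizon
    cols["os_time"] = np.minimum(t, spec.censor_horizon)
    cols["os_event"] = event.astype(np.int64)

    peg_rate = PEG_BASE_RATE * np.exp(PEG_LOG_HR_SARCOPENIA * sarc)
    pt = rng.exponential(1.0 / peg_rate)
    cols["peg_time"] = np.minimum(pt, PEG_CENSOR_DAYS)
    cols["peg_event"] = (pt <= PEG_CENSOR_DAYS).astype(np.int64)

    base_logit = np.log(TOXICITY_BASE_RATE / (1 - TOXICITY_BASE_RATE))
    p_tox = 1.0 / (1.0 + np.exp(-(base_logit + spec.toxicity_log_or * sarc)))
    cols["toxicity"] = (rng.random(n) < p_tox).astype(np.int64)

    return pd.DataFrame(cols)


def write_phantom_set(base: PhantomSpec, n: int, seed: int, out_dir) -> Path:
    """Write volume/mask NIfTI pairs plus an index CSV; returns the index path."""
    from .io_prep import save_volume, write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_path = out / "index.csv"
    with open(index_path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["path", "mask_path", "truth_mid_c3", "truth_area_cm2",
                     "dz_mm", "dy_mm", "dx_mm"])
        for i, ph in enumerate(iter_phantom_set(base, n, seed)):
            vpath = out / f"phantom_{i:04d}.nii.gz"
            mpath = out / f"phantom_{i:04d}_mask.nii.gz"
            save_volume(ph.volume, vpath)
            write_mask(ph.truth_mask, ph.volume, mpath)
            area = ph.truth_mask.n_pixels * ph.truth_mask.pixel_spacing[0] * \
                ph.truth_mask.pixel_spacing[1] / 100.0
            wr.writerow([vpath.name, mpath.name, ph.truth_mid_c3,
                         f"{area:.4f}", *[f"{s:.4f}" for s in ph.volume.spacing]])
    return index_path
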