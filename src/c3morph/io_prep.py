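"""CT volume I/O and the preprocessing chain: conversion, normalization,
interpolation, cropping.

NIfTI files are read/written with nibabel and reoriented to canonical (RAS)
axes before being transposed to the package's (z, y, x) layout with z
increasing toward the head. DICOM series are read with pydicom, ordered by
spatial position (never filename), and converted to HU via the rescale tags.

Preprocessing clips intensities to a HU window, maps them affinely to [0, 1],
resamples in-plane to a target spacing (linear for images, nearest for masks),
and center-crops or zero-pads to a fixed grid about the body's center of mass.
The crop offset is recorded so ground-truth masks can be conformed onto the
model grid with the same geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from .types import CTVolume, MuscleMask

log = logging.getLogger(__name__)

BODY_THRESHOLD_HU = -500.0  # voxels above this count toward the body center of mass


class FormatError(ValueError):
    """The on-disk image violates the expected format (mixed series, missing tags)."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    The full-resolution defaults (1.0 mm grid, 256x256 crop) suit body-composition
    practice; the scaled-down experiments use a coarser 2.0 mm / 96x96 variant.
    """

    hu_window: tuple[float, float] = (-1024.0, 1024.0)
    target_inplane_spacing: tuple[float, float] = (1.0, 1.0)
    crop_shape: tuple[int, int] = (256, 256)
    interpolation_order: int = 1

    def validate(self) -> None:
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError(f"hu_window must satisfy lo < hi, got {self.hu_window}")
        if any(s <= 0 for s in self.crop_shape):
            raise ValueError("crop_shape must be positive")
        if any(s <= 0 for s in self.target_inplane_spacing):
            raise ValueError("target_inplane_spacing must be positive")


@dataclass
class PreprocessedVolume:
    """Model-ready tensor: intensities in [0, 1] on the configured grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    crop_offset: tuple[int, int]
    provenance: PreprocessConfig


def save_volume(vol: CTVolume, path) -> Path:
    """Write a CTVolume as NIfTI; (z, y, x) data is stored as (x, y, z) RAS."""
    dz, dy, dx = vol.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.voxels).T.astype(np.float32), affine)
    img.header.set_zooms((dx, dy, dz))
    path = Path(path)
    nib.save(img, path)
    return path


def _load_nifti(path: Path) -> CTVolume:
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise FormatError(f"{path} is not a 3D volume (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path} has non-positive voxel spacing {zooms}")
    # canonical (x, y, z) with z toward the head -> (z, y, x)
    voxels = data.T
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(voxels, spacing, source_id=path.name)


def _load_dicom_dir(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".csv")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise FormatError(f"no DICOM slices found in {path}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise FormatError(f"directory {path} mixes {len(uids)} series "
                          f"(SeriesInstanceUID values differ)")
    for ds in datasets:
        if "PixelSpacing" not in ds:
            raise FormatError(f"slice {ds.filename} is missing PixelSpacing")
        if "ImagePositionPatient" not in ds:
            raise FormatError(f"slice {ds.filename} is missing ImagePositionPatient")
    # order by z position so index increases toward the head
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    intercept = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    voxels = np.stack([ds.pixel_array.astype(np.float32) * slope + intercept
                       for ds in datasets])
    dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    if len(datasets) > 1:
        zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
        dz = float(np.median(np.diff(zs)))
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    if dz <= 0:
        raise FormatError(f"non-positive slice spacing derived from {path}")
    return CTVolume(voxels, (dz, dy, dx), source_id=path.name)


def load_volume(path) -> CTVolume:
    """Load a NIfTI file or a directory holding one DICOM series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        vol = _load_dicom_dir(path)
    else:
        vol = _load_nifti(path)
    log.info("loaded %s: shape %s spacing %s", path, vol.voxels.shape, vol.spacing)
    return vol


def _resample_inplane(voxels: np.ndarray, spacing, target, order: int) -> np.ndarray:
    fy = spacing[1] / target[0]
    fx = spacing[2] / target[1]
    if abs(fy - 1) < 1e-9 and abs(fx - 1) < 1e-9:
        return voxels.astype(np.float32)
    return ndimage.zoom(voxels, (1.0, fy, fx), order=order, mode="nearest",
                        grid_mode=True).astype(np.float32)


def _crop_window(shape_yx, crop_shape, com_yx) -> tuple[int, int]:
    """Top-left origin of the crop; may be negative (zero padding)."""
    oy = int(np.floor(com_yx[0] - crop_shape[0] / 2.0 + 0.5))
    ox = int(np.floor(com_yx[1] - crop_shape[1] / 2.0 + 0.5))
    return oy, ox


def _apply_crop(voxels: np.ndarray, origin: tuple[int, int],
                crop_shape: tuple[int, int], fill: float) -> np.ndarray:
    nz = voxels.shape[0]
    out = np.full((nz, *crop_shape), fill, dtype=np.float32)
    oy, ox = origin
    ys0, ys1 = max(0, oy), min(voxels.shape[1], oy + crop_shape[0])
    xs0, xs1 = max(0, ox), min(voxels.shape[2], ox + crop_shape[1])
    if ys0 < ys1 and xs0 < xs1:
        out[:, ys0 - oy:ys1 - oy, xs0 - ox:xs1 - ox] = voxels[:, ys0:ys1, xs0:xs1]
    return out


def preprocess(vol: CTVolume, cfg: PreprocessConfig | None = None) -> PreprocessedVolume:
    """Normalize, resample and crop a CT volume into a model-ready tensor."""
    cfg = cfg if cfg is not None else PreprocessConfig()
    cfg.validate()
    if vol.voxels.shape[1] < 8 or vol.voxels.shape[2] < 8:
        raise ValueError(f"degenerate volume: in-plane shape {vol.voxels.shape[1:]}")

    res = _resample_inplane(vol.voxels, vol.spacing, cfg.target_inplane_spacing,
                            cfg.interpolation_order)
    body = res > BODY_THRESHOLD_HU
    if body.any():
        com = ndimage.center_of_mass(body)
        com_yx = (com[1], com[2])
    else:
        com_yx = ((res.shape[1] - 1) / 2.0, (res.shape[2] - 1) / 2.0)
    origin = _crop_window(res.shape[1:], cfg.crop_shape, com_yx)
    cropped = _apply_crop(res, origin, cfg.crop_shape, fill=float(cfg.hu_window[0]))

    lo, hi = cfg.hu_window
    norm = (np.clip(cropped, lo, hi) - lo) / (hi - lo)
    spacing = (vol.spacing[0], float(cfg.target_inplane_spacing[0]),
               float(cfg.target_inplane_spacing[1]))
    log.info("preprocessed %s: grid %s spacing %s crop origin %s",
             vol.source_id, norm.shape, spacing, origin)
    return PreprocessedVolume(norm.astype(np.float32), spacing, origin, cfg)


def conform_mask(mask: MuscleMask, pre: PreprocessedVolume) -> MuscleMask:
    """Carry a mask through the same resample+crop as its parent volume.

    Nearest-neighbour resampling keeps the mask binary; the crop origin is the
    one recorded on the preprocessed volume.
    """
    cfg = pre.provenance
    arr = mask.pixels.astype(np.float32)[None]
    spacing3 = (1.0, *mask.pixel_spacing)
    res = _resample_inplane(arr, spacing3, cfg.target_inplane_spacing, order=0)
    cropped = _apply_crop(res, pre.crop_offset, cfg.crop_shape, fill=0.0)
    return MuscleMask(cropped[0] >= 0.5, mask.slice_index,
                      (float(cfg.target_inplane_spacing[0]),
                       float(cfg.target_inplane_spacing[1])))


def write_mask(mask: MuscleMask, ref: CTVolume, path) -> Path:
    """Write a single-slice mask as a uint8 NIfTI with the geometry of ``ref``."""
    if not (0 <= mask.slice_index < ref.n_slices):
        raise ValueError(f"mask slice {mask.slice_index} outside reference volume "
                         f"with {ref.n_slices} slices")
    if mask.pixels.shape != ref.voxels.shape[1:]:
        raise ValueError(f"mask shape {mask.pixels.shape} does not match reference "
                         f"in-plane shape {ref.voxels.shape[1:]}")
    vol = np.zeros(ref.voxels.shape, dtype=np.uint8)
    vol[mask.slice_index] = mask.pixels.astype(np.uint8)
    dz, dy, dx = ref.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(vol.T, affine)
    img.header.set_zooms((dx, dy, dz))
    path = Path(path)
    nib.save(img, path)
    return path


def load_mask(path) -> MuscleMask:
    """Read a mask NIfTI written by :func:`write_mask`."""
    vol = load_volume(path)
    nz = np.flatnonzero(vol.voxels.reshape(vol.n_slices, -1).sum(axis=1))
    slice_index = int(nz[0]) if nz.size else 0
    return MuscleMask(vol.voxels[slice_index] >= 0.5, slice_index,
                      (vol.spacing[1], vol.spacing[2]))
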