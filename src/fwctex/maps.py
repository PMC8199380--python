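"""Fractional-water-content (FWC) parametric maps and ROI utilities.

A two-point Dixon MR acquisition yields co-registered water-only and
fat-only images.  The FWC image divides each water pixel by the total
(water + fat) signal at that pixel, giving the water signal fraction in
[0, 1] — the complement of the clinically used signal fat fraction
(FWC = 1 - FF).  Pixels with zero total signal (air, background) carry
no fraction and are flagged invalid; they are excluded, never zero-filled,
from every downstream statistic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "DixonSlice",
    "FWCMap",
    "ROIMask",
    "compute_fwc_map",
    "threshold_roi",
    "extract_roi_values",
    "load_slice",
    "save_slice",
    "load_mask",
    "save_mask",
]


@dataclass(frozen=True)
class DixonSlice:
    """Paired water-only / fat-only 2D images with pixel spacing in mm."""

    water: np.ndarray
    fat: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (0.78, 0.78)

    def __post_init__(self):
        water = np.asarray(self.water, dtype=float)
        fat = np.asarray(self.fat, dtype=float)
        if water.ndim != 2 or fat.ndim != 2:
            raise ValueError("water and fat must be 2D arrays")
        if water.shape != fat.shape:
            raise ValueError(
                f"water shape {water.shape} != fat shape {fat.shape}"
            )
        if np.any(water < 0) or np.any(fat < 0):
            raise ValueError("water and fat signals must be nonnegative")
        sp = tuple(float(s) for s in self.pixel_spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ValueError(f"pixel spacing must be two positive reals, got {sp}")
        object.__setattr__(self, "water", water)
        object.__setattr__(self, "fat", fat)
        object.__setattr__(self, "pixel_spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.water.shape


@dataclass(frozen=True)
class FWCMap:
    """FWC field in [0, 1] with a validity mask (denominator > 0).

    ``fwc`` holds NaN at invalid pixels; ``valid`` marks where the
    fraction is defined.  Statistics must only ever read ``fwc[valid]``.
    """

    fwc: np.ndarray
    valid: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (0.78, 0.78)

    def __post_init__(self):
        fwc = np.asarray(self.fwc, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if fwc.shape != valid.shape:
            raise ValueError("fwc and valid must share a shape")
        vals = fwc[valid]
        if vals.size and (np.any(vals < 0) or np.any(vals > 1) or np.any(~np.isfinite(vals))):
            raise ValueError("valid FWC values must lie in [0, 1]")
        object.__setattr__(self, "fwc", fwc)
        object.__setattr__(self, "valid", valid)
        object.__setattr__(
            self, "pixel_spacing_mm", tuple(float(s) for s in self.pixel_spacing_mm)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.fwc.shape


@dataclass(frozen=True)
class ROIMask:
    """Boolean region of interest on the image grid.

    ``source`` records provenance: a simulated operator contour
    (``manual-sim``) or an automated fraction-of-maximum threshold
    (``threshold``).
    """

    mask: np.ndarray
    operator_id: str = ""
    source: str = "manual-sim"

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if self.source not in ("manual-sim", "threshold"):
            raise ValueError(f"unknown ROI source {self.source!r}")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def compute_fwc_map(dixon: DixonSlice) -> FWCMap:
    """Build the FWC parametric image: fwc = water / (water + fat).

    Pixels where water + fat == 0 are flagged invalid (NaN sentinel).
    On valid pixels the complement identity FWC + FF = 1 holds exactly.
    """
    total = dixon.water + dixon.fat
    valid = total > 0
    fwc = np.full(dixon.shape, np.nan)
    np.divide(dixon.water, total, out=fwc, where=valid)
    return FWCMap(fwc=fwc, valid=valid, pixel_spacing_mm=dixon.pixel_spacing_mm)


def threshold_roi(image: np.ndarray, fraction: float = 0.42) -> ROIMask:
    """Automated ROI: keep pixels >= fraction x global maximum.

    The 0.42 default mirrors the routine 42%-of-maximum PET lesion
    segmentation setting.  No connected-component filtering is applied.
    """
    image = np.asarray(image, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    finite = np.isfinite(image)
    if not finite.any():
        raise ValueError("image has no finite pixels")
    vmax = np.nanmax(np.where(finite, image, -np.inf))
    if vmax <= 0:
        raise ValueError("image maximum is not positive; threshold ROI would be empty or ill-defined")
    mask = finite & (image >= fraction * vmax)
    return ROIMask(mask=mask, operator_id="auto", source="threshold")


def extract_roi_values(img, roi: ROIMask) -> np.ndarray:
    """Values of a field (FWCMap or plain 2D array) inside roi, valid only.

    Returned in deterministic row-major order.  Raises if the usable
    intersection (roi AND valid pixels) is empty.
    """
    if isinstance(img, FWCMap):
        data, valid = img.fwc, img.valid
    else:
        data = np.asarray(img, dtype=float)
        valid = np.isfinite(data)
    if data.shape != roi.shape:
        raise ValueError(f"field shape {data.shape} != roi shape {roi.shape}")
    sel = roi.mask & valid
    if not sel.any():
        raise ValueError("ROI has no valid pixels; unusable for feature extraction")
    return data[sel]  # boolean indexing is row-major


# --- NIfTI I/O -------------------------------------------------------------
# Single axial slices are stored as 2D NIfTI-1 images whose affine encodes
# pixel spacing on the diagonal.


def _affine(spacing: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = spacing
    return aff


def save_slice(path: str | os.PathLike, data: np.ndarray, spacing: tuple[float, float]) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing))
    nib.save(img, os.fspath(path))


def load_slice(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float]]:
    """Read a 2D NIfTI field; returns (array, pixel_spacing_mm)."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D slice, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    return data, (float(zooms[0]), float(zooms[1]))


def save_mask(path: str | os.PathLike, mask: np.ndarray, spacing: tuple[float, float]) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, os.fspath(path))


def load_mask(path: str | os.PathLike, operator_id: str = "", source: str = "manual-sim") -> ROIMask:
    data, _ = load_slice(path)
    return ROIMask(mask=data > 0.5, operator_id=operator_id, source=source)
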