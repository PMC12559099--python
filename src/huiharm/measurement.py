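"""Liver-function indices from raw measurements.

Three indices are computed here:

* HUI — hepatocellular uptake index, ``V_L * (L20 / S20 - 1)`` where
  ``V_L`` is the liver volume in liters and ``L20`` / ``S20`` are the mean
  liver and spleen signal intensities on the hepatobiliary-phase image.
  The volume unit is **liters** (not mL): on that scale a typical cohort
  mean HUI of ~0.93 L maps to the ICG-PDR scale through a slope of ~-0.17.
* ICG-PDR — plasma disappearance rate of indocyanine green: the OLS slope
  of log concentration against time, in 1/min. Negative for decaying
  curves; no x100 percent scaling is applied.
* ALBI-LP — albumin-bilirubin linear predictor,
  ``0.66 * log10(bilirubin [umol/L]) - 0.085 * albumin [g/L]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VolumetricImage",
    "RoiMask",
    "HuiMeasurement",
    "LabPanel",
    "mean_intensity",
    "mask_volume",
    "compute_hui",
    "compute_icg_pdr",
    "compute_albi_lp",
    "measure_hui_from_files",
    "MM3_PER_LITER",
]

MM3_PER_LITER = 1e6

ALBI_BILIRUBIN_COEF = 0.66  # per log10(umol/L)
ALBI_ALBUMIN_COEF = -0.085  # per g/L


@dataclass(frozen=True)
class VolumetricImage:
    """3-D scalar image with physical voxel spacing in mm."""

    intensities: np.ndarray
    voxel_dims: tuple[float, float, float]
    slice_thickness: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if not np.isfinite(arr).all():
            raise ValueError("intensities must be finite")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be three positive spacings (mm)")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_dims", tuple(float(d) for d in self.voxel_dims))

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest mask on an image grid.

    Any voxel with value > 0 counts fully; no partial-volume weighting.
    """

    data: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        object.__setattr__(self, "data", arr > 0)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class HuiMeasurement:
    """One patient's imaging-derived quantities."""

    patient_id: str
    scanner_id: str
    liver_volume: float  # liters
    liver_mean: float
    spleen_mean: float
    hui: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.liver_volume <= 0:
            raise ValueError("liver_volume must be positive")
        if self.spleen_mean <= 0:
            raise ValueError("spleen_mean must be positive")
        expected = compute_hui(self.liver_volume, self.liver_mean, self.spleen_mean)
        if self.hui is None:
            object.__setattr__(self, "hui", expected)
        elif not np.isclose(self.hui, expected, rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"hui={self.hui} inconsistent with V*(L/S-1)={expected}"
            )

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "scanner_id": self.scanner_id,
            "liver_volume": self.liver_volume,
            "liver_mean": self.liver_mean,
            "spleen_mean": self.spleen_mean,
            "hui": self.hui,
        }


@dataclass(frozen=True)
class LabPanel:
    """One patient's laboratory quantities.

    ICG-PDR follows the negative-valued convention (decay slope per
    minute). ALBI-LP is dimensionless, more negative = better function.
    """

    icg_pdr: float | None = None
    albi_lp: float | None = None
    bilirubin: float | None = None  # umol/L
    albumin: float | None = None  # g/L
    icg_times: tuple[float, ...] | None = None  # minutes
    icg_concentrations: tuple[float, ...] | None = None
    days_from_mri: int = 0

    def __post_init__(self) -> None:
        if self.icg_times is not None:
            t = np.asarray(self.icg_times, dtype=float)
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                raise ValueError("icg_times must be strictly increasing")
        if self.icg_concentrations is not None:
            c = np.asarray(self.icg_concentrations, dtype=float)
            if np.any(c <= 0):
                raise ValueError("icg_concentrations must be positive")

    def resolved_icg_pdr(self) -> float | None:
        if self.icg_pdr is not None:
            return self.icg_pdr
        if self.icg_times is not None and self.icg_concentrations is not None:
            return compute_icg_pdr(self.icg_times, self.icg_concentrations)
        return None

    def resolved_albi_lp(self) -> float | None:
        if self.albi_lp is not None:
            return self.albi_lp
        if self.bilirubin is not None and self.albumin is not None:
            return compute_albi_lp(self.bilirubin, self.albumin)
        return None


def _check_shapes(image: VolumetricImage, mask: RoiMask) -> None:
    if image.intensities.shape != mask.data.shape:
        raise ValueError(
            f"mask shape {mask.data.shape} does not match image shape "
            f"{image.intensities.shape}"
        )


def mean_intensity(image: VolumetricImage, mask: RoiMask) -> float:
    """Arithmetic mean of image intensities over the selected voxels."""
    _check_shapes(image, mask)
    if mask.n_voxels == 0:
        raise ValueError(f"empty {mask.label} mask: no ROI to average over")
    return float(image.intensities[mask.data].mean())


def mask_volume(mask: RoiMask, voxel_dims) -> float:
    """Mask volume in liters: selected-voxel count times voxel volume.

    Equivalent to summing per-slice area x slice spacing; an empty mask
    yields 0.0 with a warning rather than an error.
    """
    dx, dy, dz = (float(d) for d in voxel_dims)
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel_dims must be positive")
    n = mask.n_voxels
    if n == 0:
        warnings.warn(f"empty {mask.label} mask: volume is 0", stacklevel=2)
        return 0.0
    return n * dx * dy * dz / MM3_PER_LITER


def compute_hui(liver_volume: float, liver_mean: float, spleen_mean: float) -> float:
    """HUI = V_L * (L20 / S20 - 1), in liters.

    Negative when the liver enhances less than the spleen.
    """
    if spleen_mean <= 0:
        raise ValueError("spleen mean signal must be positive")
    if liver_volume < 0:
        raise ValueError("liver volume must be non-negative")
    return liver_volume * (liver_mean / spleen_mean - 1.0)


def compute_icg_pdr(times, concentrations) -> float:
    """ICG plasma disappearance rate: OLS slope of ln(C) vs t, per minute.

    Invariant to rescaling concentrations by any positive constant.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concentrations must be 1-D of equal length")
    if t.size < 2:
        raise ValueError("at least 2 samples required")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    slope, _ = np.polyfit(t, np.log(c), 1)
    return float(slope)


def compute_albi_lp(bilirubin: float, albumin: float) -> float:
    """ALBI linear predictor: 0.66*log10(bilirubin) - 0.085*albumin.

    bilirubin in umol/L (must be positive), albumin in g/L.
    """
    if bilirubin <= 0:
        raise ValueError("bilirubin must be positive (umol/L)")
    return ALBI_BILIRUBIN_COEF * float(np.log10(bilirubin)) + ALBI_ALBUMIN_COEF * albumin


def measure_hui_from_files(
    image_path: str | Path,
    liver_mask_path: str | Path,
    spleen_mask_path: str | Path,
    patient_id: str = "",
    scanner_id: str = "",
) -> HuiMeasurement:
    """Compute a :class:`HuiMeasurement` from NIfTI image and mask files.

    Masks must be on the image grid (same shape and affine spacing).
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    voxel_dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    image = VolumetricImage(np.asarray(img.dataobj, dtype=float), voxel_dims)

    def _load_mask(path, label):
        m = nib.load(str(path))
        return RoiMask(np.asarray(m.dataobj), label=label)

    liver = _load_mask(liver_mask_path, "liver")
    spleen = _load_mask(spleen_mask_path, "spleen")
    _check_shapes(image, liver)
    _check_shapes(image, spleen)

    liver_volume = mask_volume(liver, voxel_dims)
    liver_mean = mean_intensity(image, liver)
    spleen_mean = mean_intensity(image, spleen)
    return HuiMeasurement(
        patient_id=patient_id,
        scanner_id=scanner_id,
        liver_volume=liver_volume,
        liver_mean=liver_mean,
        spleen_mean=spleen_mean,
    )
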