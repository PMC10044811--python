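"""Fat-referenced intensity normalization and gray-level discretization.

T1-weighted MR intensities are arbitrary-scale: the same tissue maps to
different raw values across scanners and protocols.  The normalized
intensity value (NIV) rescales every voxel by the mean intensity of a
reference region of interest drawn in fat,

    NIV = raw / mean(raw over reference ROI) * 1000,

so fat sits near 1000 NIV regardless of acquisition.  Texture matrices
additionally require integer gray levels; :func:`discretize` bins the
normalized ROI intensities with a fixed bin width (NIV units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NormalizationError(ValueError):
    """Raised when the reference ROI cannot support normalization."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array of raw intensities.
    spacing_mm
        Per-axis voxel size in millimetres, all strictly positive.
    origin
        Physical offset of the voxel (0, 0, 0) centre.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class NormalizedVolume:
    """NIV-normalized volume; ``reference_mean`` is the denominator used."""

    voxels: np.ndarray
    reference_mean: float
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class GrayLevelMap:
    """Integer gray levels over an ROI.

    ``levels`` holds values 1..n_levels inside the ROI and 0 outside.
    Levels are min-shifted fixed-width bins: a voxel with normalized value x
    gets level floor((x - min_ROI) / bin_width) + 1.
    """

    levels: np.ndarray
    roi_mask: np.ndarray
    n_levels: int
    bin_width: float
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def roi_levels(self) -> np.ndarray:
        """1D array of levels for ROI voxels only."""
        return self.levels[self.roi_mask]


def normalize_niv(volume: ImageVolume, reference_mask: np.ndarray) -> NormalizedVolume:
    """Normalize a raw volume to NIV units using a fat-reference ROI.

    Every voxel is divided by the arithmetic mean raw intensity over
    ``reference_mask`` and multiplied by 1000, so the reference ROI itself
    averages exactly 1000 NIV.

    Raises
    ------
    NormalizationError
        If the reference mask is empty or its mean is not strictly positive.
    """
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.shape != volume.shape:
        raise NormalizationError(
            f"reference mask shape {mask.shape} != volume shape {volume.shape}"
        )
    if not mask.any():
        raise NormalizationError("reference ROI is empty")
    ref_mean = float(volume.voxels[mask].mean())
    if ref_mean <= 0:
        raise NormalizationError(f"reference ROI mean must be > 0, got {ref_mean}")
    return NormalizedVolume(
        voxels=volume.voxels / ref_mean * 1000.0,
        reference_mean=ref_mean,
        spacing_mm=volume.spacing_mm,
        origin=volume.origin,
    )


def discretize(
    normalized: NormalizedVolume | np.ndarray,
    roi_mask: np.ndarray,
    bin_width: float = 25.0,
    spacing_mm: tuple[float, float, float] | None = None,
) -> GrayLevelMap:
    """Bin ROI intensities into integer gray levels of fixed width.

    level(x) = floor((x - min_ROI) / bin_width) + 1; the number of levels is
    the level of the ROI maximum.  The map is invariant to adding a constant
    to all ROI voxels.

    Raises
    ------
    ValueError
        If the ROI is empty or ``bin_width`` is not positive.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    if isinstance(normalized, NormalizedVolume):
        vox = normalized.voxels
        spacing = normalized.spacing_mm
    else:
        vox = np.asarray(normalized, dtype=float)
        spacing = spacing_mm if spacing_mm is not None else (1.0, 1.0, 1.0)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != vox.shape:
        raise ValueError(f"ROI mask shape {mask.shape} != volume shape {vox.shape}")
    if not mask.any():
        raise ValueError("ROI is empty")
    roi_vals = vox[mask]
    lo = roi_vals.min()
    levels = np.zeros(vox.shape, dtype=np.int64)
    # floor() on the exact boundary must open a new bin: 25.0/25 -> level 2.
    levels[mask] = np.floor((roi_vals - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(levels[mask].max())
    return GrayLevelMap(
        levels=levels,
        roi_mask=mask,
        n_levels=n_levels,
        bin_width=float(bin_width),
        spacing_mm=tuple(float(s) for s in spacing),
    )
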