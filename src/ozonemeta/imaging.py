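"""CT image-quality metrics and hypodense-gas segmentation on 3-D volumes.

Metric conventions (the source names the metrics but not their formulas):

* SNR  = mean(signal ROI) / sd(noise ROI)
* CNR  = |mean(ROI A) − mean(ROI B)| / sd(noise ROI)
* SSIM = structural similarity (Wang et al. constants K1=0.01, K2=0.03,
  window 7³), delegated to scikit-image.

Volumes are scalar fields in Hounsfield units with isotropic voxel spacing
in millimetres. Gas appears strongly hypodense (air ≈ −1000 HU), so the
segmenter thresholds below a configurable HU cut (default −400) and labels
26-connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import measure
from skimage.metrics import structural_similarity

from .exceptions import (
    DegenerateNoiseError,
    DegenerateTestError,
    ValidationError,
)

__all__ = [
    "VolumeImage",
    "ROISpec",
    "QCReport",
    "snr",
    "cnr",
    "ssim",
    "paired_metric_test",
    "segment_hypodense_gas",
    "preprocess",
    "load_volume",
    "save_volume",
    "DEFAULT_GAS_HU_THRESHOLD",
]

DEFAULT_GAS_HU_THRESHOLD = -400.0
_HU_RANGE = (-1024.0, 3071.0)


@dataclass(frozen=True)
class VolumeImage:
    """A 3-D scalar field in Hounsfield units with isotropic spacing (mm)."""

    voxels: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValidationError(f"voxels must be 3-D, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("voxel values must be finite")
        if self.spacing <= 0:
            raise ValidationError(f"spacing must be > 0, got {self.spacing}")
        object.__setattr__(self, "voxels", np.asarray(v, dtype=float))


@dataclass(frozen=True)
class ROISpec:
    """A boolean region-of-interest mask congruent with a volume."""

    mask: np.ndarray
    label: str = "signal"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValidationError("ROI mask is empty")
        object.__setattr__(self, "mask", m)

    def check_shape(self, vol: VolumeImage) -> None:
        if self.mask.shape != vol.voxels.shape:
            raise ValidationError(
                f"ROI shape {self.mask.shape} does not match volume {vol.voxels.shape}"
            )


@dataclass(frozen=True)
class QCReport:
    """Image-quality summary for a before/after comparison."""

    snr: float | None = None
    cnr: float | None = None
    ssim: float | None = None
    n_pairs: int = 0
    t_statistic: float | None = None
    p_value: float | None = None


def snr(vol: VolumeImage, signal: ROISpec, noise: ROISpec) -> float:
    """Signal-to-noise ratio mean(signal)/sd(noise)."""
    signal.check_shape(vol)
    noise.check_shape(vol)
    if np.any(signal.mask & noise.mask):
        raise ValidationError("signal and noise ROIs must be disjoint")
    sd_noise = float(np.std(vol.voxels[noise.mask], ddof=1))
    if sd_noise == 0:
        raise DegenerateNoiseError("noise ROI has zero standard deviation")
    return float(np.mean(vol.voxels[signal.mask])) / sd_noise


def cnr(vol: VolumeImage, roi_a: ROISpec, roi_b: ROISpec, noise: ROISpec) -> float:
    """Contrast-to-noise ratio |mean(A) − mean(B)|/sd(noise)."""
    for roi in (roi_a, roi_b, noise):
        roi.check_shape(vol)
    sd_noise = float(np.std(vol.voxels[noise.mask], ddof=1))
    if sd_noise == 0:
        raise DegenerateNoiseError("noise ROI has zero standard deviation")
    return abs(float(np.mean(vol.voxels[roi_a.mask])) - float(np.mean(vol.voxels[roi_b.mask]))) / sd_noise


def ssim(a: VolumeImage, b: VolumeImage, *, data_range: float | None = None) -> float:
    """Structural similarity between two congruent volumes (win 7³)."""
    if a.voxels.shape != b.voxels.shape:
        raise ValidationError("volumes must have identical shapes")
    if data_range is None:
        lo = min(a.voxels.min(), b.voxels.min())
        hi = max(a.voxels.max(), b.voxels.max())
        data_range = float(hi - lo) or 1.0
    win = min(7, *(s if s % 2 == 1 else s - 1 for s in a.voxels.shape))
    return float(
        structural_similarity(a.voxels, b.voxels, data_range=data_range, win_size=win)
    )


def paired_metric_test(before: list[float], after: list[float]) -> QCReport:
    """Two-tailed paired t-test on per-pair metric differences."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValidationError("before/after lists must have equal length")
    if b.size < 2:
        raise ValidationError("need at least 2 pairs")
    diffs = a - b
    if np.std(diffs, ddof=1) == 0:
        raise DegenerateTestError("paired differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return QCReport(n_pairs=int(b.size), t_statistic=float(t), p_value=float(p))


def segment_hypodense_gas(
    vol: VolumeImage,
    hu_threshold: float = DEFAULT_GAS_HU_THRESHOLD,
) -> tuple[np.ndarray, float, int]:
    """Segment gas-density voxels below an HU threshold.

    Returns ``(mask, volume_mm3, n_components)`` where the mask covers all
    voxels strictly below the threshold, volume = count · spacing³, and
    components are counted with 26-neighbour connectivity.
    """
    if not _HU_RANGE[0] <= hu_threshold <= _HU_RANGE[1]:
        raise ValidationError(
            f"threshold {hu_threshold} outside plausible HU range {_HU_RANGE}"
        )
    mask = vol.voxels < hu_threshold
    n_components = 0
    if mask.any():
        _, n_components = measure.label(mask, connectivity=3, return_num=True)
    volume_mm3 = float(mask.sum()) * vol.spacing**3
    return mask, volume_mm3, int(n_components)


def preprocess(vol: VolumeImage) -> VolumeImage:
    """Z-score the volume, then apply a 3×3×3 median filter.

    Deterministic; not idempotent (re-running re-standardizes the filtered
    field). The z-scored field has mean 0 and unit SD before filtering.
    """
    v = vol.voxels
    sd = float(np.std(v))
    if sd == 0:
        raise ValidationError("constant volume cannot be z-scored")
    z = (v - float(np.mean(v))) / sd
    return VolumeImage(ndimage.median_filter(z, size=3), spacing=vol.spacing)


def load_volume(path) -> VolumeImage:
    """Read a NIfTI volume; requires (near-)isotropic voxels."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-6 * max(zooms):
        raise ValidationError(f"anisotropic voxels {zooms}; resample first")
    return VolumeImage(np.asarray(img.get_fdata(), dtype=float), spacing=float(zooms[0]))


def save_volume(vol: VolumeImage, path) -> None:
    """Write a volume (or 0/1 mask) as NIfTI with its isotropic spacing."""
    import nibabel as nib

    affine = np.diag([vol.spacing, vol.spacing, vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))
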