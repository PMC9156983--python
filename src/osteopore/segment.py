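"""Denoising and bone/non-bone binarization of calibrated volumes.

The study protocol smooths with a small Gaussian (σ = 0.8 voxels, support =
1 voxel, i.e. the kernel truncated at ±1 voxel and renormalized) and then
applies a global density threshold of 780 mg HA/ccm.  The threshold
comparison is inclusive (≥), the scanner convention for lower-bound
thresholds; boundaries are mirror-padded so edges are not darkened (which
would bias edge porosity).  The filter is applied to the full volume, then
the ROI is applied at thresholding time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError, InputError
from .roi import RoiMask
from .volume_io import CalibratedVolume

__all__ = [
    "SegmentationParams",
    "BoneMask",
    "gaussian_filter_volume",
    "threshold_bone",
]

#: Global bone threshold used throughout the cortical/trabecular analysis, mg HA/ccm.
DEFAULT_THRESHOLD = 780.0


@dataclass(frozen=True)
class SegmentationParams:
    gauss_sigma: float = 0.8  # voxels
    gauss_support: int = 1  # kernel truncation radius, voxels
    threshold: float = DEFAULT_THRESHOLD  # mg HA/ccm

    def __post_init__(self) -> None:
        if self.gauss_sigma < 0:
            raise InputError("gauss_sigma must be >= 0")
        if int(self.gauss_support) != self.gauss_support or self.gauss_support < 1:
            raise InputError("gauss_support must be an integer >= 1")
        if not self.threshold > 0:
            raise InputError("threshold must be > 0")


@dataclass
class BoneMask:
    """Boolean bone segmentation plus the parameters that produced it."""

    mask: np.ndarray
    params: SegmentationParams | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionError("BoneMask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]


def gaussian_filter_volume(
    volume: CalibratedVolume, sigma: float = 0.8, support: int = 1
) -> CalibratedVolume:
    """Gaussian-smooth a volume with a kernel truncated at ±``support`` voxels.

    The discrete kernel is renormalized to sum 1, so constant volumes are
    unchanged and the interior mean is preserved (mirror boundaries).
    ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise InputError("sigma must be >= 0")
    if int(support) != support or support < 1:
        raise InputError("support must be an integer >= 1")
    if sigma == 0:
        return volume.with_data(volume.data.copy(), "gaussian(sigma=0)")
    # scipy truncates at radius int(truncate*sigma + 0.5); truncate = support/sigma
    # yields a radius of exactly `support` voxels and renormalizes internally.
    truncate = support / sigma
    out = ndimage.gaussian_filter(volume.data, sigma=sigma, truncate=truncate, mode="mirror")
    return volume.with_data(out, f"gaussian(sigma={sigma}, support={support})")


def threshold_bone(
    volume: CalibratedVolume,
    roi: RoiMask | np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    params: SegmentationParams | None = None,
) -> BoneMask:
    """Binarize to bone: density ≥ ``threshold`` AND inside ``roi``.

    With ``roi=None`` the whole volume is eligible.
    """
    mask = volume.data >= threshold
    if roi is not None:
        roi_arr = roi.mask if isinstance(roi, RoiMask) else np.asarray(roi, dtype=bool)
        if roi_arr.shape != volume.data.shape:
            raise DimensionError(
                f"roi shape {roi_arr.shape} does not match volume {volume.data.shape}"
            )
        mask &= roi_arr
    return BoneMask(mask, params or SegmentationParams(threshold=threshold))
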