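"""Trabecular microarchitecture metrics from a bone segmentation.

BV/TV is direct voxel counting.  Tb.Th and Tb.Sp use the model-independent
(Hildebrand–Rüegsegger) local thickness of the bone phase and of the
background-within-ROI phase respectively.  Tb.N uses the plate-model
estimate (BV/TV)/Tb.Th, which keeps the four metrics internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .roi import RoiMask
from .segment import BoneMask
from .thickness import mean_thickness

__all__ = ["MorphometryMetrics", "bv_tv", "tb_n", "trabecular_metrics"]


@dataclass(frozen=True)
class MorphometryMetrics:
    bv_tv: float  # bone volume fraction
    tb_th_mm: float  # trabecular thickness, mm
    tb_n_per_mm: float  # trabecular number, mm⁻¹
    tb_sp_mm: float  # trabecular separation, mm

    def __post_init__(self) -> None:
        if not (0.0 <= self.bv_tv <= 1.0):
            raise InputError(f"bv_tv={self.bv_tv} outside [0, 1]")
        if self.tb_th_mm < 0 or self.tb_sp_mm < 0 or self.tb_n_per_mm < 0:
            raise InputError("morphometry metrics must be >= 0")


def _as_mask(obj) -> np.ndarray:
    if isinstance(obj, (BoneMask, RoiMask)):
        return obj.mask
    return np.asarray(obj, dtype=bool)


def bv_tv(bone: BoneMask | np.ndarray, roi: RoiMask | np.ndarray) -> float:
    """Bone volume fraction: (bone ∧ roi) voxels / roi voxels."""
    bone_arr = _as_mask(bone)
    roi_arr = _as_mask(roi)
    if bone_arr.shape != roi_arr.shape:
        raise InputError("bone and roi shapes differ")
    n_roi = int(roi_arr.sum())
    if n_roi == 0:
        raise InputError("empty ROI")
    return float((bone_arr & roi_arr).sum()) / n_roi


def tb_n(bv_tv_fraction: float, tb_th_mm: float) -> float:
    """Plate-model trabecular number (BV/TV)/Tb.Th, in mm⁻¹."""
    if bv_tv_fraction == 0:
        return 0.0
    if not tb_th_mm > 0:
        raise InputError("tb_th must be > 0")
    return bv_tv_fraction / tb_th_mm


def trabecular_metrics(
    bone: BoneMask | np.ndarray,
    roi: RoiMask | np.ndarray,
    voxel_size: float,
) -> MorphometryMetrics:
    """BV/TV, Tb.Th, Tb.N, Tb.Sp for a trabecular compartment.

    ``voxel_size`` is in µm; thickness metrics are reported in mm.
    """
    bone_arr = _as_mask(bone) & _as_mask(roi)
    frac = bv_tv(bone_arr, roi)
    roi_arr = _as_mask(roi)
    background = roi_arr & ~bone_arr
    th_mm = mean_thickness(bone_arr, voxel_size) / 1000.0 if bone_arr.any() else 0.0
    sp_mm = mean_thickness(background, voxel_size) / 1000.0 if background.any() else 0.0
    n = tb_n(frac, th_mm) if frac > 0 else 0.0
    return MorphometryMetrics(bv_tv=frac, tb_th_mm=th_mm, tb_n_per_mm=n, tb_sp_mm=sp_mm)
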