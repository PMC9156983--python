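"""Reading and writing calibrated micro-CT volumes and flat metrics tables.

The canonical in-memory representation is :class:`CalibratedVolume`: a 3-D
grid of tissue mineral density in mg HA/ccm on an isotropic voxel lattice.
Axis order is fixed as ``(slice, row, column)`` with 0-based indices; crop
ranges are half-open.  Densities may be negative after calibration (air), but
bone thresholding downstream never is.

Two on-disk layouts are supported: a DICOM series (one file per slice, using
the DICOM rescale slope/intercept when present) and a multi-page TIFF with a
YAML sidecar carrying ``voxel_size_um``, ``slope`` and ``intercept``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DimensionError, InputError, SchemaError

__all__ = [
    "CalibrationMap",
    "CalibratedVolume",
    "read_stack",
    "read_tiff_volume",
    "write_tiff_volume",
    "write_metrics",
    "read_metrics",
]


@dataclass(frozen=True)
class CalibrationMap:
    """Linear grey-level to density calibration: density = grey*slope + intercept."""

    slope: float  # (mg HA/ccm) per grey level
    intercept: float = 0.0  # mg HA/ccm

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise InputError("calibration slope must be nonzero")

    def apply(self, grey: np.ndarray) -> np.ndarray:
        return np.asarray(grey, dtype=np.float32) * self.slope + self.intercept


@dataclass
class CalibratedVolume:
    """3-D tissue mineral density grid (mg HA/ccm) with isotropic voxel size (µm)."""

    data: np.ndarray
    voxel_size: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise InputError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise InputError("volume contains non-finite densities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def physical_extent_um(self) -> tuple[float, float, float]:
        """Physical edge lengths (µm) along (slice, row, column)."""
        return tuple(n * self.voxel_size for n in self.data.shape)  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, note: str = "") -> "CalibratedVolume":
        prov = self.provenance + ("; " + note if note else "")
        return CalibratedVolume(data, self.voxel_size, prov)


def _read_slice(path: str | os.PathLike, calibration: CalibrationMap | None):
    """Return (density_2d, provenance_fragment) for one slice file."""
    spath = str(path)
    if spath.lower().endswith((".dcm", ".dicom")) or _looks_like_dicom(spath):
        import pydicom

        ds = pydicom.dcmread(spath)
        grey = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", np.nan))
        intercept = float(getattr(ds, "RescaleIntercept", np.nan))
        if np.isfinite(slope):
            return grey * slope + (intercept if np.isfinite(intercept) else 0.0), "dicom"
        if calibration is None:
            raise InputError(
                f"{spath}: DICOM has no rescale tags and no calibration was given"
            )
        return calibration.apply(grey), "dicom+sidecar"
    grey = tifffile.imread(spath)
    if calibration is None:
        raise InputError(f"{spath}: TIFF slices require an explicit calibration")
    return calibration.apply(grey), "tiff+sidecar"


def _looks_like_dicom(path: str) -> bool:
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_stack(
    paths: Sequence[str | os.PathLike],
    calibration: CalibrationMap | None = None,
    voxel_size: float | None = None,
) -> CalibratedVolume:
    """Read an ordered series of per-slice image files into a calibrated volume.

    Parameters
    ----------
    paths
        Slice files ordered by slice position (distal→proximal).
    calibration
        Grey-to-density map; required for TIFF slices, used as fallback for
        DICOMs lacking rescale tags.
    voxel_size
        Isotropic voxel edge length in µm; required unless the first DICOM
        carries PixelSpacing.
    """
    if len(paths) == 0:
        raise InputError("read_stack requires at least one slice path")
    slices = []
    kinds = set()
    for p in paths:
        density, kind = _read_slice(p, calibration)
        if density.ndim != 2:
            raise DimensionError(f"{p}: slice is not 2-D")
        slices.append(density)
        kinds.add(kind)
    shape0 = slices[0].shape
    for p, s in zip(paths, slices):
        if s.shape != shape0:
            raise DimensionError(
                f"slice {p} has shape {s.shape}, expected {shape0}"
            )
    if voxel_size is None:
        voxel_size = _voxel_size_from_dicom(paths[0])
    if voxel_size is None:
        raise InputError("voxel_size not given and not recoverable from headers")
    data = np.stack(slices, axis=0)
    prov = f"read_stack({len(paths)} slices, {'/'.join(sorted(kinds))})"
    return CalibratedVolume(data, float(voxel_size), prov)


def _voxel_size_from_dicom(path) -> float | None:
    if not _looks_like_dicom(str(path)):
        return None
    import pydicom

    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        return None
    return float(spacing[0]) * 1000.0  # DICOM spacing is mm


def write_tiff_volume(
    volume: CalibratedVolume,
    tiff_path: str | os.PathLike,
    sidecar_path: str | os.PathLike | None = None,
) -> None:
    """Write a volume as float32 multi-page TIFF plus a YAML calibration sidecar."""
    tifffile.imwrite(str(tiff_path), volume.data.astype(np.float32))
    if sidecar_path is not None:
        sidecar = {
            "voxel_size_um": float(volume.voxel_size),
            "slope": 1.0,
            "intercept": 0.0,
        }
        with open(sidecar_path, "w") as fh:
            yaml.safe_dump(sidecar, fh)


def read_tiff_volume(
    tiff_path: str | os.PathLike, sidecar_path: str | os.PathLike
) -> CalibratedVolume:
    """Read a multi-page TIFF with its YAML sidecar (voxel_size_um, slope, intercept)."""
    with open(sidecar_path) as fh:
        sidecar = yaml.safe_load(fh)
    cal = CalibrationMap(float(sidecar["slope"]), float(sidecar.get("intercept", 0.0)))
    data = tifffile.imread(str(tiff_path))
    if data.ndim == 2:
        data = data[None]
    return CalibratedVolume(
        cal.apply(data), float(sidecar["voxel_size_um"]), f"read_tiff_volume({tiff_path})"
    )


def write_metrics(
    record: Any,
    path: str | os.PathLike,
    fields: Sequence[str] | None = None,
) -> None:
    """Serialize one or more metrics records to a flat CSV, one row per record.

    ``record`` may be a dataclass instance, a mapping, or a list of either.
    Numeric fields round-trip losslessly (written at 17 significant digits).
    If ``fields`` is given, every record must supply all of them.
    """
    records = record if isinstance(record, (list, tuple)) else [record]
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            row = dataclasses.asdict(rec)
        elif isinstance(rec, Mapping):
            row = dict(rec)
        else:
            raise SchemaError(f"unsupported metrics record type: {type(rec)!r}")
        if fields is not None:
            missing = [f for f in fields if f not in row]
            if missing:
                raise SchemaError(f"record missing fields: {missing}")
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")


def read_metrics(path: str | os.PathLike) -> pd.DataFrame:
    """Read a metrics CSV written by :func:`write_metrics`."""
    return pd.read_csv(path)
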