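"""Analysis-region definition from sparse user-drawn contours.

The study workflow outlines the trabecular network or the medial cortical
band on a handful of keyframe slices and propagates the outline across the
intervening slices.  Here that propagation is realized as per-slice linear
blending of the signed distance fields of the bracketing rasterized polygons,
thresholded at zero — the standard shape-morphing construction, which handles
smooth area and shape change between keyframes.

Rasterization counts a voxel as inside when its center is inside the polygon
(even-odd rule).  The "middle third" of a cortical band is selected by
geodesic arc-length parameterization between two anchor landmarks (the
anterior/posterior growth-plate reference points), so it reduces to exact
column thirds on a straight strip and to a 60°-of-180° wedge on a
semicircular annulus.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import DimensionError, InputError

__all__ = [
    "KeyframeContour",
    "RoiMask",
    "rasterize_polygon",
    "interpolate_contours",
    "middle_third_mask",
    "read_keyframes_json",
    "write_mask_tiff",
]


@dataclass(frozen=True)
class KeyframeContour:
    """A user-drawn closed polygon on one slice, vertices as (row, col) voxels."""

    slice_index: int
    polygon: np.ndarray  # (n, 2) float, (row, col)

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise InputError("keyframe polygon needs >= 3 (row, col) vertices")
        if not ShapelyPolygon(poly).is_valid:
            raise InputError(
                f"keyframe polygon on slice {self.slice_index} is self-intersecting"
            )
        object.__setattr__(self, "polygon", poly)


@dataclass
class RoiMask:
    """3-D boolean analysis region congruent with a CalibratedVolume."""

    mask: np.ndarray
    label: str = "trabecular"  # or "cortical_medial_third"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionError("RoiMask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(self.mask.sum())


def rasterize_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a (row, col) polygon onto a grid: voxel centers inside → True."""
    poly = np.asarray(polygon, dtype=float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    # closed=False: contains_points implicitly closes the ring; closed=True
    # would consume the final vertex as the CLOSEPOLY sentinel.
    inside = MplPath(poly, closed=False).contains_points(pts, radius=1e-9)
    return inside.reshape(shape)


def _signed_distance(mask2d: np.ndarray) -> np.ndarray:
    """Signed distance field in voxels: negative inside, positive outside."""
    if not mask2d.any():
        # Entirely outside; large positive everywhere.
        return np.full(mask2d.shape, np.hypot(*mask2d.shape), dtype=float)
    outside = ndimage.distance_transform_edt(~mask2d)
    inside = ndimage.distance_transform_edt(mask2d)
    return outside - inside


def interpolate_contours(
    keyframes: Sequence[KeyframeContour],
    shape: tuple[int, int, int],
    label: str = "trabecular",
) -> RoiMask:
    """Propagate keyframe contours across intervening slices.

    Parameters
    ----------
    keyframes
        At least two contours with strictly increasing ``slice_index``.
    shape
        Full mask shape ``(n_slices, n_rows, n_cols)``.

    At a keyframe slice the mask is exactly the rasterized polygon; between
    bracketing keyframes the region is the zero sublevel set of the linearly
    blended signed distance fields; slices outside the keyframe span are empty.
    """
    if len(keyframes) < 2:
        raise InputError("contour interpolation requires >= 2 keyframes")
    idx = [k.slice_index for k in keyframes]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise InputError("keyframe slice indices must be strictly increasing")
    n_slices = shape[0]
    if idx[0] < 0 or idx[-1] >= n_slices:
        raise InputError(
            f"keyframe slice indices {idx[0]}..{idx[-1]} out of range 0..{n_slices - 1}"
        )
    plane = (shape[1], shape[2])
    mask = np.zeros(shape, dtype=bool)
    rasters = [rasterize_polygon(k.polygon, plane) for k in keyframes]
    for k, rast in zip(keyframes, rasters):
        mask[k.slice_index] = rast
    for (i0, r0), (i1, r1) in zip(
        zip(idx, rasters), zip(idx[1:], rasters[1:])
    ):
        if i1 - i0 < 2:
            continue
        sdf0 = _signed_distance(r0)
        sdf1 = _signed_distance(r1)
        for s in range(i0 + 1, i1):
            t = (s - i0) / (i1 - i0)
            mask[s] = (1.0 - t) * sdf0 + t * sdf1 < 0.0
    return RoiMask(mask, label=label)


def _geodesic_distance(mask2d: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """Geodesic distance (voxels) from ``seed`` within ``mask2d``; inf outside/unreached."""
    from skimage.graph import MCP_Geometric

    costs = np.where(mask2d, 1.0, np.inf)
    mcp = MCP_Geometric(costs)
    dist, _ = mcp.find_costs([seed])
    return dist


def _snap_to_mask(mask2d: np.ndarray, point: tuple[float, float]) -> tuple[int, int]:
    coords = np.argwhere(mask2d)
    d2 = ((coords - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    r, c = coords[int(np.argmin(d2))]
    return int(r), int(c)


def middle_third_mask(
    cortex_mask: RoiMask | np.ndarray,
    landmarks: Sequence[tuple[float, float]] | Sequence[Sequence[tuple[float, float]]],
    keep: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> RoiMask:
    """Retain the middle third of a cortical band between two anchor landmarks.

    Arc-length parameterization: the band's medial axis is extracted, each
    skeleton pixel gets a normalized position ``t = d1 / (d1 + d2)`` from its
    geodesic distances to the two anchors (measured along the skeleton), and
    every cortex voxel inherits the ``t`` of its nearest skeleton pixel.
    Voxels with ``keep[0] <= t <= keep[1]`` are retained.  On a straight
    strip this reduces to exact column thirds; on an annulus, to angular
    thirds.  (A point-to-point geodesic parameterization of the voxels
    themselves would be biased toward the band middle, because both
    distances share the voxel's radial offset from the medial line.)

    ``landmarks`` is either one ``((r1, c1), (r2, c2))`` pair applied to every
    slice or a per-slice sequence of such pairs.
    """
    mask3d = cortex_mask.mask if isinstance(cortex_mask, RoiMask) else np.asarray(
        cortex_mask, dtype=bool
    )
    if mask3d.ndim != 3:
        raise DimensionError("cortex mask must be 3-D")
    n_slices = mask3d.shape[0]
    per_slice = _normalize_landmarks(landmarks, n_slices)
    out = np.zeros_like(mask3d)
    for s in range(n_slices):
        band = mask3d[s]
        if not band.any():
            continue
        a1, a2 = per_slice[s]
        if tuple(a1) == tuple(a2):
            raise InputError("anchor landmarks are coincident")
        _check_in_bounds(a1, band.shape)
        _check_in_bounds(a2, band.shape)
        from skimage.morphology import medial_axis

        skel = medial_axis(band)
        if not skel.any():
            continue
        p1 = _snap_to_mask(skel, a1)
        p2 = _snap_to_mask(skel, a2)
        if p1 == p2:
            raise InputError("anchor landmarks snap to the same medial-axis pixel")
        d1 = _geodesic_distance(skel, p1)
        d2 = _geodesic_distance(skel, p2)
        total = d1 + d2
        with np.errstate(invalid="ignore"):
            t_skel = np.where(np.isfinite(total) & (total > 0), d1 / total, np.nan)
        # every band voxel inherits its nearest skeleton pixel's position
        _, (ir, ic) = ndimage.distance_transform_edt(~skel, return_indices=True)
        t = t_skel[ir, ic]
        with np.errstate(invalid="ignore"):
            out[s] = band & (t >= keep[0]) & (t <= keep[1])
    return RoiMask(out, label="cortical_medial_third")


def _normalize_landmarks(landmarks, n_slices):
    arr = np.asarray(landmarks, dtype=float)
    if arr.shape == (2, 2):
        return [(tuple(arr[0]), tuple(arr[1]))] * n_slices
    if arr.shape == (n_slices, 2, 2):
        return [(tuple(a), tuple(b)) for a, b in arr]
    raise InputError(
        "landmarks must be one (2, 2) anchor pair or an (n_slices, 2, 2) array"
    )


def _check_in_bounds(point, shape2d):
    r, c = point
    if not (0 <= r < shape2d[0] and 0 <= c < shape2d[1]):
        raise InputError(f"anchor {point} outside slice bounds {shape2d}")


def read_keyframes_json(path: str | os.PathLike) -> list[KeyframeContour]:
    """Read keyframes from JSON: ``[{"slice": int, "polygon": [[r, c], ...]}, ...]``."""
    with open(path) as fh:
        items = json.load(fh)
    return [
        KeyframeContour(int(it["slice"]), np.asarray(it["polygon"], dtype=float))
        for it in items
    ]


def write_mask_tiff(mask: RoiMask | np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as an 8-bit (0/255) multi-page TIFF."""
    import tifffile

    arr = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    tifffile.imwrite(str(path), (arr.astype(np.uint8) * 255))
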