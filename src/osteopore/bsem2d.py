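"""2-D section measurements in the style of backscatter electron imaging.

Backscatter grey level tracks mineral content, so pores (lacunae, vascular
canals, canaliculi) appear dark against bone.  This module quantifies
polished-section images: percent area of lacunar and vascular pores,
moment-ellipse axes of individual lacunae, cortical band thickness, and
sub-pixel canalicular diameter from a line profile.

Because only 3-D volume bounds exist for pore classes, the 2-D lacuna /
vascular discrimination uses a component-area split (default 80 µm², the
area of a mid-range lacuna section), exposed as configuration.  The
greyscale threshold is a required input — thresholding was manual in the
originating workflow and no automatic method is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import medial_axis

from .errors import InputError

__all__ = [
    "SectionImage",
    "LacunaMeasure2D",
    "PoreArea2D",
    "percent_pore_area",
    "lacuna_axes",
    "cortical_thickness_2d",
    "canalicular_diameter",
    "read_section_image",
]

#: Default (min_pore_area_um2, lacuna_vascular_split_um2).
DEFAULT_CLASS_BOUNDS = (4.0, 80.0)


@dataclass
class SectionImage:
    """2-D greyscale section with physical pixel size (µm/pixel)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InputError("SectionImage must be 2-D greyscale")
        if not self.pixel_size > 0:
            raise InputError("pixel_size must be > 0")


@dataclass(frozen=True)
class LacunaMeasure2D:
    major_axis: float  # µm
    minor_axis: float  # µm
    area: float  # µm²
    eccentricity: float

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise InputError("requires major >= minor > 0")


@dataclass(frozen=True)
class PoreArea2D:
    lacunar_pct: float  # % of tissue area
    vascular_pct: float  # % of tissue area
    n_lacunae: int
    n_vascular: int


def percent_pore_area(
    image: SectionImage,
    threshold: float,
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
    tissue_mask: np.ndarray | None = None,
) -> PoreArea2D:
    """Percent area of lacunar and vascular pores in a thresholded section.

    Below-threshold pixels (grey < threshold) are grouped by 8-connectivity
    and partitioned by component area: below ``class_bounds[0]`` µm² → noise
    (dropped), up to ``class_bounds[1]`` µm² → lacunae, above → vascular
    pores.  Percentages are of the total tissue area (the ``tissue_mask``
    pixel area, or the whole image when no mask is given).
    """
    ps2 = image.pixel_size**2
    if tissue_mask is None:
        tissue_area = image.pixels.size * ps2
    else:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
        if tissue_mask.shape != image.pixels.shape:
            raise InputError("tissue_mask shape does not match image")
        tissue_area = tissue_mask.sum() * ps2
    if tissue_area == 0:
        raise InputError("tissue area is zero")
    dark = image.pixels < threshold
    if tissue_mask is not None:
        dark &= tissue_mask
    labels, n = ndimage.label(dark, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return PoreArea2D(0.0, 0.0, 0, 0)
    areas = np.bincount(labels.ravel())[1:] * ps2
    min_area, split = class_bounds
    lacunar = (areas >= min_area) & (areas <= split)
    vascular = areas > split
    return PoreArea2D(
        lacunar_pct=100.0 * areas[lacunar].sum() / tissue_area,
        vascular_pct=100.0 * areas[vascular].sum() / tissue_area,
        n_lacunae=int(lacunar.sum()),
        n_vascular=int(vascular.sum()),
    )


def lacuna_axes(component_mask: np.ndarray, pixel_size: float) -> LacunaMeasure2D:
    """Moment-ellipse major/minor axes of a single lacuna section, in µm.

    Axes are those of the ellipse with identical second central moments as
    the pixel component.
    """
    mask = np.asarray(component_mask, dtype=bool)
    if mask.sum() < 5:
        raise InputError("lacuna component must have >= 5 pixels")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n != 1:
        raise InputError(f"expected a single connected component, found {n}")
    props = measure.regionprops(labels)[0]
    return LacunaMeasure2D(
        major_axis=props.axis_major_length * pixel_size,
        minor_axis=props.axis_minor_length * pixel_size,
        area=props.area * pixel_size**2,
        eccentricity=props.eccentricity,
    )


def cortical_thickness_2d(cortex_mask: np.ndarray, pixel_size: float) -> float:
    """Mean cortical band thickness: 2× the distance-transform ridge along the
    band's medial axis, in µm."""
    mask = np.asarray(cortex_mask, dtype=bool)
    if not mask.any():
        raise InputError("cortex mask is empty")
    if not pixel_size > 0:
        raise InputError("pixel_size must be > 0")
    skel, dist = medial_axis(mask, return_distance=True)
    if not skel.any():
        raise InputError("cortex mask has no medial axis (degenerate band)")
    return float(2.0 * dist[skel].mean() * pixel_size)


def canalicular_diameter(
    profile: np.ndarray, pixel_size: float, threshold: float
) -> float:
    """Width of a single below-threshold dip in a line profile, in µm.

    The profile must cross exactly one dark band (the canaliculus); the two
    threshold crossings are located with sub-pixel linear interpolation.
    Multiply by 1000 for the conventional nm report.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size < 3:
        raise InputError("profile must be a 1-D array of >= 3 samples")
    below = p < threshold
    if not below.any():
        raise InputError("profile never crosses below the threshold")
    runs = _runs(below)
    if len(runs) != 1:
        raise InputError(f"profile must cross exactly one dark band, found {len(runs)}")
    start, stop = runs[0]  # below on [start, stop)
    if start == 0 or stop == p.size:
        raise InputError("dark band touches the profile end; no crossing to interpolate")
    left = (start - 1) + (p[start - 1] - threshold) / (p[start - 1] - p[start])
    right = stop - (p[stop] - threshold) / (p[stop] - p[stop - 1])
    return float((right - left) * pixel_size)


def _runs(mask1d: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask1d, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def read_section_image(path, pixel_size: float) -> SectionImage:
    """Read a PNG/TIFF greyscale section image from disk."""
    from skimage.io import imread

    pixels = imread(str(path), as_gray=True)
    return SectionImage(np.asarray(pixels, dtype=np.float64), pixel_size)
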