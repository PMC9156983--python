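"""End-to-end phantom pipelines: generate → filter → threshold → metrics.

These are the deterministic drivers the CLI wraps: given a
:class:`~osteopore.phantom.PhantomSpec` they run the full cortical
(microporosity + BMDD) or trabecular (morphometry) analysis and optionally
write the metric CSVs.  All randomness comes from the spec's seed, so the
written CSVs are bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

from .bmdd import BmddResult, bmdd_histogram, peel_surface
from .micropore import analyze_microporosity
from .morphometry import trabecular_metrics
from .phantom import PhantomSpec, generate_cortical_phantom, generate_trabecular_phantom
from .segment import SegmentationParams, gaussian_filter_volume, threshold_bone
from .volume_io import write_metrics

__all__ = ["run_cortical_pipeline", "run_trabecular_pipeline"]


def run_cortical_pipeline(
    spec: PhantomSpec,
    out_dir: str | os.PathLike | None = None,
    params: SegmentationParams | None = None,
    peel_layers: int = 2,
    bin_width: float = 5.0,
    include_border: bool = True,
) -> dict:
    """Cortical analysis of a generated phantom.

    Returns a dict with the phantom truth, the pore table, microporosity
    metrics and the BMDD result; writes ``micropore_metrics.csv``,
    ``pore_table.csv``, ``bmdd_metrics.csv`` and ``bmdd_histogram.csv``
    into ``out_dir`` when given.
    """
    params = params or SegmentationParams()
    volume, roi, truth = generate_cortical_phantom(spec)
    filtered = gaussian_filter_volume(volume, params.gauss_sigma, params.gauss_support)
    bone = threshold_bone(filtered, roi, params.threshold, params)
    pores, metrics = analyze_microporosity(
        bone, roi, volume.voxel_size, include_border=include_border
    )
    peeled = peel_surface(bone, peel_layers)
    bm: BmddResult | None = None
    if peeled.mask.any():
        bm = bmdd_histogram(volume, peeled, bin_width=bin_width)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics(metrics, out / "micropore_metrics.csv")
        pores.to_csv(out / "pore_table.csv", index=False, float_format="%.17g")
        if bm is not None:
            write_metrics(
                {
                    "mean_density_mgHAccm": bm.mean_density,
                    "fwhm_mgHAccm": bm.fwhm,
                    "n_voxels": bm.n_voxels,
                },
                out / "bmdd_metrics.csv",
            )
            write_metrics(
                [
                    {"bin_center_mgHAccm": c, "count": int(n)}
                    for c, n in zip(bm.bin_centers, bm.counts)
                ],
                out / "bmdd_histogram.csv",
            )
    return {
        "truth": truth,
        "pore_table": pores,
        "micropore_metrics": metrics,
        "bmdd": bm,
        "bone_mask": bone,
        "roi": roi,
        "volume": volume,
    }


def run_trabecular_pipeline(
    spec: PhantomSpec,
    out_dir: str | os.PathLike | None = None,
    params: SegmentationParams | None = None,
) -> dict:
    """Trabecular morphometry of a generated lattice phantom."""
    params = params or SegmentationParams()
    volume, roi, truth = generate_trabecular_phantom(spec)
    filtered = gaussian_filter_volume(volume, params.gauss_sigma, params.gauss_support)
    bone = threshold_bone(filtered, roi, params.threshold, params)
    metrics = trabecular_metrics(bone, roi, volume.voxel_size)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics(metrics, out / "morphometry_metrics.csv")
    return {
        "truth": truth,
        "morphometry": metrics,
        "bone_mask": bone,
        "roi": roi,
        "volume": volume,
    }
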