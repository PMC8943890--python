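"""End-to-end workflow: simulate -> phasor -> segment -> quantify -> report.

A single configuration drives both the phantom generation and the analysis,
so real image stacks can later replace simulated ones path-for-path.  The
run directory layout is fixed::

    <outdir>/
      stacks/          phantom stacks (TIFF + axis sidecars) and truth labels
      phasors/         per-stack G and S coordinate TIFFs
      segmentations/   phasor-ROI label TIFFs
      tables/          per-image records, dose summary, ROI spectra (CSV)
      figures/         phasor histogram and segmentation overlay (PNG)
      run.json         seeds, package version, config hash

Re-running with an identical configuration and seed reproduces every table
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import matplotlib
import numpy as np
import tifffile
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .io import HyperspectralStack, PipelineConfig, write_stack
from .phantom import (
    PhantomSpec,
    default_axis,
    default_templates,
    iter_dose_series,
    rois_from_templates,
)
from .phasor import (
    PhasorROI,
    phasor_histogram,
    phasor_transform,
    render_segmented_image,
    roi_mean_spectrum,
    segment_by_rois,
)
from .quant import dose_response_table, quantify_phantom

__all__ = ["run_pipeline", "config_hash", "rois_from_config"]

logger = logging.getLogger(__name__)

_SUBDIRS = ("stacks", "phasors", "segmentations", "tables", "figures")


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 of the fully-resolved configuration."""
    payload = yaml.safe_dump(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def rois_from_config(config: PipelineConfig) -> list[PhasorROI]:
    """ROIs either auto-derived from the default templates or parsed from config."""
    seg = config.segmentation
    if seg.auto_rois:
        return rois_from_templates(default_templates(), default_axis(),
                                   half_width=seg.roi_half_width,
                                   harmonic=config.phasor.harmonic)
    rois = []
    for entry in seg.rois:
        rois.append(PhasorROI(
            label=entry["label"],
            rect=tuple(entry["rect"]) if "rect" in entry else None,
            polygon=[tuple(v) for v in entry["polygon"]]
            if "polygon" in entry else None,
            color=entry.get("color", "gray"),
        ))
    return rois


def _prepare_outdir(outdir: Path, force: bool) -> None:
    if outdir.exists() and any(outdir.iterdir()):
        if not force:
            raise FileExistsError(
                f"run directory {outdir} is not empty; pass force=True to overwrite"
            )
    for sub in _SUBDIRS:
        (outdir / sub).mkdir(parents=True, exist_ok=True)


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 force: bool = False) -> Path:
    """Execute the full dose-series workflow into ``outdir``; returns the path."""
    config.validate()
    outdir = Path(outdir)
    rois = rois_from_config(config)
    roi_labels = [roi.label for roi in rois]
    droplet_label = config.quantification.droplet_label
    if droplet_label not in roi_labels:
        raise ValueError(
            f"quantification droplet label {droplet_label!r} not among "
            f"ROI labels {roi_labels}"
        )
    _prepare_outdir(outdir, force)

    axis = default_axis()
    gen = config.generator
    base_spec = PhantomSpec(
        image_size=tuple(gen.image_size),
        n_cells=gen.n_cells,
        droplet_density=gen.droplet_density,
        droplet_radius_range=tuple(gen.droplet_radius_range),
        snr=gen.snr,
        seed=config.seed,
    )
    doses = list(config.quantification.doses)
    curve = dict(config.quantification.doses)
    n_replicates = config.quantification.n_replicates

    records = []
    manifest = []
    first_artifacts_saved = False
    for dose, replicate, stack, truth in iter_dose_series(
            base_spec, doses, curve, n_replicates, config.seed, axis):
        tag = f"{dose}_rep{replicate}"
        logger.info("processing %s", tag)
        stack32 = HyperspectralStack(stack.intensities.astype(np.float32),
                                     stack.axis, stack.pixel_size)
        write_stack(stack32, outdir / "stacks" / f"{tag}.tif")
        tifffile.imwrite(outdir / "stacks" / f"{tag}_truth.tif",
                         truth.label_map.values.astype(np.int32))

        phasors = phasor_transform(stack, harmonic=config.phasor.harmonic,
                                   pre_threshold=config.phasor.pre_threshold)
        tifffile.imwrite(outdir / "phasors" / f"{tag}_G.tif",
                         phasors.G.astype(np.float32))
        tifffile.imwrite(outdir / "phasors" / f"{tag}_S.tif",
                         phasors.S.astype(np.float32))

        seg = segment_by_rois(phasors, rois)
        tifffile.imwrite(outdir / "segmentations" / f"{tag}_labels.tif",
                         seg.labels.values.astype(np.int32))

        record = quantify_phantom(
            stack, seg, truth, condition=dose, replicate=replicate,
            droplet_label=droplet_label,
            min_droplet_px=config.quantification.min_droplet_px,
        )
        records.append(record)
        manifest.append({
            "condition": dose,
            "replicate": replicate,
            "stack": f"stacks/{tag}.tif",
            "truth": f"stacks/{tag}_truth.tif",
            "true_droplet_area_fraction": truth.true_droplet_area_fraction,
        })

        if not first_artifacts_saved:
            _save_figures(outdir, phasors, seg, rois)
            _save_roi_spectra(outdir, stack, seg)
            first_artifacts_saved = True

    records_frame, summary, tests = _summarise(config, records)
    records_frame.to_csv(outdir / "tables" / "records.csv", index=False)
    if summary is not None:
        summary.to_csv(outdir / "tables" / "dose_summary.csv", index=False)

    import pandas as pd

    pd.DataFrame(manifest).to_csv(outdir / "tables" / "manifest.csv", index=False)
    run_log = {
        "package": "srsphasor",
        "seed": config.seed,
        "config_sha256": config_hash(config),
        "n_images": len(records),
        "conditions": doses,
        "n_replicates": n_replicates,
        "roi_labels": roi_labels,
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return outdir


def _summarise(config: PipelineConfig, records):
    import pandas as pd

    frame = pd.DataFrame(
        {
            "condition": r.condition,
            "replicate": r.replicate,
            "percent_area": r.percent_area,
            "peak_ratio": r.peak_ratio,
            "n_cells": r.n_cells,
            "percent_cells_with_droplets": r.percent_cells_with_droplets,
            "mean_cell_intensity": r.mean_cell_intensity,
        }
        for r in records
    )
    conditions = list(dict.fromkeys(frame["condition"]))
    if len(conditions) > 1 and config.quantification.n_replicates >= 2:
        summary, tests = dose_response_table(
            records, config.quantification.control_condition)
    else:
        summary = (frame.groupby("condition", sort=False)
                   .agg(percent_area_mean=("percent_area", "mean"),
                        peak_ratio_mean=("peak_ratio", "mean"))
                   .reset_index())
        tests = {}
    return frame, summary, tests


def _save_figures(outdir: Path, phasors, seg, rois) -> None:
    counts, g_edges, s_edges = phasor_histogram(phasors, n_bins=128)
    fig, ax = plt.subplots(figsize=(5, 5))
    with np.errstate(divide="ignore"):
        ax.imshow(np.log1p(counts).T, origin="lower",
                  extent=(-1, 1, -1, 1), cmap="inferno", aspect="equal")
    for roi in rois:
        if roi.rect is not None:
            g_min, g_max, s_min, s_max = roi.rect
            ax.add_patch(plt.Rectangle((g_min, s_min), g_max - g_min,
                                       s_max - s_min, fill=False,
                                       edgecolor=roi.color, linewidth=1.2))
    ax.set_xlabel("G")
    ax.set_ylabel("S")
    fig.savefig(outdir / "figures" / "phasor_histogram.png", dpi=150)
    plt.close(fig)

    labels = [roi.label for roi in seg.roi_list]
    _, rgb = render_segmented_image(seg, labels, merge=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rgb)
    ax.set_axis_off()
    fig.savefig(outdir / "figures" / "segmentation_overlay.png", dpi=150)
    plt.close(fig)


def _save_roi_spectra(outdir: Path, stack, seg) -> None:
    import pandas as pd

    data = {"wavenumber": stack.axis.values}
    for roi in seg.roi_list:
        if not seg.mask_for(roi.label).any():
            continue
        profile = roi_mean_spectrum(stack, seg, roi.label, normalize=True)
        data[roi.label] = profile.mean_intensity
    pd.DataFrame(data).to_csv(outdir / "tables" / "roi_spectra.csv", index=False)
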