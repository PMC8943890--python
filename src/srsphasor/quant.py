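"""Lipid-droplet phenotype metrics and replicate-level dose statistics.

The phenotype readouts mirror how statin-induced droplet accumulation is
scored from segmented SRS images: the percent of total cell area occupied by
droplet-class pixels, the 3015/2965 cm^-1 marker-band height ratio of the
droplet mean spectrum (~0.75 for triacylglycerol-dominant droplets, higher
cholesterol-ester content lowers it), the fraction of cells containing
droplets, per-cell mean intensities from projections, and two-sample
pooled-variance Student's t-tests of each dose against control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label as cc_label

from .io import Image2D
from .phasor import SegmentationMap, SpectrumProfile

__all__ = [
    "QuantRecord",
    "TestResult",
    "percent_area",
    "peak_ratio",
    "percent_cells_with_droplets",
    "per_cell_mean_intensity",
    "students_t_test",
    "dose_response_table",
    "quantify_phantom",
    "cell_instances_from_mask",
]


@dataclass
class QuantRecord:
    """Per-image droplet metrics for one condition x replicate."""

    condition: str
    replicate: int
    percent_area: float
    peak_ratio: float            # NaN when no droplet pixels were found
    n_cells: int
    percent_cells_with_droplets: float
    mean_cell_intensity: float

    def __post_init__(self) -> None:
        for name in ("percent_area", "percent_cells_with_droplets"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        if not (math.isnan(self.peak_ratio) or self.peak_ratio >= 0):
            raise ValueError("peak_ratio must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic: float
    df: int
    p_value: float
    stars: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.p_value <= 0.01:
            self.stars = "**"
        elif self.p_value <= 0.05:
            self.stars = "*"
        else:
            self.stars = "ns"


def percent_area(seg: SegmentationMap, droplet_label: str,
                 cell_mask: Image2D) -> float:
    """Percent of cell area occupied by droplet-class pixels.

    ``cell_mask`` is the binary total-cell-area image, conventionally a
    threshold of the average intensity projection.
    """
    if cell_mask.meaning != "mask":
        raise ValueError("cell_mask must be a mask image")
    cells = cell_mask.values.astype(bool)
    n_cell_px = int(cells.sum())
    if n_cell_px == 0:
        raise ValueError("cell mask is empty: percent area is undefined")
    droplet = seg.mask_for(droplet_label)
    return 100.0 * int((droplet & cells).sum()) / n_cell_px


def _interpolate(profile: SpectrumProfile, wavenumber: float) -> float:
    axis = profile.wavenumbers.values
    if not axis[0] <= wavenumber <= axis[-1]:
        raise ValueError(
            f"wavenumber {wavenumber} outside axis range "
            f"[{axis[0]}, {axis[-1]}]"
        )
    return float(np.interp(wavenumber, axis, profile.mean_intensity))


def peak_ratio(profile: SpectrumProfile, num_wavenumber: float = 3015.0,
               den_wavenumber: float = 2965.0) -> float:
    """Height ratio of two marker bands, linearly interpolated on the axis.

    The ~6 cm^-1 channel spacing rarely lands on the marker positions
    exactly, so heights are read by linear interpolation between the two
    flanking channels of the (un-normalised) mean spectrum.
    """
    if profile.normalized:
        raise ValueError("peak_ratio requires an un-normalised spectrum")
    numerator = _interpolate(profile, num_wavenumber)
    denominator = _interpolate(profile, den_wavenumber)
    if denominator <= 0:
        raise ValueError(
            f"non-positive intensity at {den_wavenumber} cm^-1; ratio undefined"
        )
    return numerator / denominator


def cell_instances_from_mask(cell_mask: Image2D) -> Image2D:
    """8-connected components of the cell mask as a fallback instance map."""
    if cell_mask.meaning != "mask":
        raise ValueError("cell_mask must be a mask image")
    labelled = cc_label(cell_mask.values.astype(bool), connectivity=2)
    return Image2D(labelled.astype(np.int32), meaning="label")


def percent_cells_with_droplets(cell_instances: Image2D, seg: SegmentationMap,
                                droplet_label: str,
                                min_droplet_px: int = 4) -> float:
    """Percent of cells whose footprint holds >= ``min_droplet_px`` droplet pixels."""
    instances = cell_instances.values
    n_cells = int(instances.max(initial=0))
    if n_cells == 0:
        raise ValueError("no cells in the instance map")
    droplet = seg.mask_for(droplet_label)
    counts = np.bincount(instances[droplet], minlength=n_cells + 1)[1:]
    return 100.0 * int((counts >= min_droplet_px).sum()) / n_cells


def per_cell_mean_intensity(projection: Image2D, cell_instances: Image2D
                            ) -> list[tuple[int, float]]:
    """Mean projection intensity over each cell footprint, ordered by cell id."""
    instances = cell_instances.values
    if projection.shape != instances.shape:
        raise ValueError("projection and instance map shapes must match")
    n_cells = int(instances.max(initial=0))
    values = np.asarray(projection.values, dtype=float)
    sums = np.bincount(instances.ravel(), weights=values.ravel(),
                       minlength=n_cells + 1)
    counts = np.bincount(instances.ravel(), minlength=n_cells + 1)
    out = []
    for cell_id in range(1, n_cells + 1):
        if counts[cell_id] == 0:
            warnings.warn(f"cell {cell_id} has an empty footprint; skipped",
                          stacklevel=2)
            continue
        out.append((cell_id, float(sums[cell_id] / counts[cell_id])))
    return out


def students_t_test(group_a, group_b) -> TestResult:
    """Classic two-sample pooled-variance Student's t-test (two-tailed).

    ``t = (mean_a - mean_b) / (s_p sqrt(1/n_a + 1/n_b))`` with the pooled
    variance ``s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)``
    and ``df = n_a + n_b - 2``.  Significance stars: ``*`` for P <= 0.05,
    ``**`` for P <= 0.01, otherwise ``ns``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must be finite")
    n_a, n_b = a.size, b.size
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return TestResult(statistic=0.0, df=df, p_value=1.0)
        t = math.inf if diff > 0 else -math.inf
        return TestResult(statistic=t, df=df, p_value=0.0)
    t = diff / math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(statistic=float(t), df=df, p_value=min(p, 1.0))


def dose_response_table(records: list[QuantRecord], control_condition: str
                        ) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Condition-level summary (mean +/- sample SD) and per-dose t-tests.

    Each dose's percent-area replicates are tested against the control's with
    a pooled-variance Student's t-test; no multiple-testing correction is
    applied across doses (each dose is starred on its own).
    """
    if not records:
        raise ValueError("no records to summarise")
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
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not in records")
    counts = frame.groupby("condition")["percent_area"].count()
    if (counts < 2).any():
        lacking = sorted(counts.index[counts < 2])
        raise ValueError(f"conditions with < 2 replicates: {lacking}")

    control_pa = frame.loc[frame["condition"] == control_condition,
                           "percent_area"].to_numpy()
    rows = []
    tests: dict[str, TestResult] = {}
    for condition in conditions:
        sub = frame[frame["condition"] == condition]
        pa = sub["percent_area"].to_numpy()
        row = {
            "condition": condition,
            "n_replicates": len(sub),
            "percent_area_mean": pa.mean(),
            "percent_area_sd": pa.std(ddof=1),
            "peak_ratio_mean": sub["peak_ratio"].mean(),
            "peak_ratio_sd": sub["peak_ratio"].std(ddof=1),
            "percent_cells_with_droplets_mean":
                sub["percent_cells_with_droplets"].mean(),
            "mean_cell_intensity_mean": sub["mean_cell_intensity"].mean(),
        }
        if condition != control_condition:
            result = students_t_test(pa, control_pa)
            tests[condition] = result
            row.update(t_statistic=result.statistic, df=result.df,
                       p_value=result.p_value, stars=result.stars)
        else:
            row.update(t_statistic=np.nan, df=pd.NA, p_value=np.nan, stars="")
        rows.append(row)
    return pd.DataFrame(rows), tests


def quantify_phantom(stack, seg: SegmentationMap, truth, condition: str,
                     replicate: int, droplet_label: str = "droplet",
                     min_droplet_px: int = 4) -> QuantRecord:
    """Convenience: all per-image metrics for one segmented phantom."""
    from .phasor import roi_mean_spectrum
    from .projections import average_projection, threshold_mask

    projection = average_projection(stack)
    cell_mask = threshold_mask(projection, "otsu")
    pa = percent_area(seg, droplet_label, cell_mask)
    droplet_px = int(seg.mask_for(droplet_label).sum())
    if droplet_px:
        profile = roi_mean_spectrum(stack, seg, droplet_label, normalize=False)
        ratio = peak_ratio(profile)
        pcwd = percent_cells_with_droplets(truth.cell_instance_map, seg,
                                           droplet_label, min_droplet_px)
    else:
        ratio = math.nan
        pcwd = 0.0
    means = per_cell_mean_intensity(projection, truth.cell_instance_map)
    mean_intensity = float(np.mean([m for _, m in means])) if means else math.nan
    return QuantRecord(
        condition=condition,
        replicate=replicate,
        percent_area=pa,
        peak_ratio=ratio,
        n_cells=truth.n_cells,
        percent_cells_with_droplets=pcwd,
        mean_cell_intensity=mean_intensity,
    )
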