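"""Spectral-phasor transform, phasor-plane segmentation and ROI spectra.

The spectral phasor maps each pixel's SRS spectrum ``I_k`` (``k = 0..N-1``
channel index) to normalised discrete-Fourier coordinates at harmonic ``n``::

    G = sum_k I_k cos(2 pi n k / N) / sum_k I_k
    S = sum_k I_k sin(2 pi n k / N) / sum_k I_k

Raw intensities enter the transform unchanged (no smoothing, baseline
correction or normalisation); the division by the spectral sum makes the
coordinates invariant to overall brightness, so pixels cluster by spectral
*shape*.  With the +sin convention used here a delta spectrum concentrated in
the first channel maps to ``(1, 0)`` and any non-negative spectrum lies inside
the unit disk.  The kernel is indexed by channel, not wavenumber, which is why
the axis must be (approximately) uniformly retuned.

Pixels whose spectral sum is not positive carry no usable shape information
(noise-dominated background after detector offset removal); they are flagged
invalid, carry ``G = S = 0`` and are excluded from histograms and ROI
membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .io import HyperspectralStack, Image2D, WavenumberAxis

__all__ = [
    "PhasorField",
    "PhasorROI",
    "SegmentationMap",
    "SpectrumProfile",
    "phasor_transform",
    "phasor_kernel",
    "phasor_histogram",
    "segment_by_rois",
    "roi_mean_spectrum",
    "render_segmented_image",
]


@dataclass
class PhasorField:
    """Per-pixel (G, S) coordinates plus a validity mask."""

    G: np.ndarray
    S: np.ndarray
    valid: Image2D
    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.G.shape != self.S.shape or self.G.shape != self.valid.shape:
            raise ValueError("G, S and valid must share one 2D shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.G.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.values.sum())


@dataclass
class PhasorROI:
    """A labelled region of the phasor plane.

    Either an axis-aligned rectangle ``rect = (g_min, g_max, s_min, s_max)``
    or a simple closed polygon given as a vertex list in (G, S) coordinates.
    Containment is closed on the boundary.
    """

    label: str
    rect: tuple[float, float, float, float] | None = None
    polygon: list[tuple[float, float]] | None = None
    color: str = "gray"
    _poly_obj: "shapely.Polygon | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValueError(f"ROI {self.label!r}: give exactly one of rect/polygon")
        if self.rect is not None:
            g_min, g_max, s_min, s_max = self.rect
            if g_min > g_max or s_min > s_max:
                raise ValueError(f"ROI {self.label!r}: rectangle bounds out of order")
        else:
            if len(self.polygon) < 3:
                raise ValueError(f"ROI {self.label!r}: polygon needs >= 3 vertices")
            poly = shapely.Polygon(self.polygon)
            if not poly.is_valid:
                raise ValueError(f"ROI {self.label!r}: polygon must be simple")
            self._poly_obj = poly

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Vectorised closed-boundary membership test."""
        g = np.asarray(g, dtype=float)
        s = np.asarray(s, dtype=float)
        if self.rect is not None:
            g_min, g_max, s_min, s_max = self.rect
            return (g >= g_min) & (g <= g_max) & (s >= s_min) & (s <= s_max)
        # intersects == covers for points; includes the boundary
        return shapely.intersects_xy(self._poly_obj, g, s)


@dataclass
class SegmentationMap:
    """Pixel labels where value ``i >= 1`` indexes ``roi_list[i-1]``; 0 = unassigned."""

    labels: Image2D
    roi_list: list[PhasorROI]

    def __post_init__(self) -> None:
        if self.labels.meaning != "label":
            raise ValueError("SegmentationMap.labels must be a label image")
        if int(self.labels.values.max(initial=0)) > len(self.roi_list):
            raise ValueError("label image refers past the end of roi_list")

    def label_index(self, label: str) -> int:
        for i, roi in enumerate(self.roi_list, start=1):
            if roi.label == label:
                return i
        raise KeyError(f"no ROI named {label!r}")

    def mask_for(self, label: str) -> np.ndarray:
        return self.labels.values == self.label_index(label)


@dataclass
class SpectrumProfile:
    """Mean spectrum of a pixel class, optionally min-max normalised to [0, 1]."""

    wavenumbers: WavenumberAxis
    mean_intensity: np.ndarray
    n_pixels: int
    normalized: bool = False
    label: str = ""


def phasor_kernel(n_channels: int, harmonic: int) -> tuple[np.ndarray, np.ndarray]:
    """Cosine/sine kernels over the channel index ``k = 0..N-1``."""
    if harmonic >= n_channels:
        raise ValueError(
            f"harmonic {harmonic} must be < number of channels {n_channels}"
        )
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    phase = 2.0 * np.pi * harmonic * np.arange(n_channels) / n_channels
    return np.cos(phase), np.sin(phase)


def phasor_transform(stack: HyperspectralStack, harmonic: int = 1,
                     pre_threshold: float | None = None) -> PhasorField:
    """Transform every pixel spectrum to first-harmonic phasor coordinates.

    ``pre_threshold`` optionally invalidates pixels whose spectral *sum* is at
    or below the given value (default: only non-positive sums are invalid).
    """
    data = stack.intensities
    n_channels = data.shape[2]
    if n_channels < 2:
        raise ValueError("phasor transform needs at least 2 channels")
    cos_k, sin_k = phasor_kernel(n_channels, harmonic)
    total = data.sum(axis=2)
    threshold = 0.0 if pre_threshold is None else max(0.0, float(pre_threshold))
    valid = total > threshold
    if not valid.any():
        warnings.warn("no valid pixels: all spectral sums are non-positive",
                      stacklevel=2)
    g_num = data @ cos_k
    s_num = data @ sin_k
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(valid, g_num / total, 0.0)
        s = np.where(valid, s_num / total, 0.0)
    return PhasorField(
        G=g, S=s,
        valid=Image2D(valid.astype(np.uint8), meaning="mask"),
        harmonic=harmonic,
    )


def phasor_histogram(phasors: PhasorField, n_bins: int = 128
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D count histogram of valid phasors on the [-1, 1] x [-1, 1] grid.

    Bins are half-open with the final bin right-closed; coordinates outside
    the grid (possible only for noise-driven spectra) are counted in the edge
    bins so that the histogram total equals the number of valid pixels.

    Returns ``(counts, g_edges, s_edges)`` with ``counts[i, j]`` the number of
    phasors in G-bin ``i`` and S-bin ``j``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = phasors.valid.values.astype(bool)
    g = np.clip(phasors.G[mask], -1.0, 1.0)
    s = np.clip(phasors.S[mask], -1.0, 1.0)
    counts, g_edges, s_edges = np.histogram2d(
        g, s, bins=n_bins, range=[[-1.0, 1.0], [-1.0, 1.0]]
    )
    return counts, g_edges, s_edges


def segment_by_rois(phasors: PhasorField, rois: list[PhasorROI]) -> SegmentationMap:
    """Assign each valid pixel to the first listed ROI containing its phasor.

    Overlapping ROIs are resolved by list order (first wins); pixels in no ROI
    and invalid pixels get label 0.
    """
    if not rois:
        raise ValueError("ROI list must not be empty")
    labels = np.zeros(phasors.shape, dtype=np.int32)
    unassigned = phasors.valid.values.astype(bool)
    for index, roi in enumerate(rois, start=1):
        hit = unassigned & roi.contains(phasors.G, phasors.S)
        labels[hit] = index
        unassigned &= ~hit
        if not unassigned.any():
            break
    return SegmentationMap(labels=Image2D(labels, meaning="label"),
                           roi_list=list(rois))


def roi_mean_spectrum(stack: HyperspectralStack, seg: SegmentationMap,
                      label: str, normalize: bool = False) -> SpectrumProfile:
    """Mean spectrum over the pixels of one segmentation class.

    With ``normalize=True`` the mean spectrum is affinely rescaled so its
    minimum is 0 and its maximum is 1 (a constant spectrum maps to all zeros).
    """
    member = seg.mask_for(label)
    n_pixels = int(member.sum())
    if n_pixels == 0:
        raise ValueError(f"segmentation class {label!r} has no member pixels")
    mean = stack.intensities[member].mean(axis=0)
    if normalize:
        low, high = mean.min(), mean.max()
        mean = np.zeros_like(mean) if high == low else (mean - low) / (high - low)
    return SpectrumProfile(wavenumbers=stack.axis, mean_intensity=mean,
                           n_pixels=n_pixels, normalized=normalize, label=label)


# fixed display palette for overlays (matplotlib color names)
_DEFAULT_OVERLAY = {
    "background": (0.15, 0.15, 0.15),
    "cytoplasm": (0.55, 0.35, 0.75),
    "nucleus": (0.20, 0.45, 0.85),
    "nucleolus": (0.35, 0.80, 0.90),
    "cell_periphery": (0.85, 0.30, 0.30),
    "droplet_periphery": (0.20, 0.75, 0.30),
    "droplet": (0.95, 0.85, 0.10),
}


def render_segmented_image(seg: SegmentationMap, labels_to_show: list[str],
                           merge: bool = False
                           ) -> tuple[Image2D, np.ndarray]:
    """Binary/merged class image plus an RGB overlay.

    Without ``merge`` a single label is rendered as its binary mask; with
    ``merge`` the listed classes are painted in list order into one label
    image.  Returns ``(label_image, rgb)`` where ``rgb`` is float in [0, 1].
    """
    if not labels_to_show:
        raise ValueError("labels_to_show must not be empty")
    if not merge and len(labels_to_show) != 1:
        raise ValueError("without merge, render exactly one label")
    indices = [seg.label_index(name) for name in labels_to_show]  # validates
    out = np.zeros(seg.labels.shape, dtype=np.int32)
    rgb = np.zeros((*seg.labels.shape, 3), dtype=float)
    for shown, (name, index) in enumerate(zip(labels_to_show, indices), start=1):
        mask = seg.labels.values == index
        out[mask] = shown if merge else 1
        color = _DEFAULT_OVERLAY.get(name, (0.8, 0.8, 0.8))
        rgb[mask] = color
    return Image2D(out, meaning="label"), rgb
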