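"""Intensity projections, threshold masks and ratiometric CH2/CH3 images."""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .io import HyperspectralStack, Image2D, ZStack

__all__ = ["max_projection", "average_projection", "threshold_mask", "ratio_image"]


def _stacking_axis(stack: HyperspectralStack | ZStack) -> tuple[np.ndarray, int]:
    if isinstance(stack, HyperspectralStack):
        return stack.intensities, 2
    if isinstance(stack, ZStack):
        return stack.intensities, 0
    raise TypeError("expected a HyperspectralStack or ZStack")


def max_projection(stack: ZStack | HyperspectralStack) -> Image2D:
    """Per-pixel maximum along the stacking axis (no interpolation)."""
    data, axis = _stacking_axis(stack)
    return Image2D(data.max(axis=axis), meaning="intensity")


def average_projection(stack: HyperspectralStack | ZStack) -> Image2D:
    """Per-pixel arithmetic mean along the stacking axis."""
    data, axis = _stacking_axis(stack)
    return Image2D(data.mean(axis=axis), meaning="intensity")


def threshold_mask(image: Image2D, threshold: float | str = "otsu") -> Image2D:
    """Binary mask: 1 where ``image > threshold``.

    ``threshold="otsu"`` picks the threshold by Otsu's between-class-variance
    maximisation on a 256-bin histogram; a constant image has no histogram
    structure to split and raises, so callers must then supply a number.
    """
    values = np.asarray(image.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("threshold_mask requires a finite image")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown automatic threshold {threshold!r}")
        if np.ptp(values) == 0:
            raise ValueError(
                "cannot apply Otsu thresholding to a constant image; "
                "supply a numeric threshold"
            )
        threshold = threshold_otsu(values, nbins=256)
    return Image2D((values > float(threshold)).astype(np.uint8), meaning="mask")


def ratio_image(numerator: Image2D, denominator: Image2D, mask: Image2D,
                display_max: float = 0.8) -> Image2D:
    """Masked pixelwise ratio ``(numerator / denominator) * mask``.

    Pixels with a non-positive denominator map to 0 regardless of the mask
    (background semantics, keeps downstream area math well defined).  Values
    are NOT clipped; ``display_max`` (default 0.8, the conventional display
    ceiling for CH2/CH3 ratio images) is carried as rendering metadata only.
    """
    if numerator.shape != denominator.shape or numerator.shape != mask.shape:
        raise ValueError("numerator, denominator and mask shapes must match")
    if mask.meaning != "mask":
        raise ValueError("mask must be a mask image")
    num = np.asarray(numerator.values, dtype=float)
    den = np.asarray(denominator.values, dtype=float)
    ok = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    ratio *= mask.values
    ratio[~ok] = 0.0
    return Image2D(ratio, meaning="ratio", display_range=(0.0, float(display_max)))
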