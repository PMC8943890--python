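"""Seeded hyperspectral phantoms of breast-cancer-like cell fields.

The generator emulates the kind of data the analysis is built for: fields of
view containing ellipsoidal cells with nucleus, nucleoli, cytoplasm, a thin
cell rim, and cytoplasmic lipid droplets with a mixing rim, each compartment
carrying a distinct CH-stretch spectrum over 2800-3050 cm^-1.  Compartment
spectra are sums of broad Gaussian bands at the canonical positions: 2851
(CH2 symmetric), 2880 (CH2 asymmetric), 2930 (CH3 symmetric), 2965 (CH3
asymmetric / cholesterol-ester marker), and 3010-3015 (=CH, unsaturated
lipid), on top of a flat pedestal representing the aqueous/non-resonant
background.  The droplet template is calibrated so that its evaluated
3015/2965 cm^-1 height ratio equals 0.75, the literature value for
triacylglycerol-dominant droplets.

Detector noise is zero-mean additive Gaussian; ``snr`` is defined as the
maximum of the droplet template on the axis divided by the noise standard
deviation.  Noisy spectra may go negative, as real lock-in SRS data do, and
downstream code must tolerate that.

Compartment label codes are fixed: 0 background, 1 cytoplasm, 2 nucleus,
3 nucleolus, 4 cell periphery, 5 droplet periphery, 6 droplet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .io import HyperspectralStack, Image2D, WavenumberAxis, ZStack
from .phasor import PhasorROI, phasor_kernel

__all__ = [
    "Peak",
    "SpectralTemplate",
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "LABELS",
    "LABEL_NAMES",
    "default_axis",
    "default_templates",
    "mix_templates",
    "generate_phantom",
    "generate_dose_series",
    "iter_dose_series",
    "generate_zstack",
    "template_phasors",
    "rois_from_templates",
    "derive_seed",
]


LABELS: dict[str, int] = {
    "background": 0,
    "cytoplasm": 1,
    "nucleus": 2,
    "nucleolus": 3,
    "cell_periphery": 4,
    "droplet_periphery": 5,
    "droplet": 6,
}
LABEL_NAMES: tuple[str, ...] = tuple(
    sorted(LABELS, key=LABELS.__getitem__)
)


class PlacementError(RuntimeError):
    """Requested geometry cannot be placed within the bounded retry budget."""


# --------------------------------------------------------------------------
# spectral templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    center: float      # cm^-1
    amplitude: float
    width: float       # Gaussian sigma / Lorentzian HWHM, cm^-1
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("peak shape must be 'gaussian' or 'lorentzian'")

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        delta = np.asarray(wavenumbers, dtype=float) - self.center
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * (delta / self.width) ** 2)
        return self.amplitude / (1.0 + (delta / self.width) ** 2)


@dataclass(frozen=True)
class SpectralTemplate:
    """Non-negative compartment spectrum: peaks plus a constant pedestal."""

    peaks: tuple[Peak, ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def evaluate(self, wavenumbers) -> np.ndarray:
        wavenumbers = np.asarray(wavenumbers, dtype=float)
        out = np.full(wavenumbers.shape, self.baseline, dtype=float)
        for peak in self.peaks:
            out += peak.evaluate(wavenumbers)
        return out


def mix_templates(a: SpectralTemplate, b: SpectralTemplate,
                  weight_a: float = 0.5) -> SpectralTemplate:
    """Linear mixture of two templates (peak-wise, amplitudes scaled)."""
    if not 0.0 <= weight_a <= 1.0:
        raise ValueError("weight_a must lie in [0, 1]")
    weight_b = 1.0 - weight_a
    peaks = tuple(
        replace(p, amplitude=p.amplitude * weight_a) for p in a.peaks
    ) + tuple(
        replace(p, amplitude=p.amplitude * weight_b) for p in b.peaks
    )
    return SpectralTemplate(peaks=peaks,
                            baseline=weight_a * a.baseline + weight_b * b.baseline)


# TAG marker-band positions and target height ratio for droplet calibration
_TAG_NUM_WN = 3015.0
_TAG_DEN_WN = 2965.0
_TAG_RATIO = 0.75

_BAND_SIGMA = 18.0  # cm^-1; condensed-phase CH-stretch bands are broad


def _band(center: float, amplitude: float) -> Peak:
    return Peak(center=center, amplitude=amplitude, width=_BAND_SIGMA)


def default_templates() -> dict[str, SpectralTemplate]:
    """Default compartment spectra (arbitrary intensity units).

    Amplitudes are free parameters of the phantom; they are chosen so that
    (i) compartment phasor clusters on the default 40-channel axis are
    mutually separated by more than twice the default ROI half-width,
    (ii) every cellular compartment is brighter on average than the
    background pedestal so a global threshold recovers the cell footprint,
    and (iii) the droplet 3015/2965 height ratio is exactly 0.75.
    """
    cytoplasm = SpectralTemplate(
        peaks=(_band(2851, 0.50), _band(2880, 0.65), _band(2930, 1.00),
               _band(2965, 0.50), _band(3010, 0.25)),
        baseline=0.40,
    )
    nucleus = SpectralTemplate(
        peaks=(_band(2851, 0.18), _band(2880, 0.33), _band(2930, 1.00),
               _band(2965, 0.55), _band(3010, 0.28)),
        baseline=0.40,
    )
    nucleolus = SpectralTemplate(
        peaks=(_band(2851, 0.30), _band(2880, 0.55), _band(2930, 1.60),
               _band(2965, 0.80), _band(3010, 0.38)),
        baseline=0.22,
    )
    background = SpectralTemplate(peaks=(), baseline=0.72)

    # droplet: strong CH2 bands, moderate CH3, plus the =CH band whose
    # amplitude is solved so evaluate(3015)/evaluate(2965) == _TAG_RATIO
    droplet_base = SpectralTemplate(
        peaks=(_band(2851, 0.95), _band(2880, 0.70), _band(2930, 0.50),
               _band(2965, 0.42)),
        baseline=0.32,
    )
    v_den = float(droplet_base.evaluate(_TAG_DEN_WN))
    v_num = float(droplet_base.evaluate(_TAG_NUM_WN))
    unit = Peak(center=_TAG_NUM_WN, amplitude=1.0, width=_BAND_SIGMA)
    k_num = float(unit.evaluate(np.array(_TAG_NUM_WN)))
    k_den = float(unit.evaluate(np.array(_TAG_DEN_WN)))
    amp_3015 = (_TAG_RATIO * v_den - v_num) / (k_num - _TAG_RATIO * k_den)
    if amp_3015 < 0:
        raise ValueError("droplet template cannot reach the target TAG ratio")
    droplet = SpectralTemplate(
        peaks=droplet_base.peaks + (_band(_TAG_NUM_WN, amp_3015),),
        baseline=droplet_base.baseline,
    )

    templates = {
        "background": background,
        "cytoplasm": cytoplasm,
        "nucleus": nucleus,
        "nucleolus": nucleolus,
        "cell_periphery": mix_templates(cytoplasm, background, 0.5),
        "droplet_periphery": mix_templates(droplet, cytoplasm, 0.5),
        "droplet": droplet,
    }
    return templates


def default_axis(n_channels: int = 40, low: float = 2800.0,
                 high: float = 3050.0) -> WavenumberAxis:
    """Uniform wavenumber axis spanning the CH-stretch window (~6 cm^-1 steps)."""
    return WavenumberAxis(np.linspace(low, high, n_channels))


# --------------------------------------------------------------------------
# phantom specification and ground truth
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    image_size: tuple[int, int] = (256, 256)
    n_cells: int = 12
    droplet_density: float = 2.0           # expected droplets per cell (Poisson)
    droplet_radius_range: tuple[float, float] = (2.0, 4.0)  # px
    templates: Mapping[str, SpectralTemplate] | None = None
    snr: float = 20.0                      # droplet peak / noise std; inf = noiseless
    seed: int = 0
    cell_axis_range: tuple[float, float] = (18.0, 26.0)  # ellipse semi-axes, px
    nucleus_scale: float = 0.50            # nucleus semi-axes / cell semi-axes
    cell_rim_px: float = 2.0               # cell-periphery annulus width
    droplet_rim_px: float = 1.0            # droplet-periphery annulus width
    max_place_tries: int = 400

    def __post_init__(self) -> None:
        if self.droplet_density < 0:
            raise ValueError("droplet_density must be >= 0")
        if not self.snr > 0:
            raise ValueError("snr must be positive (inf for noiseless)")
        lo, hi = self.droplet_radius_range
        if not 0 < lo <= hi:
            raise ValueError("droplet_radius_range must satisfy 0 < lo <= hi")

    def resolved_templates(self) -> dict[str, SpectralTemplate]:
        templates = dict(self.templates) if self.templates else default_templates()
        missing = set(LABELS) - set(templates)
        if missing:
            raise ValueError(f"templates missing compartments: {sorted(missing)}")
        return templates


@dataclass
class GroundTruth:
    label_map: Image2D                 # compartment codes (LABELS)
    cell_instance_map: Image2D         # 0 = background, 1..n_cells
    droplet_instance_map: Image2D      # 0 = none, 1..n_droplets
    true_droplet_area_fraction: float  # droplet px / cell px (0 when no cells)

    @property
    def n_cells(self) -> int:
        return int(self.cell_instance_map.values.max(initial=0))

    @property
    def n_droplets(self) -> int:
        return int(self.droplet_instance_map.values.max(initial=0))


# --------------------------------------------------------------------------
# geometry rendering
# --------------------------------------------------------------------------

def _ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                  semi_axes: tuple[float, float], theta: float) -> np.ndarray:
    rr, cc = np.ogrid[:rows, :cols]
    dr = rr - center[0]
    dc = cc - center[1]
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    u = dr * cos_t + dc * sin_t
    v = -dr * sin_t + dc * cos_t
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disc_indices(rows: int, cols: int, center: tuple[float, float],
                  radius: float) -> tuple[np.ndarray, np.ndarray]:
    r0, c0 = center
    r_lo = max(0, int(math.floor(r0 - radius)))
    r_hi = min(rows, int(math.ceil(r0 + radius)) + 1)
    c_lo = max(0, int(math.floor(c0 - radius)))
    c_hi = min(cols, int(math.ceil(c0 + radius)) + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    return rr[inside], cc[inside]


def _render_geometry(spec: PhantomSpec, rng: np.random.Generator
                     ) -> tuple[GroundTruth, np.ndarray]:
    """Rasterise cells, nuclei, nucleoli and droplets.

    Returns the ground truth plus a per-pixel droplet-periphery owner map
    (0 = none) used by the Z-stack renderer.
    """
    rows, cols = spec.image_size
    labels = np.zeros((rows, cols), dtype=np.int32)
    cell_instances = np.zeros_like(labels)
    droplet_instances = np.zeros_like(labels)
    periphery_owner = np.zeros_like(labels)

    a_lo, a_hi = spec.cell_axis_range
    margin = a_hi + 1.0

    # --- cells: non-overlapping rotated ellipses fully inside the frame
    cell_masks: list[np.ndarray] = []
    occupied = np.zeros((rows, cols), dtype=bool)
    for cell_id in range(1, spec.n_cells + 1):
        placed = False
        for _ in range(spec.max_place_tries):
            a = rng.uniform(a_lo, a_hi)
            b = rng.uniform(a_lo, a_hi)
            theta = rng.uniform(0.0, math.pi)
            if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
                raise PlacementError("image too small for the requested cell size")
            center = (rng.uniform(margin, rows - margin),
                      rng.uniform(margin, cols - margin))
            mask = _ellipse_mask(rows, cols, center, (a, b), theta)
            if not (mask & occupied).any():
                interior = _ellipse_mask(
                    rows, cols, center,
                    (max(a - spec.cell_rim_px, 1.0), max(b - spec.cell_rim_px, 1.0)),
                    theta,
                )
                labels[mask] = LABELS["cell_periphery"]
                labels[interior] = LABELS["cytoplasm"]
                cell_instances[mask] = cell_id
                occupied |= mask
                cell_masks.append(mask)

                # nucleus: scaled co-oriented ellipse with a small offset
                na = a * spec.nucleus_scale * rng.uniform(0.9, 1.1)
                nb = b * spec.nucleus_scale * rng.uniform(0.9, 1.1)
                jitter = 0.12 * min(a, b)
                n_center = (center[0] + rng.uniform(-jitter, jitter),
                            center[1] + rng.uniform(-jitter, jitter))
                nucleus = _ellipse_mask(rows, cols, n_center, (na, nb), theta)
                nucleus &= interior
                labels[nucleus] = LABELS["nucleus"]

                # 1-2 nucleoli: small discs inside the nucleus
                nucleus_px = np.argwhere(nucleus)
                if nucleus_px.size:
                    for _ in range(int(rng.integers(1, 3))):
                        for _ in range(spec.max_place_tries):
                            pick = nucleus_px[rng.integers(len(nucleus_px))]
                            radius = rng.uniform(1.8, 3.0)
                            ir, ic = _disc_indices(rows, cols, tuple(pick), radius)
                            if np.all(nucleus[ir, ic]):
                                labels[ir, ic] = LABELS["nucleolus"]
                                break
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {cell_id} after {spec.max_place_tries} tries"
            )

    # --- droplets: Poisson count per cell, uniform in the cytoplasm.
    # Droplets may overlap one another (coalescing droplets are common) but
    # are rejected against nuclei, nucleoli, cell rims and background.
    droplet_id = 0
    for cell_id, mask in enumerate(cell_masks, start=1):
        count = int(rng.poisson(spec.droplet_density))
        cyto_px = np.argwhere(mask & (labels == LABELS["cytoplasm"]))
        for _ in range(count):
            if len(cyto_px) == 0:
                raise PlacementError(f"cell {cell_id} has no cytoplasm for droplets")
            success = False
            for _ in range(spec.max_place_tries):
                pick = cyto_px[rng.integers(len(cyto_px))]
                radius = rng.uniform(*spec.droplet_radius_range)
                dr, dc = _disc_indices(rows, cols, tuple(pick), radius)
                ok = np.isin(labels[dr, dc],
                             (LABELS["cytoplasm"], LABELS["droplet"],
                              LABELS["droplet_periphery"])).all()
                ok = ok and (cell_instances[dr, dc] == cell_id).all()
                if ok:
                    droplet_id += 1
                    labels[dr, dc] = LABELS["droplet"]
                    droplet_instances[dr, dc] = droplet_id
                    pr, pc = _disc_indices(rows, cols, tuple(pick),
                                           radius + spec.droplet_rim_px)
                    rim = labels[pr, pc] == LABELS["cytoplasm"]
                    labels[pr[rim], pc[rim]] = LABELS["droplet_periphery"]
                    periphery_owner[pr[rim], pc[rim]] = droplet_id
                    success = True
                    break
            if not success:
                raise PlacementError(
                    f"could not place a droplet in cell {cell_id} after "
                    f"{spec.max_place_tries} tries (density too high?)"
                )

    cell_px = int((labels > 0).sum())
    droplet_px = int((labels == LABELS["droplet"]).sum())
    fraction = droplet_px / cell_px if cell_px else 0.0

    truth = GroundTruth(
        label_map=Image2D(labels, meaning="label"),
        cell_instance_map=Image2D(cell_instances, meaning="label"),
        droplet_instance_map=Image2D(droplet_instances, meaning="label"),
        true_droplet_area_fraction=fraction,
    )
    return truth, periphery_owner


# --------------------------------------------------------------------------
# spectral rendering
# --------------------------------------------------------------------------

def _template_matrix(templates: Mapping[str, SpectralTemplate],
                     wavenumbers: np.ndarray) -> np.ndarray:
    return np.stack([templates[name].evaluate(wavenumbers)
                     for name in LABEL_NAMES])


def generate_phantom(spec: PhantomSpec, axis: WavenumberAxis | None = None
                     ) -> tuple[HyperspectralStack, GroundTruth]:
    """Render a seeded hyperspectral phantom and its ground truth.

    Every pixel's spectrum is its compartment template evaluated on the axis
    plus (for finite ``snr``) zero-mean Gaussian noise with standard deviation
    ``max(droplet template on axis) / snr``.  Bit-identical for equal
    ``spec`` + ``axis``.
    """
    if axis is None:
        axis = default_axis()
    rng = np.random.default_rng(spec.seed)
    truth, _ = _render_geometry(spec, rng)
    templates = spec.resolved_templates()
    tmat = _template_matrix(templates, axis.values)
    cube = tmat[truth.label_map.values]
    if np.isfinite(spec.snr):
        sigma = tmat[LABELS["droplet"]].max() / spec.snr
        cube = cube + rng.normal(0.0, sigma, size=cube.shape)
    return HyperspectralStack(intensities=cube, axis=axis), truth


def derive_seed(seed: int, *indices: int) -> int:
    """Deterministic child seed for (seed, index...) tuples, < 2**31."""
    ss = np.random.SeedSequence([int(seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def iter_dose_series(base_spec: PhantomSpec, doses: Sequence[str],
                     accumulation_curve: Mapping[str, float],
                     n_replicates: int, seed: int,
                     axis: WavenumberAxis | None = None
                     ) -> Iterator[tuple[str, int, HyperspectralStack, GroundTruth]]:
    """Stream phantoms of a dose series, one per dose x replicate.

    Each phantom's droplet density is ``base density x accumulation multiplier``
    with a child seed derived from ``(seed, dose index, replicate index)``.
    """
    if not doses:
        raise ValueError("doses must be non-empty")
    for dose in doses:
        if dose not in accumulation_curve:
            raise ValueError(f"no accumulation multiplier for dose {dose!r}")
        if accumulation_curve[dose] < 0:
            raise ValueError("accumulation multipliers must be >= 0")
    for d_index, dose in enumerate(doses):
        density = base_spec.droplet_density * accumulation_curve[dose]
        for r_index in range(n_replicates):
            spec = replace(base_spec, droplet_density=density,
                           seed=derive_seed(seed, d_index, r_index))
            stack, truth = generate_phantom(spec, axis)
            yield dose, r_index, stack, truth


def generate_dose_series(base_spec: PhantomSpec, doses: Sequence[str],
                         accumulation_curve: Mapping[str, float],
                         n_replicates: int, seed: int,
                         axis: WavenumberAxis | None = None
                         ) -> list[tuple[str, int, HyperspectralStack, GroundTruth]]:
    return list(iter_dose_series(base_spec, doses, accumulation_curve,
                                 n_replicates, seed, axis))


def generate_zstack(spec: PhantomSpec, n_planes: int,
                    channel_wavenumber: float, seed: int | None = None
                    ) -> tuple[ZStack, GroundTruth]:
    """Single-frequency focal series: droplets live in one random plane each.

    Each plane shows the constant cell-body rendering at ``channel_wavenumber``
    with only the droplets (and their rims) whose focal plane matches; the
    union of the per-plane droplet masks equals the droplet instance support.
    With ``n_planes == 1`` the single plane equals the phantom's rendering at
    that wavenumber.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth, periphery_owner = _render_geometry(spec, rng)
    templates = spec.resolved_templates()
    values = _template_matrix(templates, np.array([channel_wavenumber]))[:, 0]

    labels = truth.label_map.values
    droplet_ids = np.arange(1, truth.n_droplets + 1)
    planes_of = rng.integers(0, n_planes, size=droplet_ids.size)

    # cell-body background: droplet and rim pixels revert to cytoplasm
    base_labels = labels.copy()
    droplet_like = np.isin(labels, (LABELS["droplet"], LABELS["droplet_periphery"]))
    base_labels[droplet_like] = LABELS["cytoplasm"]

    planes = np.empty((n_planes, *labels.shape), dtype=float)
    for p in range(n_planes):
        plane_labels = base_labels.copy()
        in_plane = droplet_ids[planes_of == p]
        if in_plane.size:
            disc = np.isin(truth.droplet_instance_map.values, in_plane)
            rim = np.isin(periphery_owner, in_plane) & (
                labels == LABELS["droplet_periphery"])
            plane_labels[rim] = LABELS["droplet_periphery"]
            plane_labels[disc] = LABELS["droplet"]
        planes[p] = values[plane_labels]
    if np.isfinite(spec.snr):
        sigma = values[LABELS["droplet"]] / spec.snr
        planes = planes + rng.normal(0.0, sigma, size=planes.shape)
    return ZStack(intensities=planes, z_step=1.0), truth


# --------------------------------------------------------------------------
# template phasors and auto-ROIs
# --------------------------------------------------------------------------

def template_phasors(templates: Mapping[str, SpectralTemplate],
                     axis: WavenumberAxis, harmonic: int = 1
                     ) -> dict[str, tuple[float, float]]:
    """Phasor coordinates of each compartment template on the given axis."""
    cos_k, sin_k = phasor_kernel(axis.n_channels, harmonic)
    out = {}
    for name, template in templates.items():
        spectrum = template.evaluate(axis.values)
        total = spectrum.sum()
        if total <= 0:
            out[name] = (0.0, 0.0)
        else:
            out[name] = (float(spectrum @ cos_k / total),
                         float(spectrum @ sin_k / total))
    return out


# Core compartments are listed before the mixed-rim classes: rim spectra are
# linear mixtures whose phasors lie between the core clusters, so first-wins
# containment must not let a rim box pre-empt pixels of a core class.
_ROI_ORDER = ("droplet", "nucleolus", "nucleus", "cytoplasm",
              "droplet_periphery", "cell_periphery", "background")

_ROI_COLORS = {
    "droplet": "gold",
    "droplet_periphery": "green",
    "nucleolus": "cyan",
    "nucleus": "blue",
    "cell_periphery": "red",
    "cytoplasm": "purple",
    "background": "dimgray",
}


def rois_from_templates(templates: Mapping[str, SpectralTemplate],
                        axis: WavenumberAxis, half_width: float = 0.05,
                        harmonic: int = 1,
                        order: Iterable[str] = _ROI_ORDER) -> list[PhasorROI]:
    """Square phasor ROIs centred on the template phasor positions."""
    centers = template_phasors(templates, axis, harmonic)
    rois = []
    for name in order:
        g, s = centers[name]
        rois.append(PhasorROI(
            label=name,
            rect=(g - half_width, g + half_width, s - half_width, s + half_width),
            color=_ROI_COLORS.get(name, "gray"),
        ))
    return rois
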