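"""Hyperspectral stack / Z-stack containers, TIFF I/O and pipeline configuration.

On-disk convention
------------------
A hyperspectral stack is stored as a multi-page TIFF (one page per wavenumber
channel) next to a small YAML sidecar that carries the wavenumber axis and,
optionally, the pixel size.  The in-memory layout is ``(row, col, channel)``
with the channel axis last; TIFF pages are written in channel order so page
``k`` corresponds to ``axis.values[k]``.  Z-stacks use ``(plane, row, col)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "AxisValidationError",
    "StackAxisMismatchError",
    "ConfigError",
    "WavenumberAxis",
    "HyperspectralStack",
    "ZStack",
    "Image2D",
    "read_stack",
    "write_stack",
    "read_zstack",
    "write_zstack",
    "load_config",
    "PipelineConfig",
    "GeneratorConfig",
    "PhasorConfig",
    "SegmentationConfig",
    "QuantConfig",
]


class AxisValidationError(ValueError):
    """The wavenumber axis violates monotonicity or uniform-spacing rules."""


class StackAxisMismatchError(ValueError):
    """Page count of a stack does not match the length of its axis."""


class ConfigError(ValueError):
    """Pipeline configuration is malformed."""


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

# The acquisition retunes the pump laser in fixed wavelength steps, so the
# wavenumber axis must be close to uniformly spaced for channel-index Fourier
# kernels to be meaningful.  Tolerated relative deviation of any single step
# from the mean step:
_MAX_SPACING_DEVIATION = 0.10


@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered Raman-shift axis (cm^-1), one entry per stack page."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise AxisValidationError("axis must be a non-empty 1D sequence")
        if not np.all(np.isfinite(values)):
            raise AxisValidationError("axis contains non-finite values")
        if values.size > 1:
            steps = np.diff(values)
            if np.any(steps <= 0):
                raise AxisValidationError(
                    "wavenumber axis must be strictly increasing"
                )
            mean_step = steps.mean()
            if np.max(np.abs(steps - mean_step)) >= _MAX_SPACING_DEVIATION * mean_step:
                raise AxisValidationError(
                    "wavenumber axis spacing deviates more than "
                    f"{_MAX_SPACING_DEVIATION:.0%} from uniform"
                )
        object.__setattr__(self, "values", values)

    @property
    def n_channels(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_channels


@dataclass
class HyperspectralStack:
    """3D intensity block indexed ``(row, col, channel)`` plus its axis."""

    intensities: np.ndarray
    axis: WavenumberAxis
    pixel_size: float | None = None  # um / pixel, optional

    def __post_init__(self) -> None:
        data = np.asarray(self.intensities, dtype=float)
        if data.ndim != 3:
            raise ValueError("intensities must be 3D (row, col, channel)")
        if data.shape[2] != self.axis.n_channels:
            raise StackAxisMismatchError(
                f"stack has {data.shape[2]} channels but axis lists "
                f"{self.axis.n_channels} wavenumbers"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("stack intensities must be finite")
        self.intensities = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ZStack:
    """Single-frequency focal series indexed ``(plane, row, col)``."""

    intensities: np.ndarray
    z_step: float = 1.0  # um between planes

    def __post_init__(self) -> None:
        data = np.asarray(self.intensities, dtype=float)
        if data.ndim != 3 or data.shape[0] < 1:
            raise ValueError("Z-stack must be 3D (plane, row, col) with >=1 plane")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        self.intensities = data

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]


_IMAGE_MEANINGS = ("intensity", "ratio", "mask", "label")


@dataclass
class Image2D:
    """2D image with a semantic tag; masks are {0,1}, labels are ints >= 0."""

    values: np.ndarray
    meaning: str = "intensity"
    display_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("Image2D requires a 2D array")
        if self.meaning not in _IMAGE_MEANINGS:
            raise ValueError(f"meaning must be one of {_IMAGE_MEANINGS}")
        if self.meaning == "mask":
            if not np.isin(values, (0, 1)).all():
                raise ValueError("mask images may contain only 0 and 1")
            values = values.astype(np.uint8)
        elif self.meaning == "label":
            if not np.issubdtype(values.dtype, np.integer) or (values < 0).any():
                raise ValueError("label images must hold non-negative integers")
        else:
            values = values.astype(float)
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# --------------------------------------------------------------------------
# stack I/O
# --------------------------------------------------------------------------

def _default_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".axis.yaml")


def read_stack(path: str | Path, axis_path: str | Path | None = None) -> HyperspectralStack:
    """Read a multi-page TIFF and its wavenumber sidecar.

    ``axis_path`` defaults to ``<path>.axis.yaml``.  The page count must match
    the axis length exactly; the axis must pass validation.
    """
    path = Path(path)
    axis_path = Path(axis_path) if axis_path is not None else _default_sidecar(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single-page stack
        pages = pages[None, ...]
    with open(axis_path) as fh:
        sidecar = yaml.safe_load(fh)
    if not isinstance(sidecar, Mapping) or "wavenumbers" not in sidecar:
        raise ConfigError(f"sidecar {axis_path} must contain a 'wavenumbers' list")
    wavenumbers = np.asarray(sidecar["wavenumbers"], dtype=float)
    if pages.shape[0] != wavenumbers.size:
        raise StackAxisMismatchError(
            f"TIFF has {pages.shape[0]} pages but sidecar lists "
            f"{wavenumbers.size} wavenumbers"
        )
    axis = WavenumberAxis(wavenumbers)
    pixel_size = sidecar.get("pixel_size")
    return HyperspectralStack(
        intensities=np.moveaxis(pages, 0, -1),
        axis=axis,
        pixel_size=float(pixel_size) if pixel_size is not None else None,
    )


def write_stack(stack: HyperspectralStack, path: str | Path,
                axis_path: str | Path | None = None) -> None:
    """Write a stack as a multi-page float TIFF plus a YAML axis sidecar.

    Round-trip with :func:`read_stack` is lossless for intensities and axis.
    """
    path = Path(path)
    axis_path = Path(axis_path) if axis_path is not None else _default_sidecar(path)
    pages = np.ascontiguousarray(np.moveaxis(stack.intensities, -1, 0))
    tifffile.imwrite(path, pages)
    sidecar: dict = {"wavenumbers": [float(v) for v in stack.axis.values]}
    if stack.pixel_size is not None:
        sidecar["pixel_size"] = float(stack.pixel_size)
    with open(axis_path, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_zstack(path: str | Path, z_step: float = 1.0) -> ZStack:
    pages = tifffile.imread(Path(path))
    if pages.ndim == 2:
        pages = pages[None, ...]
    return ZStack(intensities=pages, z_step=z_step)


def write_zstack(zstack: ZStack, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.ascontiguousarray(zstack.intensities))


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    image_size: tuple[int, int] = (256, 256)
    n_cells: int = 12
    droplet_density: float = 2.0
    droplet_radius_range: tuple[float, float] = (2.0, 4.0)
    snr: float = 20.0  # peak droplet signal / noise std; inf = noiseless

    def validate(self) -> None:
        rows, cols = self.image_size
        if rows < 8 or cols < 8:
            raise ConfigError("generator.image_size must be at least 8x8")
        if self.n_cells < 0:
            raise ConfigError("generator.n_cells must be >= 0")
        if self.droplet_density < 0:
            raise ConfigError("generator.droplet_density must be >= 0")
        lo, hi = self.droplet_radius_range
        if not (0 < lo <= hi):
            raise ConfigError("generator.droplet_radius_range must satisfy 0 < lo <= hi")
        if not self.snr > 0:
            raise ConfigError("generator.snr must be positive (inf for noiseless)")


@dataclass
class PhasorConfig:
    harmonic: int = 1
    pre_threshold: float | None = None

    def validate(self) -> None:
        if self.harmonic < 1:
            raise ConfigError("phasor.harmonic must be >= 1")
        if self.pre_threshold is not None and self.pre_threshold < 0:
            raise ConfigError("phasor.pre_threshold must be >= 0 when set")


@dataclass
class SegmentationConfig:
    auto_rois: bool = True
    roi_half_width: float = 0.05
    rois: list = field(default_factory=list)

    def validate(self) -> None:
        if not 0 < self.roi_half_width <= 1:
            raise ConfigError("segmentation.roi_half_width must be in (0, 1]")
        if not self.auto_rois and not self.rois:
            raise ConfigError("segmentation.rois required when auto_rois is false")


# Dose design of the synthetic statin series: three low doses with no effect
# followed by an accumulating response, mirroring a 48 h atorvastatin
# treatment ramp (0.5-25 uM) with droplet build-up above 5 uM.
_DEFAULT_DOSES: dict[str, float] = {
    "control": 1.0,
    "0.5uM": 1.0,
    "1uM": 1.0,
    "5uM": 3.0,
    "10uM": 5.0,
    "25uM": 6.0,
}


@dataclass
class QuantConfig:
    droplet_label: str = "droplet"
    control_condition: str = "control"
    min_droplet_px: int = 4
    doses: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DOSES))
    n_replicates: int = 3

    def validate(self) -> None:
        if self.min_droplet_px < 1:
            raise ConfigError("quantification.min_droplet_px must be >= 1")
        if not self.doses:
            raise ConfigError("quantification.doses must be non-empty")
        if any(m < 0 for m in self.doses.values()):
            raise ConfigError("quantification dose multipliers must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("quantification.n_replicates must be >= 1")
        if self.control_condition not in self.doses:
            raise ConfigError(
                f"control condition {self.control_condition!r} missing from doses"
            )


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    phasor: PhasorConfig = field(default_factory=PhasorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quantification: QuantConfig = field(default_factory=QuantConfig)

    def validate(self) -> None:
        self.generator.validate()
        self.phasor.validate()
        self.segmentation.validate()
        self.quantification.validate()


_BLOCK_TYPES = {
    "generator": GeneratorConfig,
    "phasor": PhasorConfig,
    "segmentation": SegmentationConfig,
    "quantification": QuantConfig,
}

_TUPLE_FIELDS = {"image_size", "droplet_radius_range"}


def _build_block(name: str, cls, raw: Mapping):
    known = set(cls.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}"
        )
    kwargs = {}
    for key, value in raw.items():
        if key in _TUPLE_FIELDS and isinstance(value, Sequence):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                data: Mapping | None = None,
                require_blocks: Sequence[str] = ()) -> PipelineConfig:
    """Load and validate a pipeline configuration.

    Either ``path`` (YAML file) or ``data`` (already-parsed mapping) must be
    given.  Absent blocks fall back to defaults; ``require_blocks`` lists
    blocks that must be present explicitly (the error names the block).
    Unknown top-level or block-level keys are rejected.
    """
    if (path is None) == (data is None):
        raise ValueError("provide exactly one of path or data")
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError("config root must be a mapping")
    data = copy.deepcopy(dict(data))

    allowed = {"seed", *_BLOCK_TYPES}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    for block in require_blocks:
        if block not in data:
            raise ConfigError(f"required config block {block!r} is missing")

    kwargs: dict = {"seed": int(data.get("seed", 0))}
    for name, cls in _BLOCK_TYPES.items():
        raw = data.get(name)
        if raw is None:
            kwargs[name] = cls()
        elif isinstance(raw, Mapping):
            kwargs[name] = _build_block(name, cls, raw)
        else:
            raise ConfigError(f"config block {name!r} must be a mapping")
    config = PipelineConfig(**kwargs)
    config.validate()
    return config
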