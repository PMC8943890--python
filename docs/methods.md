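# Methods

## The spectral phasor model

A hyperspectral SRS stack assigns every pixel a spectrum `I_k` sampled at
`N` Raman shifts (channels). The spectral phasor at harmonic `n` (default 1)
is the normalised discrete Fourier coefficient

    G = Σ_k I_k cos(2πnk/N) / T,   S = Σ_k I_k sin(2πnk/N) / T,   T = Σ_k I_k.

Conventions fixed by this package, so ROI coordinates are portable:

- **+sin sign and channel-index kernel.** The kernel runs over the channel
  index `k`, not the wavenumber value; a delta spectrum concentrated in the
  first channel maps to (1, 0). Because the kernel is index-based, the axis
  must be retuned in (approximately) even steps; axis validation rejects any
  step deviating more than 10% from the mean step.
- **No preprocessing.** Raw intensities enter the transform — no smoothing,
  baseline subtraction, or normalisation. An optional intensity
  pre-threshold on the spectral sum exists but defaults to off.
- **Validity.** Pixels with `T ≤ 0` (possible in noisy data, since the
  detector model is signed) carry no shape information. They are flagged
  invalid with `G = S = 0`, and excluded from histograms and ROI membership.
  This stops noise-dominated background from contaminating phasor clusters.

Useful identities (all tested): non-negative spectra map into the closed
unit disk; the phasor of a sum of spectra is the `T`-weighted average of the
phasors (the linear mixing rule, which is why compartment boundaries form
chords between cluster centres); cyclically shifting a spectrum by one
channel rotates its phasor by `2πn/N`.

## Phasor-plane segmentation

Segmentation assigns each valid pixel to the first ROI in a user-ordered
list whose region contains its (G, S); containment is closed on boundaries;
pixels in no ROI keep label 0. ROIs are axis-aligned rectangles or simple
polygons (point-in-polygon via shapely, boundary inclusive).

ROIs can be written explicitly in the config, or derived automatically as
squares of half-width 0.05 centred on the phasor positions of the phantom's
compartment templates. The automatic list orders **core compartments before
mixed-rim classes** (droplet, nucleolus, nucleus, cytoplasm, then droplet
periphery, cell periphery, background): rim spectra are linear mixtures
whose phasors lie between core clusters, and under first-wins containment a
rim box must not pre-empt pixels of a core class.

## Phenotype metrics

- **Percent droplet area** = 100 × |droplet-class pixels ∩ cell mask| /
  |cell mask|. The cell mask is a threshold of the average intensity
  projection (Otsu on a 256-bin histogram by default). Only the droplet
  class counts — not the droplet-periphery rim.
- **3015/2965 cm⁻¹ marker ratio** of the *un-normalised* droplet-class mean
  spectrum. Heights are read by linear interpolation between flanking
  channels because the ~6.4 cm⁻¹ sampling does not land on the marker
  positions. The ratio indexes droplet composition: ≈0.75 for
  triacylglycerol-dominant droplets, lower with cholesterol-ester content.
  It is computed from the class mean spectrum (a per-droplet option exists
  via instance masks); it is invariant to global intensity scaling.
- **Percent of cells containing droplets**: a cell counts as
  droplet-positive when its footprint holds at least `min_droplet_px = 4`
  droplet pixels (guards against single-pixel noise). Cell instances come
  from generator ground truth when available, otherwise from 8-connected
  components of the cell mask.
- **Per-cell mean intensity** of a projection (e.g. the 2851 cm⁻¹ maximum
  intensity projection of a Z-stack) over each cell footprint.
- **Statistics**: classic pooled-variance two-sample Student's *t* (equal
  replicate counts make Welch unnecessary), two-tailed p from the *t*
  distribution, `df = n_a + n_b − 2`; stars `*` at P ≤ 0.05 and `**` at
  P ≤ 0.01. Each dose is compared with control independently; no
  multiple-testing correction is applied across doses (a deliberate caveat —
  the per-dose stars mirror how such panels are conventionally reported).

## The phantom generator

The generator renders what the analysis consumes: fields of ellipsoidal
cells (non-overlapping, fully in frame) with a 2 px outer rim
(cell-periphery class), a co-oriented nuclear ellipse (~0.5 of the cell
axes) holding 1–2 disc nucleoli, and cytoplasmic lipid droplets — discs of
radius 2–4 px with a 1 px mixing rim — placed uniformly in the cytoplasm by
rejection sampling (droplets may coalesce with each other but never overlap
nuclei, nucleoli or the cell rim; a bounded retry budget turns impossible
densities into an explicit error). Droplet counts per cell are Poisson with
mean `droplet_density`. Ground truth returns the compartment label map, cell
and droplet instance maps, and the true droplet area fraction
(droplet px / cell px).

Each compartment carries a spectral template: Gaussian bands (σ = 18 cm⁻¹;
condensed-phase CH-stretch bands are broad) at 2851, 2880, 2930, 2965 and
3010–3015 cm⁻¹ over a flat pedestal. Detector noise is zero-mean additive
Gaussian — SRS noise at typical powers is laser/shot-noise dominated and
well approximated as additive — with `snr` defined as (max droplet template
on the axis) / (noise std). Noisy spectra may go negative, as real lock-in
SRS data do.

**Template calibration.** Absolute per-compartment intensities are free
parameters of the phantom; the defaults were fixed once against three
requirements:

1. compartment phasor clusters on the default 40-channel axis separate
   pairwise by more than twice the 0.05 auto-ROI half-width (so noiseless
   segmentation is exact and recovery at SNR 10 stays above 90%);
2. every cellular compartment's average-projection level exceeds the
   background pedestal, so Otsu thresholding recovers the exact cell
   support on noiseless data (this is why the droplet baseline is 0.32
   rather than lower: a dimmer droplet interior falls to the background
   level in the average projection and drops out of the cell mask);
3. the droplet template's evaluated 3015/2965 cm⁻¹ height ratio equals
   0.75 exactly — the =CH band amplitude is solved in closed form at
   template construction.

The background pedestal (0.72) is deliberately generous relative to real
off-resonance SRS backgrounds: it represents the aqueous/non-resonant
pedestal and gives background pixels a well-defined spectral sum, so their
phasors form a compact cluster at the origin instead of a noise-dominated
scatter. The consequences are stated under Limitations.

**Dose series.** A dose series maps condition labels to droplet-density
multipliers (default: control, 0.5, 1, 5, 10, 25 µM with multipliers
1, 1, 1, 3, 5, 6 — three ineffective low doses followed by accumulating
response, emulating a 48 h statin ramp), with three replicates per
condition. Child seeds derive deterministically from (seed, dose index,
replicate index) via `numpy.random.SeedSequence`, so every phantom is
independent yet reproducible. The default field holds 12 cells, so a
three-replicate condition covers 36 cells — matching the ≥30-cells-per-
condition design such experiments use.

**Z-stacks.** Single-frequency focal series place each droplet in one
random plane over a constant cell-body rendering; the union of per-plane
droplet masks equals the droplet support, so the maximum intensity
projection sees every droplet while single planes do not.

## Key parameters

| parameter | default | units | notes |
|---|---|---|---|
| axis | 2800–3050, 40 channels | cm⁻¹ | ~6.4 cm⁻¹ steps |
| harmonic `n` | 1 | – | standard first-harmonic phasor |
| ROI half-width | 0.05 | phasor units | auto-ROI squares |
| image size | 256 × 256 | px | phantom field of view |
| n_cells | 12 | – | 36 cells per 3-replicate condition |
| droplet_density | 2.0 | droplets/cell | Poisson mean, × dose multiplier |
| droplet radius | 2–4 | px | uniform |
| snr | 20 | – | droplet peak / noise std; `inf` = noiseless |
| min_droplet_px | 4 | px | droplet-positive cell gate |
| ratio display max | 0.8 | – | display metadata only, data unclipped |

## Numerical choices

- Otsu (256 bins) is the default automatic threshold — reproducible and the
  common default of interactive tools; a constant image raises instead of
  guessing.
- Division-by-zero pixels in ratio images map to 0 (background semantics),
  never NaN/inf, keeping area arithmetic well defined; ratio values are
  stored unclipped with the 0–0.8 display range as metadata.
- Phasor histograms bin valid pixels on a half-open [−1, 1)² grid (last bin
  closed); out-of-disk coordinates (noise-driven) are clipped into the edge
  bins so counts are conserved.
- Min-max spectrum normalisation maps a constant spectrum to all zeros by
  convention.
- ROI overlap resolves by list order (first wins); containment is closed so
  abutting ROIs share their boundary deterministically.
- Stacks are written as float multi-page TIFF with a YAML wavenumber
  sidecar; round-trips are bit-exact. Intensities are floats even when an
  instrument would digitise at 12 bits, because the phasor arithmetic is
  real-valued.

## Problem sizes used in the test suite

Unit tests run on 96² phantoms with 2 cells; recovery tests use the default
256² × 40 phantom (~63k scored pixels); the dose-response check runs
10 seed batches × 6 doses × 3 replicates (180 phantoms) at the default
geometry; the whole suite completes in well under a minute on one CPU.

## What passing tests do and do not show

The phantom reproduces the *structure* of the measurement problem —
brightness-invariant spectral clustering, compartment geometry, dose-
dependent droplet load, additive noise — so the tests demonstrate that the
pipeline recovers known truth under that model. Real data differ in ways
the phantom deliberately omits: no optical point-spread function or
partial-volume blur (real droplets near the resolution limit mix spectra
over several pixels), no confocal sectioning in Z-stacks, no spatially
structured background or non-resonant spectral slope, Gaussian rather than
Poisson/pink noise, and background far cleaner than any real field of view.
Segmentation accuracies measured here are therefore upper bounds, and real
analyses should expect to hand-tune ROIs rather than derive them from
templates. Manual steps of the original workflow (freehand cell outlines,
hand-drawn phasor ROIs) are replaced by reproducible equivalents (connected
components / template-centred boxes), which is a deliberate behavioural
difference, not an oversight.
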