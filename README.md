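# srsphasor

Spectral-phasor analysis of hyperspectral stimulated Raman scattering (SRS)
microscopy, built for label-free lipid-droplet phenotyping of cell
populations — e.g. quantifying statin-induced lipid accumulation in breast
cancer cell lines without fluorescent dyes.

## What it does

A hyperspectral SRS experiment acquires one image per Raman shift across the
CH-stretch window (2800–3050 cm⁻¹, typically 40 channels ~6 cm⁻¹ apart), so
every pixel carries a vibrational spectrum. `srsphasor` implements the full
desk-side analysis:

1. **Spectral phasor transform.** Each pixel spectrum `I_k` (`k = 0…N−1`) is
   mapped to normalised first-harmonic Fourier coordinates

   ```
   G = Σₖ I_k cos(2πnk/N) / Σₖ I_k      S = Σₖ I_k sin(2πnk/N) / Σₖ I_k
   ```

   Raw intensities enter unchanged; the normalisation removes brightness so
   pixels cluster in the (G, S) plane purely by spectral shape. Non-negative
   spectra always land inside the unit disk.
2. **Phasor-plane segmentation.** Labelled ROIs (rectangles or polygons) in
   the (G, S) plane classify pixels into compartments — nucleus, nucleoli,
   cytoplasm, cell periphery, lipid droplets, droplet periphery, background —
   and the labels map back to image space.
3. **Ratiometric and projection imaging.** CH₂/CH₃ (2851/2930 cm⁻¹) ratio
   images with threshold masking, plus maximum/average intensity projections
   of Z-stacks and spectral stacks.
4. **Droplet phenotype quantification.** Percent of cell area occupied by
   droplet pixels, the 3015/2965 cm⁻¹ marker ratio of the droplet mean
   spectrum (≈0.75 for triacylglycerol-dominant droplets; cholesterol esters
   pull it down), percent of cells containing droplets, per-cell projection
   intensities, and pooled-variance Student's *t*-tests of each dose against
   control across replicates.
5. **Ground-truth phantoms.** A seeded generator renders multi-cell fields
   with per-compartment CH-stretch spectra, dose-dependent droplet loads and
   Gaussian detector noise, so every stage can be validated against known
   truth (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from srsphasor import (
    PhantomSpec, default_axis, default_templates, generate_phantom,
    phasor_transform, rois_from_templates, segment_by_rois,
    roi_mean_spectrum, average_projection, threshold_mask,
    percent_area, peak_ratio,
)

axis = default_axis()                      # 40 channels, 2800-3050 cm^-1
spec = PhantomSpec(seed=1, snr=np.inf, droplet_density=4.0)
stack, truth = generate_phantom(spec, axis)

field = phasor_transform(stack)            # per-pixel (G, S)
rois = rois_from_templates(default_templates(), axis, half_width=0.05)
seg = segment_by_rois(field, rois)

cell_mask = threshold_mask(average_projection(stack), "otsu")
print("true droplet area fraction: %.3f %%"
      % (100 * truth.true_droplet_area_fraction))
print("estimated percent area:     %.3f %%"
      % percent_area(seg, "droplet", cell_mask))
profile = roi_mean_spectrum(stack, seg, "droplet")
print("droplet 3015/2965 ratio:    %.3f" % peak_ratio(profile))
```

prints

```
true droplet area fraction: 6.135 %
estimated percent area:     6.135 %
droplet 3015/2965 ratio:    0.748
```

On this noiseless phantom the phasor segmentation recovers the droplet area
fraction exactly, and the 3015/2965 cm⁻¹ marker ratio of the segmented
droplet class reproduces the generator's calibrated TAG value of 0.75 to
within the ~6 cm⁻¹ channel-sampling error.

## Command line

```bash
srsphasor run --config config.yaml --outdir results/run1   # full pipeline
srsphasor simulate --outdir phantoms --seed 1              # phantoms only
srsphasor phasor --stack stack.tif --out-prefix out/ph     # G/S + histogram
srsphasor segment --stack stack.tif --outdir out           # ROI labels + spectra
srsphasor ratio --stack stack.tif --out-prefix out/ch2ch3  # CH2/CH3 image
srsphasor quantify --manifest phantoms/manifest.csv --outdir out
```

`run` writes a deterministic directory (`stacks/`, `phasors/`,
`segmentations/`, `tables/`, `figures/`, `run.json`): re-running with the
same config and seed reproduces every CSV byte-for-byte.

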