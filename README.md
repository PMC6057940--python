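# fibrilquant

Quantification of fibrillar collagen organization in second-harmonic
generation (SHG) microscopy, plus single-hit limiting-dilution frequency
estimation — the image-analysis and assay-statistics toolkit behind
studies of stromal remodeling at the tumour–stromal interface.

## Who this is for

Groups quantifying extracellular-matrix remodeling from grayscale
microscopy (SHG, picrosirius-red-adjacent workflows) who need
reproducible, scriptable versions of the standard ImageJ-style readouts,
with exact synthetic ground truth to validate every statistic; and groups
running limiting-dilution transplant assays who want the single-hit
Poisson fit (the "1 in N" stem-cell frequency) with profile-likelihood
CIs and group tests, offline.

## What it computes

For a calibrated grayscale image *I* (pixel size in μm), optionally
restricted to an ROI or to the ≤200 μm interface band adjoining a tissue
compartment:

* **Coverage** — % of pixels with *I* > *t* for a single global
  threshold *t* (per image; per depth and at peak for z-stacks). A pooled
  Otsu threshold is available as a reproducible global choice.
* **GLCM correlation decay** — Haralick correlation of the gray-level
  co-occurrence matrix *P(i,j | d, θ)* as a function of offset distance
  *d*, summarized by the normalized area under the curve and the
  half-decay distance. Slower decay ⇒ more organized fiber network.
* **Structure-tensor orientation** — per-pixel orientation
  θ = 90° − ½·atan2(2J₁₂, J₁₁ − J₂₂) and coherency
  (λ₁−λ₂)/(λ₁+λ₂) from the Gaussian-windowed tensor of cubic-B-spline
  image gradients; summarized as an axial histogram with **peak
  alignment** (mode, degrees) and **alignment frequency** (mass within
  ±Δ of the peak, Δ = 10° by default).
* **Limiting-dilution analysis** — MLE of the active-cell frequency *f*
  under P(response | dose d) = 1 − exp(−f·d), with 95% profile CIs,
  boundary-case handling, and a 1-df likelihood-ratio group test.
* **Group statistics** — equal-variance t, Mann–Whitney U,
  Kruskal–Wallis and Fisher's exact tests wired to the appropriate
  metric types in the batch pipeline.

A synthetic fiber-phantom generator (`generate_fiber_scene`) renders
SHG-like 320 × 320 μm fields with exact ground truth (coverage mask,
per-segment orientations, alignment fraction), so the whole pipeline is
testable without tissue data. See `docs/methods.md` for models,
conventions and parameter defaults.

## Worked example

```python
from fibrilquant import (FiberSceneSpec, generate_fiber_scene,
                         normalize_intensity, orientation_analysis)

spec = FiberSceneSpec(height_px=256, width_px=256, pixel_size_um=1.25,
                      n_fibers=1500, fiber_length_um=30.0,
                      peak_angle_deg=40.0, kappa=8.0, seed=2)
scene = generate_fiber_scene(spec)
img = normalize_intensity(scene.image, "percentile(99.9)")
field, hist = orientation_analysis(img)
print(scene.true_peak_angle_deg, hist.peak_angle_deg, hist.alignment_frequency)
```

prints

```
40.0 42.5 0.9314...
```

— the phantom was built with its fiber axis at 40°; the structure-tensor
pipeline recovers a peak alignment of 42.5° from the noisy image (mean
absolute error ≈ 1° over repeated phantoms at this concentration) and an
alignment frequency of 0.93, i.e. 93% of the oriented signal lies within
±10° of the peak. The scripts in `examples/` walk through each
capability the same way (coverage vs ground truth, texture decay of
organized vs disorganized networks, dilution-assay fitting, and the full
batch study), each printing the numbers it computes and what they mean.

## Command line

```bash
fibrilquant synth --config scene.yaml --out phantoms/ --seed 1
fibrilquant coverage images/*.tif --threshold 500 --pixel-size 0.625
fibrilquant glcm images/*.tif --pixel-size 0.625
fibrilquant orient images/*.tif --pixel-size 0.625
fibrilquant lda dilution_table.csv
fibrilquant run --config study.yaml      # full batch pipeline
```

`run` writes `metrics.csv`, `comparisons.csv`, `run_manifest.json` and
`run.log` into the configured output directory; all outputs embed the
package version and a config hash, and reruns with identical
config + seed are byte-identical (except the timestamped log).

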