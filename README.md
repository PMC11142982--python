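# oriquant

Quantification pipeline for **oxidation–reduction imaging (ORI)** of the
myocardium: from 3D fluorescence volumes of cleared infarcted hearts to
per-group oxidation-intensity metrics and oxidized-volume ratios.

## The problem

After myocardial ischemia–reperfusion, reactive oxygen species oxidize
myoglobin (OxyMb/CarbMb → MetMb). MetMb has elevated endogenous
fluorescence in the red band (>600 nm), so the redox state of unlabeled,
cleared heart tissue can be read out optically: light-sheet stacks at
633 nm excitation show a hypersignal in the oxidized part of the
volume-at-risk (VAR), and per-voxel emission spectra red-shift
(620–660 nm band) as CarbMb converts to MetMb. Quantifying that signal
reproducibly is non-trivial because hearts differ in clearing quality,
wall geometry and dye load, which all shift raw intensity scales.

`oriquant` implements the analysis end of this experiment for image
analysts and cardioprotection researchers:

- **segmentation** — Otsu-based anatomical segmentation of the left
  ventricle, extraction of the VAR from the Unisperse-blue intensity
  contrast (the dye quenches the healthy wall), and the equivalent-wedge
  rule for sham hearts that carry no dye;
- **histogram model** — the normalization chain
  (background deletion → 0.002 % foot trim → [0, 1] rescale → frequency
  conversion → group averaging) followed by a two-Gaussian mixture fit
  f(x) = w₁·φ(x; μ₁, σ₁) + w₂·φ(x; μ₂, σ₂) with φ truncated to [0, 1],
  w₁ + w₂ = 1 and μ₁ < μ₂; reported metrics are the component surfaces
  (areas under the curves), their overlap ∫ min(w₁φ₁, w₂φ₂) dx, the
  median of the right (MetMb-like) component, and the mean fit residual;
- **quantification** — the segmentation threshold (mean of the reference
  groups' right-component medians, 0.485 on the normalized scale =
  48.5 % of the maximal intensity), oxidized-voxel classification
  (strictly above threshold, within the VAR), oxidized/VAR and
  oxidized/LV volume ratios, bootstrap 95 % group intervals, and OLS
  correlation against external scalars such as MRI infarct volumes;
- **spectral** — dichroic-gap repair, 585 nm peak normalization,
  non-negative least-squares unmixing onto endmember spectra, the
  620–660 nm red-shift index and depth profiling (in-depth red-shift
  control);
- **phantom** — a seeded synthetic-data generator (annulus wall, wedge
  VAR, oxidized sub-wedge, dye quenching, background noise, optional
  Beer–Lambert depth attenuation, spectral stacks mixed from synthetic
  endmember curves) with exact voxel-level ground truth.

## Worked example

```python
import oriquant as oq

spec = oq.PhantomSpec(rng_seed=0)                 # synthetic infarcted heart
volume, truth_labels, truth_ox = oq.generate_heart_phantom(spec)

labels = oq.segment_ventricles(volume)            # LV / RV / lumen
labels = oq.extract_var(volume, labels)           # VAR vs healthy wall

freq, trimmed = oq.run_chain(volume, labels.var_mask)
fit = oq.fit_two_gaussians(freq, seed=0)
print(f"VAR voxels retained : {trimmed.retained}")
print(f"left Gaussian : surface {fit.surface_1:.2f}, mu {fit.mu1:.3f}")
print(f"right Gaussian: surface {fit.surface_2:.2f}, mu {fit.mu2:.3f}")
print(f"overlap {fit.overlap_area:.3f}, mean residual {fit.mean_residual:.2e}")

ox = oq.segment_oxidized(volume, labels.var_mask, threshold=0.485)
q = oq.quantify_heart(volume, labels, ox, 0.485, heart_id="demo", group="IR")
print(f"oxidized/VAR = {q.ratio_ox_var:.3f}, oxidized/LV = {q.ratio_ox_lv:.3f}")
```

prints

```
VAR voxels retained : 27904
left Gaussian : surface 0.70, mu 0.287
right Gaussian: surface 0.30, mu 0.722
overlap 0.001, mean residual 2.57e-04
oxidized/VAR = 0.302, oxidized/LV = 0.101
```

The phantom was built with a 30 % oxidized core inside the VAR: the right
Gaussian captures that component (surface 0.30 at the high-intensity
mode), and thresholding the normalized intensities recovers an
oxidized/VAR ratio of 0.302.

A `ori` command-line interface exposes each stage
(`phantom`, `segment`, `histogram`, `fit`, `threshold`, `oxidize`,
`quantify`, `unmix`, `run`); see `ori --help`.

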