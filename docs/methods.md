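# Methods

This note documents the models and procedures implemented in `oriquant`,
the parameter choices that matter, what the synthetic phantom does and
does not emulate, and the package's known limitations.

## Imaging model and conventions

Volumes are 3D scalar grids in `(z, y, x)` order (TIFF page index = z),
with physical voxel size in µm (isotropic 1 µm when unknown; all volume
outputs are reported both in voxel counts and µm³, and every published
quantity is a unit-free ratio). Raw intensities keep their acquired dtype
and are promoted to float64 only inside computations. Anatomical labels
use a fixed map: 0 background, 1 LV wall, 2 RV, 3 lumen, 4 VAR,
5 healthy; VAR and healthy are subdivisions of the LV wall.

## Anatomical segmentation

Tissue is separated from background by Otsu's criterion applied to
log-transformed intensities. The log matters: fluorescence contrasts are
multiplicative, and on the linear scale the dominant variance split can
fall between the dye-quenched healthy wall and the bright VAR rather
than between background and tissue, discarding the quenched wall. The
foreground is closed with a 1-voxel structuring element (edge-padded, so
the first and last z-slices are not eroded), components below 64 voxels
are dropped, the largest connected component becomes the LV wall, any
other becomes RV, and background enclosed within a slice becomes lumen.

The VAR is split from the healthy wall by the *lower* threshold of a
three-class Otsu criterion restricted to wall voxels. Three classes
because the wall holds up to three intensity populations (quenched
healthy, ischemic-baseline VAR, oxidized VAR); a two-class criterion can
maximize variance by splitting the VAR internally instead of at the dye
boundary. The split is accepted only if the wall's intensity histogram
(128 bins, 5-bin smoothing) dips below half of the smaller flanking mode
between the two modes surrounding the threshold, with both modes at
least 2 % of the global peak — a unimodal (sham, no dye) wall fails this
valley test and raises `SeparationError` instead of guessing. All
thresholds are recomputed from range-scaled histograms, so VAR
extraction is invariant to positive affine rescaling of the input.

Sham hearts carry no dye contrast; for them the *equivalent wedge* of
the LV wall (matched angular extent and transmural depth, measured about
the wall centroid) is selected so intensities are compared on a similar
volume. The pipeline applies this fallback automatically whenever the
valley test refuses a split.

## Histogram normalization chain

Per heart, VAR voxel intensities are binned into 256 equal-width bins
spanning their range (the bin count is a package default; it is fine
enough for the mixture fit on 8/16-bit data). Then, in order:

1. **background deletion** — bins wholly below a cutoff (absolute
   intensity or quantile; default 0 = no-op for masks that already
   exclude background) are discarded;
2. **foot trim** — each bin's relative frequency is compared to a fixed
   threshold of 2×10⁻⁵ (0.002 %); the first and last bins reaching it
   bound the retained range. The rule is read per-bin, applied once,
   before range normalization. Note it only bites when the VAR holds
   ≳10⁵ voxels (below that a single-count bin already exceeds 0.002 %),
   in which case it also stabilizes the retained range against
   extreme-value noise;
3. **range normalization** — the retained intensity range is mapped
   affinely onto [0, 1] (lowest retained edge → 0, highest → 1) and
   counts become frequencies summing to one.

Counts are conserved: every discarded voxel is accounted in
`discarded_background` / `discarded_foot`. The complete chain is
invariant under positive affine transforms of the raw intensities (the
acceptance suite checks identity to 1e-9 per bin).

Group histograms are arithmetic means of per-heart frequency histograms,
renormalized to unit sum. Histograms on different grids are resampled
onto the default 256-centre grid by linear interpolation with zero fill
outside each histogram's support.

## Two-Gaussian mixture model

The group-mean frequency histogram is fitted with

  f(x) = [w·φ(x; μ₁, σ₁) + (1−w)·φ(x; μ₂, σ₂)] · Δx

where φ is a Gaussian density renormalized over [0, 1] (truncated), so
the component weights are exact areas on the support and the two
surfaces sum to one by construction. The fit is nonlinear least squares
on the binned curve (not voxel-level EM — the object being modelled *is*
the histogram), with bounds 0 ≤ μ ≤ 1 and a σ floor of half a bin width
to prevent delta-spike degeneracy. Initialization uses the weighted
25th/75th percentiles plus four seeded random restarts; the lowest
residual wins, ties broken by the smaller parameter norm; components are
reported sorted by mean.

Derived metrics: `surface_1 = w₁`, `surface_2 = w₂`;
`overlap_area = ∫₀¹ min(w₁φ₁, w₂φ₂) dx` by trapezoidal quadrature at
step 1e-3; `median_right = μ₂` (the median of a Gaussian equals its
mean); `mean_residual` is the mean absolute difference between fit and
frequencies at the bin centres. Overlap ≈ min(w₁, w₂) flags a
degenerate (effectively unimodal) decomposition. Model order is checked
by fitting k ∈ {1, 2, 3} mixtures and comparing a small-sample-corrected
information criterion (AICc) on the Gaussian residuals.

## Threshold and oxidized volume

The segmentation threshold is the arithmetic mean of the right-component
medians of the reference groups (those at or below the cohort mean of
medians). The package default constant is 0.485 on the normalized scale,
i.e. 48.5 % of the maximal retained intensity; recomputing the mean from
the three rounded reference medians (0.485, 0.490, 0.477) gives 0.484 —
both paths are exposed, the constant is the default. A VAR voxel is
oxidized when its intensity, mapped through the *same* chain (background
cut, foot trim, min–max of that VAR), lies strictly above the threshold;
strictness fixes the boundary rule (threshold 1.0 → empty mask,
threshold 0 → the whole retained VAR). Ratios oxidized/VAR and
oxidized/LV are voxel counts times voxel volume; group summaries report
medians with seeded percentile-bootstrap 95 % intervals (10 000
resamples by default) and flag groups whose median exceeds the computed
mean of medians. Statistical hypothesis testing beyond these intervals
is out of scope. Correlation against external scalar measurements (MRI
infarct volume, troponin) is ordinary least squares with Pearson r and
per-point residuals; a constant response is flagged rather than
silently reported.

Note one honest property of the method: a featureless (unimodal) VAR,
e.g. the sham equivalent wedge, min–max normalizes to a distribution
centred near 0.5, so roughly half its voxels exceed a 0.485 threshold.
Sham "oxidized" ratios are therefore not near zero; they reflect the
normalization, which is why sham hearts serve as a reference condition
rather than a true negative control at the ratio level.

## Spectral computations

Dichroic-mirror gaps (default ±10 nm around 405/488/565/647 nm — the
mirror lines are instrument facts, the half-width is a package default)
are repaired by linear interpolation between the nearest valid
channels, constant at the axis edges. Spectra are normalized by the
intensity at the channel nearest 585 nm (ties toward the shorter
wavelength, for determinism); the red-shift index is the mean normalized
intensity over 620–660 nm. Unmixing solves per-voxel non-negative least
squares with no sum-to-one closure — fluorescence scales with emitter
concentration, and nothing forces the endmember set to be exhaustive;
voxels whose unconstrained solution is already non-negative are solved
in one vectorized pass. Spectral class images are the per-voxel arg-max
of the coefficients. Depth profiles are peak-normalized mean spectra of
consecutive slabs; a seeded permutation test on the Spearman trend of
the red-shift index versus depth serves as the attenuation control.

## The phantom: what it emulates, and what it does not

The generator produces an analytic annulus (LV wall) with an angular,
optionally partial-transmural wedge (VAR) and an oxidized sub-wedge of
exactly `round(fraction × n_VAR)` voxels — geometry is voxel-countable
ground truth, not an anatomical mesh. Intensities (defaults, arbitrary
units): healthy wall `quench × N(600, 40)` with quench 0.2, VAR
baseline `N(600, 50)`, oxidized `N(900, 50)`, background `N(20, 5)`,
all truncated at 0 by redraw (clipping would pile a spike at zero and
corrupt the background-deletion stage). The VAR baseline equals the
healthy mean deliberately: undyed tissue is equally bright, and only
the Unisperse quench creates the extraction contrast — hence a sham
spec (quench 1, oxidized fraction 0) is unimodal and exercises the
separation-failure path. The 300-unit component separation is 6σ, and
the quench is strong enough that the healthy/VAR valley dominates the
wall histogram. Cohorts derive per-heart seeds from a master seed
(`SeedSequence.spawn`) and jitter the group parameters multiplicatively
(default 5 % relative).

Spectral stacks are per-voxel non-negative combinations of synthetic
endmember curves — Gaussian sums with a main peak near 585 nm whose red
tail (>600 nm) is larger for the oxidized forms. They are explicitly
synthetic parameterizations capturing that single defining ordering, not
digitized measurements. Depth attenuation is Beer–Lambert with
α(λ) = α₀·(585/λ)⁴, decreasing in wavelength, which reproduces the
in-depth red shift of absorbing media qualitatively.

Not emulated: realistic cardiac anatomy, light-sheet optics (stripes,
PSF), clearing chemistry, spatial intensity correlations beyond region
membership. Passing tests therefore demonstrate the *analysis* is
correct under the stated statistical structure; they do not validate the
biology or the optics of real acquisitions.

## Problem sizes used in tests and the acceptance script

Mixture recovery uses 50 histograms of 10⁵ samples (256 bins). The
oxidized-fraction and pseudo-kinetic experiments use 64×128×128 phantoms
(≈10⁵ VAR voxels) — large enough for the 0.002 % foot rule to engage and
for the per-heart min–max normalization to be stable. The pseudo-kinetic
cohort (5 groups × 6 hearts) uses built-in oxidized means
{730, 800, 860, 920, 1020} with 2 % inter-heart jitter: exact rank
recovery (Spearman ρ = 1) is only a meaningful property of the pipeline
when the built-in group differences exceed both the jitter of the group
means and the mixture fit's own uncertainty on overlapping components;
with gaps below ~30 units at 5 % jitter the ordering itself is not
identifiable by any estimator.

## Known limitations

- The two-Gaussian decomposition of heavily overlapping components is
  weakly identified on blurred group-average histograms; small VARs
  (≲3×10⁴ voxels) give noisy `median_right` estimates.
- `median_right = μ₂` uses the untruncated-Gaussian identity; for
  components pressed against the support edges the truncated median
  would differ slightly.
- The sham equivalent wedge assumes an approximately annular wall in
  each slice (radial extent from the wall's own voxels).
- MRI/ORI comparison takes scalar infarct volumes as input; image
  registration between modalities is out of scope, as are proprietary
  microscope formats.
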