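# Methods

## Measurement model

A surface-deposited circular DNA molecule stained at a fixed
dye-to-base-pair ratio is imaged as a diffraction-limited punctum whose
*integrated* fluorescence is proportional to its length:
`E[I] = c · size_bp`, with `c` (a.u./bp) depending on buffer, dye ratio
and exposure. The package never assumes a value for `c`; it is estimated
per condition by regressing known plasmid sizes on fitted population
mean intensities. Per-molecule intensity scatter is modelled as
multiplicative (a coefficient of variation), which matches the
observation that population SD grows with size while SD/mean stays
roughly constant.

Size conversion uses ordinary least squares of size (bp) on intensity
(a.u.). The reported ± error for a converted intensity is the half-width
of the **prediction interval for a new observation** at the curve's
confidence level (default 0.99), not the confidence band of the
regression mean: the quantity of interest is the size of one molecule or
population, and the per-molecule band is the wider, honest one. With
only three calibration points the interval has one residual degree of
freedom and is correspondingly wide; more reference sizes narrow it.

R² is always computed about the mean of the known sizes, including for
the through-origin fit. Uncentred R² for a zero-intercept model lives on
a different (inflated) scale and would make the free and coerced fits
incomparable; on the common scale, coercing the origin can only lower
R², which is the comparison users need when deciding whether the
intercept is physical.

## Pipeline stages and parameters

**QC** (automated surrogate for manual inspection): focus score =
variance of the Laplacian normalised by squared mean (brightness
invariant; 0 for constant rasters), plus the fraction of pixels at or
above a saturation level (default 65535, the 16-bit ceiling). Defaults
are permissive (`focus_min = 0`, `saturation_max = 1%`); a manual
exclusion list is available. Codifying the criterion makes runs
reproducible where a by-eye screen is not.

**Shading**: estimated retrospectively from the data (no flat-field
image is assumed): per-pixel median across fields — robust against
sparse bright puncta — then Gaussian smoothing with σ = field/24,
rescaled to mean 1. The σ trades punctum leakage against vignette
attenuation: heavy smoothing systematically underestimates vignette
depth (a Gaussian-on-Gaussian convolution shrinks amplitude by
σv²/(σv²+σs²)), and field/24 keeps that bias ≲1% while still erasing
diffraction-limited spots from a modest stack. Correction is
elementwise division. A retrospective estimate can only recover
illumination *relative to the field average*; the generator's vignette
is therefore normalised to mean 1 so corrected intensities are directly
comparable to ground truth.

**Denoising**: 3×3 median by default (`gaussian` and `none`
available). Masks are computed on the denoised image; intensities are
measured on the un-denoised corrected image so the filter cannot bias
the integrals.

**Segmentation** is the union of two masks:

- *edge mask*: Sobel gradient magnitude thresholded at median + 6 robust
  SDs (MAD-scaled; automatic, returns empty on constant or pure-noise
  input), closed with a 3×3 structure, hole-filled, then **eroded by
  2 px**. The erosion matters: the gradient halo of a bright punctum
  (shot noise scales with signal) extends well past the spot core, and
  without it neighbouring molecules merge at 2–3× the distance they
  should.
- *local mask*: pixel > moving-window mean + k·SD (window 31 px, k = 3),
  which recovers dim puncta on residual illumination gradients that a
  single global threshold misses.

After the union, components smaller than `min_area = 8 px` are removed
— the 3×3 median filter correlates noise over ~3 px, so spurious
above-threshold clumps reach several pixels, while a real
diffraction-limited spot (σ ≈ 1.5 px) covers ≥ ~15 px — and components
touching the image border are dropped (truncated integrals would bias
sizing low).

**Measurement**: each component is dilated by 3 px to recapture the PSF
tails the thresholds cut off (pixels of *other* components are never
annexed); `raw_integrated` is the pixel sum over that support. Local
background per pixel is the median of an annulus 2 px beyond the
support, 4 px wide, excluding all foreground;
`adjusted = raw − area · background`. This makes the measurement
invariant to additive offsets and linear in true intensity (both are
tested). Negative adjusted intensities are kept and excluded later by
histogram range, to avoid biasing the dim tail. Components with an
empty annulus are dropped and counted.

**Population fitting**: histogram the adjusted intensities (default 100
bins from 0), find peaks (local maxima after a 3-bin moving average,
prominence ≥ 5% of the maximum, ≥ 3 bins apart), seed a Gaussian per
peak from its interpolated FWHM (σ₀ = FWHM/2√(2 ln 2), µ₀ = peak
position, amplitude = peak height; a half-maximum crossing that runs off
the histogram edge raises an unresolved-peak error instead of a bad
fit), then least-squares fit of a Gaussian to the binned counts
restricted to µ₀ ± 2σ₀ (≥ 20 molecules required). The window isolates
each population: a second population outside the window moves the fitted
mean by < 1%. Fits are to binned counts; on clean data this is
equivalent to sample statistics (tested), and it is robust to the heavy
bright tail that unresolved molecule aggregates produce.

**Colocalization**: Pearson correlation over the molecule's mask dilated
by 1 px (configurable to exact mask) between the two corrected
channels; one-sided p-value via the t-transform, cross-checked against a
permutation null in the tests. An undefined correlation (constant
channel-2 patch = no dCas9 signal at all) is classified non-colocalized.
Thresholds (`PCC > 0.25`, `p < 0.05`) live in one config object.

**Background subtraction**: histograms must share bin edges; the
background counts are rescaled by the ratio of imaged fields
(fields are the sampling unit — deposition density, not molecule count,
is what the two samples share), subtracted binwise, and negative bins
clipped to zero with the clipped mass logged. The surviving fraction
(residual mass / target molecules) is the headline number; with two
independent draws of the same 10⁴-molecule population it stays below 2%,
which bounds the pipeline's false-discovery level.

**Population calling**: the binwise residual is realised as bin-centre
values and clustered with exact 1-D k-means — a dynamic program over
contiguous partitions of the sorted values (optimal 1-D clusters are
contiguous), O(k·n²), globally optimal, deterministic, no seed. Ties
break toward the earliest split. `k` is user-set (default 2);
clusters below `min_cluster_frac` are flagged as possibly spurious.
Cluster means are converted to bp through the condition-matched
calibration curve; using a curve across conditions triggers a warning
(cross-condition bias is on the order of 1 kbp).

Because the pipeline deliberately does no declumping, unresolved
overlapping molecules form a bright tail (e.g. two co-deposited monomers
measure as one dimer-intensity record, a monomer fused with a bright
background molecule lands beyond the dimer). In two-population analyses
of crowded samples the recommended practice — used in the package's own
end-to-end checks — is k = 3: the tail gets its own cluster and the
monomer/dimer split is assessed over the two genuine populations, the
same judgement applied to sparse trimer-range molecules in concatemer
analyses.

**qPCR arithmetic**: standard curve Ct = a·log10(copies) + b (slope
−3.32 at 100% efficiency); LoD gate excludes conditions whose Ct is not
strictly below the no-template control; mass = copies × size_bp ×
650 Da / N_A (650 g/mol per bp is the conventional average for dsDNA);
density per µm² × field area = expected molecules per image. The field
of view defaults to 1.5×10⁴ µm², inferred from the printed pair "one
vector per 15 µm²" ↔ "~1000 vectors per image"; it is configurable and
marked as inferred. Note the full chain copies → mass → mass fraction is
reported as-is so that internally inconsistent inputs are visible rather
than silently reconciled.

## The synthetic generator

`gen_field`/`gen_experiment` emulate: linear intensity-per-bp with
per-population CV (truncated at 0), isotropic Gaussian PSF rendered by
exact pixel integrals (error < 0.5% from 5σ window truncation), a
Gaussian vignette of configurable relative depth (mean-normalised, see
above), gain-scaled shot noise (`gain · Poisson(clean/gain)`, variance =
gain × signal, the pragmatic EMCCD approximation) plus additive Gaussian
read noise, channel-2 spots on a per-population fraction of molecules,
and uniformly placed unattached channel-2 spots modelling transiently
bound probe. Defaults: 512×512 px fields at 0.057 µm²/px (the inferred
1.5×10⁴ µm² field), σ_PSF = 1.5 px, 10 a.u./bp, background 200 a.u.,
read noise 10 a.u., gain factor 2, vignette depth 0.15.

Not emulated: optical aberrations and defocus, DNA conformation
(supercoiling, partial surface relaxation), photobleaching, chromatic
offset between channels, and structured (non-vignette) illumination.
Passing tests therefore demonstrate the *algorithmic* correctness and
statistical calibration of the pipeline under its stated model, not
robustness to those real-world effects; the condition-tagged calibration
and configurable thresholds are the knobs a real deployment would tune.
Molecules deposited closer than a few PSF widths are rendered truthfully
(overlapping) and flagged in the ground truth; the pipeline reports them
as single bright records by design.

## Numerical and degenerate-input choices

- Coordinates are 0-based (row, col), pixel centres at integers;
  sub-pixel truth positions are rendered via the PSF integral.
- Constant images: empty masks (not errors); focus score 0; QC fails an
  all-zero raster with a flag.
- Gaussian fit bounds keep µ inside the window and σ positive; failure
  to converge raises, never silently.
- `kmeans_1d` accepts a seed argument for interface symmetry; the exact
  solver ignores it.
- Residual realisation rounds binwise masses to the nearest integer.
- Histogram values outside range are counted and logged, not dropped
  silently.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
sized for laptop-scale runs: calibration uses 9 fields × ~120 molecules
(≥300 per plasmid), recovery checks use ~500 molecules over three
1280×1280 fields, subtraction statistics use 10⁴–3×10⁴-molecule
intensity tables, and the dCas9-gated two-sample experiment uses 25
target + 15 background fields at 60 molecules per field. These sizes are
the package's chosen defaults for its own verification; all scale up
linearly via the config objects.

## Known limitations

- No declumping/watershed: crowded depositions bias counts and create a
  bright artifact tail (mitigated by k = 3 calling, above).
- Three-point calibrations give very wide prediction intervals; the
  interval is honest, not a defect, but more reference sizes are better.
- The colocalization false-positive rate depends on the unattached-probe
  surface density and is sample-specific; the negative-control degree
  should always be measured alongside the target sample.
- Retrospective shading estimation needs several fields to be robust; a
  single field yields a smooth but noisier estimate.
- The k in k-means is user judgement, as is which clusters are genuine
  populations; the package reports cluster sizes and flags small ones
  rather than deciding.
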