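# puncta-sizer

Single-molecule detection and sizing of sparse circular DNA — plasmids,
episomal vectors, rAAV genomes and their concatemers — from two-channel
fluorescence microscopy images.

## The problem

Circular DNA species that make up a few percent of a heterogeneous DNA
sample (for example episomal rAAV vector genomes in DNA extracted from
transduced cells) are invisible to gels and hard to size in bulk. This
package implements a single-molecule alternative: surface-deposited DNA
is stained with the bis-intercalator YOYO-1 and imaged as
diffraction-limited puncta. Two physical facts carry the method:

1. **Intensity is linear in length.** The integrated YOYO-1 emission of a
   punctum is proportional to the molecule's size in base pairs, so a
   linear regression on reference plasmids of known size,

   `size_bp = a · I + b`,

   converts a background-adjusted integrated intensity `I` (a.u.) into a
   size with a prediction-interval error band. The calibration is
   condition-specific — buffer and dye ratio change the slope — so curves
   carry a condition tag.

2. **Sequence identity by dCas9 colocalization.** A nuclease-dead Cas9
   loaded with a target-specific guide and a fluorophore-tagged tracrRNA
   marks molecules carrying the target sequence in a second channel. A
   punctum is called colocalized when the pixelwise Pearson correlation
   between the two channels over its (1-px-dilated) mask satisfies
   `PCC > 0.25` with a one-sided `p < 0.05`
   (`t = r·√((n−2)/(1−r²))`, `n−2` df).

The analysis pipeline is: QC (focus/saturation) → retrospective shading
correction → median denoising → segmentation by the union of an
edge-based mask and a local mean + k·SD threshold → per-molecule
background-adjusted integrated intensities → FWHM-seeded Gaussian
population fits (`σ = FWHM / 2√(2 ln 2)`) → calibration regression. For
target-vs-background comparisons the background sample's intensity
histogram is rescaled (fields are the sampling unit) and subtracted
binwise, and populations in the residual — optionally gated to
dCas9-colocalized molecules — are identified by **exact** 1-D k-means
(dynamic programming over contiguous partitions of the sorted values,
globally optimal and seed-free) and mapped to base pairs through the
calibration curve.

A synthetic-field generator with per-molecule ground truth (linear
intensity model, Gaussian PSF, vignette shading, EMCCD-like gain-scaled
shot noise plus read noise, partial and false channel-2 occupancy) makes
every stage testable without microscope data. qPCR copy-number
arithmetic (standard curve, LoD gating, copies → mass → expected
molecules per field of view) is included for planning deposition
densities.

## Worked example

Calibrate on a simulated mixture of three reference plasmids (2686,
5562 and 12920 bp; ~120 molecules per 512×512 field over 9 fields), then
size an unknown intensity:

```python
import puncta_sizer as ps

plasmids = (2686, 5562, 12920)
mixture = [ps.PopulationSpec(size_bp=s, fraction=1/3, intensity_cv=0.06)
           for s in plasmids]
imaging = ps.ImagingConfig(seed=1)
fields, truth = ps.gen_experiment(mixture, imaging, n_fields=9,
                                  molecules_per_field=120, seed=1)

cfg = ps.RunConfig(seed=1, condition="TE_1to1_dye")
curve, fits, table = ps.calibrate_workflow(fields, plasmids, cfg)
print(f"size_bp = {curve.slope:.4f} * intensity + {curve.intercept:.1f}"
      f"  (R^2 = {curve.r_squared:.4f})")
for fit, size in zip(fits, plasmids):
    print(f"  {size:>6} bp plasmid: mean intensity {fit.mean:,.0f} a.u., "
          f"sized {fit.size_bp:,.0f} +/- {fit.size_error_bp:,.0f} bp (n={fit.n_molecules})")

est = ps.intensity_to_size(curve, 51810.0)
print(f"unknown molecule at 51,810 a.u. -> {est.size_bp:,.0f} +/- {est.error_bp:,.0f} bp")
```

prints

```
size_bp = 0.1003 * intensity + -21.5  (R^2 = 1.0000)
    2686 bp plasmid: mean intensity 26,761 a.u., sized 2,661 +/- 3,586 bp (n=305)
    5562 bp plasmid: mean intensity 56,037 a.u., sized 5,596 +/- 3,240 bp (n=317)
   12920 bp plasmid: mean intensity 128,988 a.u., sized 12,910 +/- 3,861 bp (n=279)
unknown molecule at 51,810 a.u. -> 5,173 +/- 3,270 bp
```

The slope recovers the generator's 10 a.u./bp (as 0.1003 bp per a.u.),
each population is sized to within ~1% of its true length, and the
± ranges are 99% prediction intervals — wide here because a three-point
regression has a single residual degree of freedom.

The same workflows are exposed on the command line:

```bash
puncta-sizer simulate  --config cfg.json --out data/
puncta-sizer calibrate --images data/fields --sizes 2686,5562,12920 --out calib/
puncta-sizer analyze   --target moi10k/ --background moi0/ \
                       --curve calib/calibration.json --coloc --out report/
```

Every run echoes its full configuration into the output directory.

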