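# Methods

This note documents the models, parameter choices and numerical decisions
behind `bruisebands`, and what the synthetic experiments can and cannot
show about real fruit.

## Synthetic scene model

A scene is one apple on a dark background (reflectance 0.03), imaged by a
line-scan system over a uniform spectral grid anchored at 553.9 nm with
5 nm spacing, covering 398.9–1003.9 nm (122 bands). The anchor makes
553.9 nm an exact band center; 424.5, 774.2 and 812.5 nm fall within half
a grid step of a band center, so all four key wavebands are addressable.

**Sound peel reflectance** is a smooth sigmoid ramp (0.30 in the blue to
0.72 in the NIR) minus four Gaussian absorption features: carotenoids
(500 nm, σ 35, depth 0.12), chlorophyll (680 nm, σ 12, depth 0.10), sugar
(820 nm, σ 18, depth 0.05) and water (960 nm, σ 55, depth 0.15).

**Pixel-to-pixel and apple-to-apple variability** is carried by four
orthonormal latent spectral components (Gram–Schmidt on a chlorophyll-like
dip, a red/NIR tilt, a broad green hump and a slow cosine). Each component
receives a smooth per-pixel weight field (Gaussian-filtered white noise,
σ = 3 px) with standard deviations (0.18, 0.06, 0.015, 0.008), plus a
per-apple offset with standard deviations (0.09, 0.08, 0.015, 0.008)
representing pigment differences between fruit. A multiplicative radial
shading profile, 1 − 0.55·(r/R)², models the spherical brightness falloff
of the fruit; it dominates the first principal component of any scene.
Additive reflectance texture noise has σ = 0.004.

**Bruises** multiply the sound reflectance by 1 − a(x, y)·d(λ), where
a is a soft-edged elliptical footprint (semi-axes ≈ 9 × 7 px, placed at
0.45 R from the disk center) and d(λ) combines a browning term
(Gaussian at 554 nm, σ 30, plus a 1.3× stronger Gaussian at 424.5 nm,
σ 34 — brown pigment absorbs increasingly toward shorter wavelengths) and
an NIR water term (a sigmoid plateau rising at 745 nm plus Gaussians at
774.2 and 812.5 nm). Peak depressions grow linearly with impact energy E:
browning 0.12 + 0.22·E, NIR 0.10 + 0.08·E, with E = 0.33, 0.66, 1.11 J
for the low/medium/high groups and an 8% per-apple amplitude jitter.

The pendulum utility computes E = m_b·g·h + m_r·g·h/2 with
h = L(1 − cos θ). With the nominal 67 g ball and 68 cm, 663 g rod this
gives 0.950/0.564/0.290 J at 50/38/27°, about 15% below the nominal group
energies above; the measurement convention behind the nominal values is
not recoverable, so the generator keeps the nominal energies as the
severity parameterization and the utility reports the formula value.

**Camera.** Throughput (QE × halogen illuminant × optics) is a two-sided
Gaussian in wavelength peaking at 560 nm (88,000 DN/s/row), σ = 130 nm on
the blue side and 300 nm on the red side, so the 424.5 nm band sees about
a third of the peak rate and saturates last. The sensor model is 14-bit
(full scale 16,383 DN) with a 100 DN dark offset, Poisson shot noise at
4 electrons/DN conversion gain, 2 DN Gaussian read noise, and
clip-and-round quantization. Full-resolution cubes are acquired at 0.17 s
exposure (the single-row 90%-of-full-scale exposure at 553.9 nm); white
(Spectralon, reflectance 0.99) and dark references are means of 10
simulated lines.

### Generator calibration

The free parameters above were calibrated once, as a package design step,
against the phenomenology the analysis assumes: the bruise contrast
concentrates in PC3 of a single scene's apple-pixel PCA (shading in PC1,
pigment variability in PC2); the first four components of the pooled
extracted spectra carry ≥ 99.2% of variance; with three selected wavebands
all four classifiers exceed 94% held-out accuracy while the quadratic
classifiers (QDA, RBF-SVM) reach 95% with two bands and the linear ones
lag — the class clouds are multiplicatively shaded cones with
severity-dependent elongation, which a linear boundary cuts less well.
The per-apple latent offsets are the load-bearing ingredient: without
them, two bands (one bruise-sensitive, one reference) separate the classes
almost perfectly and a third band adds nothing measurable.

## Calibration and pixel extraction

Flat-field conversion is I_R = (I_r − I_d)/(I_w − I_d) with single
reference frames broadcast along the scan axis. Entries with
I_w ≤ I_d are flagged invalid and set to NaN, never clipped; values above
1 (possible over the references' noise floor) are kept. ENVI raster I/O
supports BIL/BSQ/BIP interleaves with an ASCII header carrying the
wavelength list; a missing wavelength field is an error.

Labeled pixels are selected per bruised apple from the PC3 score image
(PC4 as fallback if PC3 yields no usable split), automating the visual
identification of clearly bruised and clearly sound regions:

* **Constrained Otsu.** The threshold maximizes between-class variance,
  restricted to thresholds that leave at most 12% of apple pixels on the
  minority side. Plain Otsu tends to bisect the dominant sound mode when
  the bruise occupies only a few percent of the disk; the constraint keeps
  the split on the bruise tail. The minority side is labeled bruise.
* **Margin.** Pixels within 1.05 within-apple score standard deviations
  of the threshold are discarded from both classes — the analogue of
  picking only clearly observable regions. On high-impact scenes the
  resulting bruise-label purity against ground truth is typically ≥ 0.95
  (audited and reported by `analysis/02_extract_dataset.py`).

Apples from the sound control group contribute sound pixels only (their
status is known from the experimental design). Up to 60 pixels per class
per apple enter the pooled dataset (≈ 2,500 spectra for 24 apples), read
from the calibrated reflectance cube at the selected coordinates, then
split 70/30 stratified by class.

## Band selection

Candidates are the peaks and valleys of the first four pooled-PCA
loadings with prominence ≥ 10% of each loading's maximum absolute value
(typically ~18 candidates, always including grid points at the four key
wavebands). SFS greedily adds the candidate maximizing mean 5-fold CV
accuracy on the training partition; ties break toward the lower
wavelength; the test partition is scored once per step for reporting and
never used for selection. Classifier settings: LDA (SVD solver), QDA with
covariance regularization (1e−3) applied only if a class covariance is
singular, linear SVM (C = 1) and RBF SVM (C = 1, kernel width from the
median pairwise-distance heuristic), the SVMs behind a training-statistics
standardizer; the discriminant analyses run on raw reflectance (they are
affine-equivariant).

The optimal band count is the smallest k at which every classifier's CV
accuracy meets a 0.94 floor and gains less than 1 percentage point from
k to k+1; if no k qualifies, k_max is returned with a warning. On the
default cohort the rule returns 3. The rule is knowingly sensitive to its
ε when the curves saturate between k = 2 and 3: on some replicate cohorts
every classifier already clears both conditions at k = 2 and the rule
returns 2. Likewise the 2-band accuracies of the quadratic classifiers
fluctuate by ±2–3 points across replicate cohorts.

## Resolution optimization

For a band of contiguous detector rows, the predicted white-reference
signal is exposure × Σ rows throughput × 0.99, capped at full scale with a
saturation flag. The reference band (the selected band nearest 553.9 nm)
fixes the exposure by demanding 90% of full scale; both remaining bands
are widened — smallest odd symmetric row count — until they reach a target
fraction (25, 50 or 90%). A grid cell is skipped when the single-row
signal already exceeds its target, the target is unreachable inside the
axis, or the solved ROI would overshoot the white reference by more than
15%. Reference widths of 1, 3, 5 and 9 rows give four exposure levels
(≈ 0.17 to 0.019 s); typically 5–11 combinations survive per key-waveband
triple.

Each combination is emulated by re-acquiring every scene from its
noiseless reflectance truth at the combination's exposure: per output
band, the shot-noise-limited, read-noise-added, clipped row-block sum,
flat-fielded against references acquired the same way. (Rescaling the
stored 0.17 s raw cube would scale its noise linearly and erase the
signal-to-noise trade-off the optimization is about.) The spec-style
`bin_cube` — raw row sums / throughput-weighted reflectance means — exists
alongside and is oracle-tested. Classifiers are retrained on the binned
training spectra; maps are produced for the training cohort; combinations
are ranked lexicographically by apple-level accuracy, then fewest
false-positive pixels after morphology, then shortest exposure. All four
classifiers' combinations compete jointly, and the overall winner is
evaluated on a freshly generated cohort — ranking within a single fixed
classifier proved fragile when its selected triple happened to generalize
poorly to unseen apples.

## Classification maps

Background is removed by an Otsu threshold on the reference band, keeping
the largest connected component with holes filled. The trained model
labels apple pixels only. Maps are cleaned by binary opening then closing
with 3 × 3 disk structuring elements (configurable); an apple is declared
bruised when its largest connected positive component reaches 10 pixels
(≈ 0.4% of the disk at the default scale). Overlays paint positives pure
red (255, 0, 0) on the 0–254 grayscale reference band so the map
round-trips exactly from the overlay.

## Problem sizes and determinism

Default scenes are 80 × 80 px with a 30 px apple radius and 122 bands;
cohorts are 24 apples (6 per group); datasets ≈ 2,500 spectra. At this
scale the full study (cohort → SFS → resolution optimization → held-out
evaluation) runs in about a minute on one CPU. Every stochastic step —
scene synthesis, pixel subsampling, splits, CV folds, re-acquisition
noise — descends from a single integer seed, and identical seeds
reproduce cubes bit for bit.

## What the synthetic experiments do not show

The generator plants exactly the spectral structure the selection stage
looks for, so waveband recovery here validates the machinery, not the
biology; real bruise spectra vary with cultivar, bruise age and
temperature. Specular glints, stem/calyx regions (a known source of false
positives), camera smile/keystone, translation-stage jitter and multi-view
coverage of the fruit surface are not modelled. Absolute accuracies on
this synthetic cohort should be read as calibration targets of the
generator, not as predictions for any physical system. Because the bruise
sits on the brightly lit crown of the simulated sphere while sound pixels
span the whole disk, comparisons of bruise versus sound spectra are made
on illumination-normalized spectra (ratio to the neutral 610–660 nm
window); raw-region means would confound browning with shading.
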