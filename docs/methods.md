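# Methods

`hsifob` implements per-pixel discrimination of high quantitative fecal
occult blood (FIT ≥ 400 ng/mL) on stool surfaces from 121-band
hyperspectral reflectance cubes (400–1000 nm, 5 nm steps), together with
the diagnostic-accuracy statistics used to evaluate such a discriminator
and a seeded phantom simulator that provides ground-truth fixtures. This
note records the model, the parameter choices that matter, and the design
decisions taken where the procedure was genuinely open.

## Reflectance calibration

Raw counts are converted per pixel and band as `R = (I − D) / (W − D)`
with a white reference `W` and an optional dark frame `D` (default
all-zeros, which degenerates to the plain white-reference ratio). `W − D`
must be strictly positive everywhere; reflectance is clipped to
`[0, clip_max]` (default 2.0 — specular glints can exceed 1) and the clip
count is logged rather than silently discarded. Spatial indexing is
0-based, row-major, origin top-left; region masks share this convention.
ENVI (`.hdr` text header + raw binary, BSQ/BIL/BIP) is the canonical
on-disk dialect; band-stacked TIFF with a sidecar wavelength header is
also supported.

## Spectral preprocessing

The discrimination chain applies, in order: Savitzky–Golay smoothing,
per-spectrum normalization, multiplicative scatter correction (MSC), and
a Savitzky–Golay second derivative with physical 5 nm spacing. Each step
is deterministic and applies identically to a spectrum or per pixel of a
cube.

* **Filter windows.** Smoothing uses window 5 / order 2 and the second
  derivative window 7 / order 3 by default. At 5 nm sampling these spans
  (25 nm and 35 nm) are deliberately narrower than the ~20–25 nm full
  width of the hemoglobin Q bands: windows in the 55–75 nm range smear
  that structure into 600–660 nm side lobes and defeat the purpose of
  band selection. All four values are configuration-exposed.
* **Normalization** defaults to SNV (mean 0, SD 1 per spectrum), the
  usual companion of MSC; unit-vector and min–max scaling are available.
  SNV exactly cancels per-pixel affine scatter (gain and offset).
* **MSC** regresses each spectrum on a reference over all bands
  (`s ≈ a + b·ref`) and returns `(s − a)/b`. The reference defaults to
  the mean partially-preprocessed training spectrum and is frozen inside
  the saved model, so inference needs no training data. A slope below
  1e-12 is a degenerate scatter fit and raises.
* **Step order** follows the fixed default `smooth → normalize → msc →
  second_derivative`; any other order must be configured explicitly.
* "Second derivative" is the standard chemometric reading adopted here;
  derivative spacing is in nm so the output has physical units.

## Discriminant model

Training operates on one ROI-mean spectrum per sampling area — labels
(FIT ≥ cutoff, boundary inclusive) exist only per area — while inference
scores every pixel.

* **Feature standardization.** Preprocessed second-derivative features
  are of order 1e-3; the SVM margin is only meaningful after per-band
  z-scoring. The standardizer is fitted on the training matrix and stored
  in the model.
* **Kernel.** The default is an RBF support-vector machine (C = 1,
  `gamma="scale"`, class-balanced weights). The bounded positive region
  of the RBF decision function is what lets the discriminator *reject*
  spectra far outside the training gamut: colored liquids such as tomato
  juice have large second-derivative magnitude in exactly the Q-band
  window, and an unbounded linear margin necessarily assigns such
  out-of-gamut points to one side — empirically the positive one. With
  RBF they decay to the (negative) intercept. The trade-off is that
  hemoglobin on backgrounds utterly unlike the training matrix is not
  extrapolated either; a linear kernel remains one flag away.
* **Band selection** is sequential backward elimination (SBE) wrapped
  around stratified 5-fold cross-validated accuracy. The fold assignment
  is fixed once per run (seeded) so criterion comparisons between
  candidate subsets are paired and the whole procedure is deterministic.
  Each step removes the band whose removal maximizes the criterion (ties
  remove the lowest index); elimination stops at `min_bands` or when the
  best candidate falls more than `tolerance` (default 0.01) below the
  best criterion seen. The full removal history is stored in the model.
  Elimination may start from a coarse sub-grid of bands (`band_step`),
  which preserves the wavelength axis while keeping the O(B²) wrapper
  search tractable; the high-level workflow uses every 3rd band.
* **Decision threshold.** A margin threshold of 0 is the field default on
  discriminant images, but single pixels are far noisier than the
  area-mean spectra the SVM trains on, so the training workflow
  calibrates the threshold instead: each training area's judging
  statistic (its k-th largest pixel score, k = 5% of the area) is
  computed, and the threshold maximizing Youden's J against the FIT
  labels is chosen (median of all near-optimal candidates, which is much
  more stable on ~100 areas than the raw argmax).

## Decision rules

* An **area** is positive when ≥ 5% of its pixels exceed the threshold
  (`min_positive_fraction`, configurable); a small nonzero fraction
  rejects isolated noise pixels while staying close to "any detected
  region on the area".
* A whole capture's **pattern** over the stool mask is whole-positive at
  positive fraction ≥ 0.80, whole-negative at ≤ 0.01, else
  partial-positive. "Entire stool" and "entirely negative" have no pixel
  definition in the underlying protocol; both cut points are exposed.
* The **validation sampling scheme** draws five non-overlapping
  fixed-radius discs per case according to the pattern: 5 positive / 3
  positive + 2 negative / 5 negative, seeded-randomly placed on eligible
  pixels. For P whole-positive, Q partial and R whole-negative cases this
  yields exactly 5(P+Q+R) areas of which 5P + 3Q are algorithm-positive.
* A **case** is positive when any of its areas is positive, on either
  channel (algorithm call, or FIT ≥ cutoff). The any-rule matches
  screening practice; the underlying study never states its per-case
  aggregation.

## Diagnostic statistics

Sensitivity, specificity, accuracy, PPV and NPV are computed from the
2×2 concordance of algorithm calls against dichotomized FIT, each with an
exact Clopper–Pearson 95% interval (beta-quantile endpoints; lower bound
0 at k = 0, upper bound 1 at k = n). Zero-denominator metrics are
reported as undefined with a reason, never as 0 or 1. Group comparisons
use the continuity-corrected Pearson chi-square, switching to the Fisher
exact test when any expected cell is below 5 (`method="auto"`); the
uncorrected chi-square is available by flag. Report output rounds
half-up to one decimal in percent; internal values keep full precision.

## Phantom simulator

No clinical stool hyperspectral images are publicly deposited, so every
pipeline stage is exercised on synthetic phantoms with known ground
truth:

* **Optics.** Per pixel, `R(λ) = R_bg(λ) · 10^(−load·ε(λ))` — Beer–Lambert
  attenuation of a smooth diffuse background by surface hemoglobin.
  The built-in extinction table is *synthetic*: a parametric sum of
  Gaussian bands with the literature peak positions (oxy Soret ~415 nm,
  Q bands ~540/577 nm; deoxy ~430/555/760 nm) in arbitrary consistent
  units; only that peak structure is relied upon. Subsurface blood is
  attenuated 100× (configurable), emulating blood inside the stool bulk
  that the camera cannot see, while the truth map keeps its nominal
  load.
* **Backgrounds** are smooth parametric curves: brown stool (sigmoidal
  rise toward the NIR), plus the verification liquids (milk high/flat,
  water moderate, tea/coffee low with slope, tomato juice a single
  red-shifted step — colored, but without the Q-band double dip).
* **Per-capture background variation** (default 0.15): a random gain
  plus a broad (≥ 60 nm) Gaussian bump field in log-reflectance. Stool
  color and albedo differ between patients; without this variation a
  per-spectrum-normalized global level becomes an artificial proxy for
  total hemoglobin absorption, and band selection has no reason to
  prefer the hemoglobin bands.
* **Noise model.** Halogen-like illumination (weak in the blue — the
  Soret region has realistically poor SNR on dark stool), white level
  20000 counts, additive Gaussian sensor noise SD 0.5 counts (a
  well-exposed staring hyperspectral camera, per-pixel SNR on the order
  of 10² at mid-VIS), per-pixel lognormal scatter gain SD 0.10 with a
  small additive offset. All randomness derives from the spec seed.
* **FIT values** per area are `gain · (mean load) · lognormal noise`
  with mean-one noise of CV 0.15 (analyzer repeatability plus the
  mismatch between the scraped spot and the imaged surface) and gain
  2000 ng/mL per unit load, i.e. the 400 ng/mL cutoff corresponds to
  load 0.2.
* **Study generation.** Training-style batches place blood discs under
  roughly half of the sampled areas with loads drawn from a lognormal
  (σ = 0.9) calibrated so ~35% of areas are FIT-positive — matching the
  construction batch's class balance, with genuinely ambiguous areas
  near the cutoff. Validation-style batches follow a pattern composition
  (whole-positive: blood blanketing the stool; partial: one blood patch;
  whole-negative: none).

### What the phantoms do and do not show

The phantoms reproduce the optical structure the method assumes — narrow
hemoglobin absorption features on smooth, varying diffuse backgrounds,
scatter, sensor noise, noisy FIT reference values — and therefore support
parameter-recovery, specificity and bookkeeping tests. They do not
reproduce stool texture, moisture glints, partial occlusion, spatially
correlated noise, or the real (unpublished) spectral contrast between
stool matrix and occult blood at 400 ng/mL, so passing tests demonstrate
correctness of the pipeline under its stated model, not clinical
performance. The end-to-end accuracy check deliberately evaluates on the
training study itself, mirroring the construction-phase protocol whose
published concordance is likewise resubstitution; held-out phantom
studies give similar but more seed-variable numbers.

## Problem sizes and numerical choices

Phantom studies in the test suite and acceptance script use 40–50 cases
of 48×48-pixel cubes with two training areas per case, chosen as the
smallest sizes at which class balance, wrapper selection and the decision
rules behave as at full scale. Elimination starts from every 3rd band
(41 bands) with `min_bands = 6`. Degenerate inputs raise rather than
propagate: empty masks, zero-variance spectra under SNV, constant MSC
references, white ≤ dark at any pixel-band (the first offending index is
named), single-class training sets. Model files are JSON with a SHA-256
integrity digest; any byte-level tampering or version mismatch is
detected at load.

## Known limitations

* Spectra-only: no spatial regularization or texture models; discriminant
  images are per-pixel.
* The RBF discriminator does not extrapolate to backgrounds far outside
  its training gamut (by design, see above).
* Pattern cut points (0.80 / 0.01) and the area rule (5%) are defensible
  defaults, not estimates from data.
* The synthetic extinction table is not suitable for quantitative
  absorption work — only its peak structure is contractual.
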