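# hsifob — hyperspectral detection of fecal occult blood

Colorectal-cancer screening relies on the fecal immunochemical test
(FIT), which quantifies hemoglobin scraped from a stool sample in ng/mL.
`hsifob` implements an imaging alternative for the *high*-concentration
regime: given a 121-band hyperspectral reflectance cube (400–1000 nm at
5 nm steps) of a stool surface, it classifies every pixel as
high-occult-blood (FIT ≥ 400 ng/mL) or not, by exploiting hemoglobin's
absorption signature — the Soret band near 415 nm and the Q bands near
540 and 577 nm — rather than visible color. The package is aimed at
researchers prototyping such discriminators and at anyone who needs the
accompanying diagnostic-accuracy statistics with exact intervals.

## What it computes

**Pipeline.** Raw counts are calibrated against a white (and optional
dark) reference, `R = (I − D)/(W − D)`. Spectra are preprocessed by
Savitzky–Golay smoothing, SNV normalization, multiplicative scatter
correction against a stored reference, and a Savitzky–Golay second
derivative (5 nm spacing). A support-vector machine (RBF by default),
trained on one ROI-mean spectrum per sampling area with labels
`FIT ≥ cutoff`, is wrapped in sequential backward elimination: bands are
removed greedily while a seeded, stratified 5-fold cross-validated
accuracy criterion holds up. Discriminant images threshold the per-pixel
margin score; an area is positive when ≥ 5% of its pixels are, a stool
is whole-positive / partial-positive / whole-negative by the extent of
positive area, and a case is positive when any of its areas is.

**Statistics.** From the 2×2 concordance of algorithm calls against
dichotomized FIT: sensitivity, specificity, accuracy, PPV and NPV, each
with an exact Clopper–Pearson 95% CI; Pearson chi-square (with
continuity correction) or Fisher exact group comparisons; per-lesion
detection grids across FIT cutoffs.

**Phantoms.** A seeded simulator renders stool- and liquid-background
cubes with Beer–Lambert hemoglobin absorption, per-capture background
variation, scatter and sensor noise, plus FIT values tied to the true
hemoglobin load — so the whole pipeline is testable with known ground
truth. See `docs/methods.md` for the model and all defaults.

## Worked example

The `hsifob` console script mirrors the two study phases. A complete
session on a simulated 20-case fixture:

```text
$ hsifob simulate --n-cases 20 --seed 7 --out fixture
wrote 20 cases to fixture

$ hsifob train --fixture fixture --min-bands 6 --band-step 3 --seed 7 --out model
selected 6 bands, CV accuracy 0.925

$ hsifob calibrate --cubes fixture/case003.dat --white fixture/case003_white.dat --out refl
fixture/case003.dat -> refl/case003_refl.dat (clipped 0)

$ hsifob classify --model model/model.json --cubes refl/case003_refl.dat \
    --stool-masks fixture/case003_stool.png --out cls
{
  "case003_refl": {
    "pattern": "partial_positive",
    "positive_fraction": 0.22017543859649122
  }
}
```

`train` reports the cross-validated accuracy of the final band subset
(0.925 here: the wrapper kept 6 of 121 bands). `classify` prints the
pattern call per capture — this stool is partial-positive, with 22% of
its surface flagged — and writes score maps, positive-pixel masks and
the five validation areas per case that the pattern rule prescribes.

`evaluate` turns calls + FIT values (or a pre-built 2×2) into the
accuracy report. Feeding it the validation-batch concordance counts of a
published 250-area study:

```text
$ hsifob evaluate --table 45 14 9 182
2x2: tp=45 fp=14 fn=9 tn=182
per area: sensitivity: 83.3% [95% CI: 70.7-92.1], specificity: 92.9% [95% CI: 88.3-96.0],
accuracy: 90.8% [95% CI: 86.5-94.1], ppv: 76.3% [95% CI: 63.4-86.4], npv: 95.3% [95% CI: 91.2-97.8]
```

Reading: of 54 truly high-FIT areas the algorithm found 45 (83.3%), and
an algorithm-negative call was right 95.3% of the time. The same flow is
available as a library:

```python
import hsifob as h

study = h.generate_study(n_cases=50, areas_per_case=2, seed=101)
model = h.train_on_study(study, seed=101)          # SBE + threshold calibration
table, metrics = h.evaluate_per_area(model, study)
print(model.selected_wavelengths)                  # [ 415. 520. 565. 580. 985. 1000.]
print(metrics.sensitivity.value, metrics.specificity.value)  # 0.97 0.99
```

Note the selected bands: the Soret region (415 nm) and the Q-band window
(520–580 nm) — the wrapper finds hemoglobin's absorption features
without being told where they are.

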