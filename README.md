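# zot — adaptive tumour/peritumour transition-zone analysis

Radiomics studies routinely analyse not just the tumour core but the
*peritumour* — the inflamed tissue immediately around it, where changes
start earliest.  The standard way to delimit that region is the fixed-radius
tumour rim (**tRIM**): dilate the tumour mask by one radius, erode it by
another, subtract.  The rim is chosen a priori, ignores the image entirely,
and across small concavities it bridges the anatomy and sweeps in adjacent
structures of a different nature.

`zot` implements an *adaptive* alternative: the **zone of transition
(ZoT)**, an annular region found by analysing how the image gradient decays
along the tumour border's normals.  For every border pixel a thin stripe is
laid across the border; the gradient-magnitude profile along it is
bell-shaped with its maximum at the edge, and the transition ends on each
side either at a structural local minimum (a valley before an adjacent
structure) or at the corner of the descending, L-curve-like branch.  The
per-stripe transition segments are accumulated into a sparse mask,
thickened, converted to a local-occupancy density map and segmented with
the Chan–Vese active contour, giving the outer and inner ZoT borders.

The package also provides everything needed to use the regions in
predictive modelling, and synthetic lesion phantoms to validate all of it
without clinical data:

- `zot.phantom` — disk-like nodules with shaded (ramped) borders and larger
  jagged lesions with concavities and adjacent bright confounders, with
  known ground-truth transition bands; Gaussian labelled cohorts for the
  machine-learning layer.
- `zot.imaging` — Sobel gradient magnitude, morphological border
  extraction with outward normals, smoothing-spline / Lanczos sub-pixel
  resampling.
- `zot.detect` — the four-step ZoT detector (`ZoTDetector`).
- `zot.trim` — the tRIM baseline and best-Dice-frequency radius matching.
- `zot.features` — twelve first-order descriptors (entropy, mean, SD,
  median, MAD, skewness, kurtosis, uniformity, IQR, CV and last-decile
  mean/median), local parametric maps, volume features, the signed relative
  change RCS = |f_A − f_V| / |mean(f_A, f_V)| · sgn(f_A − f_V) between
  contrast phases, and the 762 / 132 / 120-feature study pools.
- `zot.protocol`, `zot.studies` — sklearn-style estimators and drivers for
  the study protocols: quartile scaling + standardisation, prior-weighted
  LASSO screening, exhaustive quadruple search with a |ρ| ≥ 0.3 correlation
  filter and Holm–Bonferroni Wilcoxon significance, KDE + Latin-hypercube
  oversampling, SVM-margin stratified splitting, 100×3-fold CV SVM training
  with overfitting-aware model selection, a univariate screen for small
  cohorts, and clinical metrics (SN, SP, ACC, NPV, PPV, informedness
  I = SN + SP − 1 at the Youden cutoff, diagnostic odds ratio, AUC).

## Worked example

Generate a phantom nodule (12 mm radius, 4 mm transition band, 5% noise),
detect its ZoT, build the matched 6/3 mm rim, and score both against the
known band:

```bash
zot phantom --preset hcc-disk --seed 1 --out-dir demo/ph
zot detect  --image demo/ph/slice_phase0.tif --mask demo/ph/tumour_mask.png \
            --out-mask demo/zot.png --out-contours demo/zot.json
zot trim    --mask demo/ph/tumour_mask.png --outer-mm 6 --inner-mm 3 --out demo/trim.png
zot evaluate --pred demo/zot.png  --truth demo/ph/truth_band.png
zot evaluate --pred demo/trim.png --truth demo/ph/truth_band.png
```

prints

```
ZoT area: 671 px
tRIM area: 728 px
{"dice": 0.6179196704428425}
{"dice": 0.5836575875486382}
```

671 px over a border of ~75 px is a mean radial width of ≈ 8–9 mm — the
gradient support of a 4 mm intensity ramp seen through a 3×3 derivative
kernel — and the adaptive annulus overlaps the true band slightly better
than the fixed-radius rim even on this ideally circular nodule (the rim's
worst cases are jagged lesions, where the adaptive region also keeps
adjacent bright structures out).

The univariate study driver works on any labelled feature table:

```python
from zot.phantom import make_labeled_cohort
from zot.studies import run_univariate_study

table = make_labeled_cohort(18, 28, effect_size=[2.5, 0, 0, 0, 0], n_features=5, seed=2)
res = run_univariate_study(table)
print(res.feature, res.metrics.printed())
# f000 {'SN': 100, 'SP': 82, 'ACC': 89, 'NPV': 100, 'PPV': 78, 'I': 0.82, 'DOR': inf}
```

meaning the planted feature is selected after Holm-corrected Wilcoxon
screening and, at its Youden cutoff, separates the 18 positives from the 28
negatives with sensitivity 100%, specificity 82% and informedness 0.82.

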