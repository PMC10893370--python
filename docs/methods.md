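# Methods

## The detection model

The zone of transition (ZoT) is modelled as an annular region straddling
the visible tumour border, in which image intensity ramps from the tumour
core level to the surrounding parenchyma.  The detector assumes:

- a single, closed tumour ROI per call (multi-lesion slices are split
  upstream);
- isotropic pixel spacing (anisotropic inputs must be resampled first);
- the gradient-magnitude profile across the border is bell-shaped with its
  maximum at (or near) the border — contrast may vary along the border, but
  each local crossing has one dominant edge;
- the tissues on either side are either homogeneous (the profile decays
  into a noise floor, and the transition end is a *corner*, a sudden change
  of slope) or contain a nearby distinct structure (the profile rises again
  and the transition end is the *valley* between the two bells).

The four pipeline steps: (1) morphological border extraction (ROI minus
its 3×3-square erosion) and Sobel gradient magnitude; (2) per border pixel,
three 2-px-wide stripes (along the outward normal and at ±45°, to cope with
the digital staircase of the border), each averaged to a 1-px profile,
resampled at a 0.1-pixel step, peak-aligned, and analysed for its two
transition extents; (3) rasterisation of the per-stripe transition segments
onto the 0.1-step sub-pixel canvas and thickening by a 9-sample square
dilation; (4) a 9-sample local-occupancy density map of the thickened mask,
segmented by the Chan–Vese two-phase active contour, the result rescaled to
the original resolution.  The outer contour of the largest segmented
component and the contour of its enclosed hole are the ZoT borders; a
missing hole (degenerate small lesions) is synthesised by eroding the
region's intersection with the ROI, which guarantees annularity.

Normals are estimated from the smoothed signed distance transform of the
ROI and quantised to the 8 compass directions, which is what stripe
placement on a digital border supports; the ±45° companions cover the
quantisation error.

### Sub-pixel canvas

Steps 3–4 run on the same 0.1-step grid as the resampled profiles, and only
the final annulus is brought back to image resolution.  All sample-quoted
sizes (the 9-sample thickening SE, the 9-sample density window) are
therefore 0.9 original pixels.  This is what makes the method's spatial
resolution commensurate with the sub-pixel profile analysis: run at native
resolution the same morphology would add ≥ 8 px of width to every annulus
and no 4 mm transition band could ever be recovered.

### Transition-extent rules

- **Structural-minimum gate.**  A local minimum of the smoothed profile
  counts as a transition end only if its prominence exceeds
  `min_prominence_frac` (default 0.3) of the analysed bell's height.
  Interpolation (Lanczos/spline) ringing and noise produce shallow minima
  just past every bell; treating those as structure would widen the annulus
  by 1–2 px per side.  Genuine valleys before an adjacent structure are far
  more prominent than the gate.
- **Corner fallback.**  With no qualifying minimum, the extent is the
  L-curve corner of the branch's monotone envelope (running minimum):
  the point of maximal discrete Menger curvature on the unit-normalised
  curve, found by a coarse-to-fine triangle test.  Inside the detector the
  finest triangle leg is floored at n/20 samples so sub-sample ripple
  cannot attract the refinement; the public `lcurve_corner` defaults to a
  1-sample leg, where it coincides with the brute-force curvature maximiser
  on clean curves.
- **Peak alignment.**  Displacements of the profile maximum from the border
  pixel up to `shift_cap_px` (3 px) are compensated by re-anchoring the
  segment on the border, keeping the manual segmentation as the reference.
  A maximum further away belongs to a different structure (e.g. a brighter
  adjacent edge); the analysis then falls back to the local maximum within
  the cap window and flags the stripe.  Without this fallback an adjacent
  high-contrast structure hijacks the profile and its own transition is
  rasterised instead of the tumour's.
- **Featureless sides.**  A side with neither minimum nor corner carries no
  localisable transition; the stripe is dropped from the union unless the
  profile simply ran off the image, in which case the full branch is kept
  and the extent marked truncated.

### Profile smoothing

Profiles are resampled with a cubic smoothing spline.  The penalty is a
small fixed value (λ = 0.05) frozen on phantom pilots: heavier smoothing
(including the per-profile GCV choice, available via `lam=None`) visibly
widens the gradient bell and with it the detected annulus, while the
structural-minimum gate already supplies the noise robustness smoothing
would otherwise buy.  For a fixed penalty the spline is linear in the data,
so the detector resamples all profiles of a slice in one matrix product.

### Frozen segmentation parameters

The source method fixes no Chan–Vese parameters, so they are part of this
package's configuration, chosen once on disk phantoms and frozen:
contour-length weight μ = 0.1; foreground data-fidelity weight λ₁ = 3
against λ₂ = 1, which places the segmentation threshold near the
high-occupancy consensus of the stripe density map (the annulus follows
where most stripes agree, not the union fringe); 200 iterations; the active
contour runs on a 2×-decimated copy of the density map (the map itself and
the morphology stay at the full sub-pixel grid).  On the pilot (10 disk
phantoms, 4 mm band, noise 5% of contrast) the frozen configuration gives a
median Dice of 0.60 against the true band and a width-monotonicity Spearman
ρ of 0.98 across band widths 2–6 mm.

## The fixed-radius rim

`make_trim` is the literature baseline: dilation minus erosion of the ROI
with *disk* structuring elements of the mm radii (a disk matches a metric
radius; the source texts leave the SE shape open).  `match_radii`
operationalises "the pair for which the two regions most frequently match"
as best-Dice frequency: the winning pair attains the best per-slice Dice on
the most slices, ties broken by mean Dice, then smaller outer radius.

## Features

Twelve first-order descriptors; conventions the source leaves open are
fixed and recorded in `zot.features.CONVENTIONS`: Shannon entropy in bits
and uniformity over 64 equal-width bins spanning the sample min–max;
skewness as the standardised third moment and kurtosis non-excess (Pearson,
0 on constant samples); the last decile inclusive of the 90th percentile;
CV = σ/|μ| (0 when μ = 0); local maps on a 3×3 window clipped to the ROI.
The RCS between contrast phases is undefined when |mean(f_A, f_V)| vanishes
and is reported as missing; study drivers drop features with missing
values.  Pool bookkeeping: a transition region on one channel contributes
132 features per phase (12 descriptors × 10 local maps + 12 raw), the
tumour core 120 (grey-level maps only); the dual-phase pool is
2×132 + 2×120 + 6 volume features + 252 RCS features = 762.

## Study protocols

Normalisation maps each feature's [Q1, Q3] to [0, 1], then standardises;
parameters are learned on training data and frozen.  LASSO screening uses
5-fold CV with each sample weighted by its class prior (the stated design;
with empirical priors this is the neutral weighting of the original
environment).  All C(n, 4) quadruples of the retained features are
filtered by pairwise Pearson correlation — any couple with |ρ| ≥ 0.3
discards the quadruple; the absolute value is a deliberate extension, since
a strong negative correlation is equally redundant — then each surviving
quadruple's linear-SVM projection is rank-sum tested (Holm–Bonferroni,
α = 10⁻³) and the most informative significant quadruple wins.

Oversampling draws synthetic rows per class from per-feature Gaussian-KDE
quantile functions joined by a Latin hypercube; among the candidate draws
(default budget 10³, configurable to the 10⁵ of the reference design) the
one minimising the Frobenius distance between original and augmented
correlation matrices is kept, and original rows are retained verbatim.
Class targets are configuration: the reference design's 62/107 for target
169 is not the proportional apportionment of its 32/57 input (that would be
61/108), so the proportional largest-remainder split is only the default.

The train/holdout split stratifies jointly by label and by SVM-margin class
(signed margin > 1 correct, 0–1 inside the margin, < 0 misclassified, from
an SVM on the whole set), apportioning counts by largest remainder; the
117-of-169 design reproduces the 43/74 vs 19/33 partition exactly.  The
training loop runs repeated (default 100) 3-fold CV; per run the RBF-SVM's
(γ, C) are tuned by seeded random search over log-space on validation-fold
AUC — the protocol's contract is the selection rules, not the tuner — then
runs whose train-fold AUC is below their validation-fold AUC are discarded
as overfitting-suspect, survivors are refitted on all folds, and the final
model maximises (informedness, AUC) on the training set, with probabilities
from a logistic calibration of the decision values.  Rank tests use the
continuity-corrected Mann–Whitney form, matching the original environment's
rank-sum; all p-values are two-sided.  Printed metrics round
half-away-from-zero (percentages to integers, informedness to two decimals,
DOR to an integer), matching the reference tables' convention.

## Phantoms: what they emulate and what they do not

Disk phantoms emulate small near-circular nodules with shaded borders on
noisy parenchyma; jagged phantoms (harmonic radial perturbation, seeded
phases, circular concavity bites) emulate larger irregular lesions, with
optional adjacent bright confounders.  The intensity ramp across the
transition band is linear by default (sigmoid optional) — the minimal
assumption, since no physical transition profile is established — and the
ground-truth band is exactly the annulus of the ramp, |signed distance| ≤
width/2.  Noise is additive Gaussian (Poisson optional) at a default SD of
5% of the core/background contrast.  Phantoms do not simulate scanner
physics, partial-volume effects, intensity inhomogeneity fields, textured
parenchyma or 3-D geometry; passing the phantom suite shows the pipeline
recovers known transition geometry under idealised contrast, not clinical
performance.

Confounder placement uses the lesion mask's distance transform so the disk
clears the transition band by a configurable gap everywhere; the default
2 mm is the smallest separation at which two edges remain resolvable by a
3×3 derivative kernel at 1 mm/px, while keeping the structure inside a
6 mm rim's reach — the scenario in which the adaptive region's exclusion
of adjacent structures is a meaningful claim.  At a 1 mm gap the two
gradient bells merge and no gradient-reading method can separate them.

A note on recovered widths: a 4 mm intensity ramp observed through a 3×3
Sobel kernel, Lanczos/spline interpolation and profile smoothing has a
gradient support of roughly 8–9 mm; the detected annulus tracks that
support, so it is systematically wider than the underlying intensity band.
Band-width *changes* are faithfully tracked (monotone, ρ ≈ 0.98).

## Degenerate inputs and edge cases

ROIs that erode to nothing keep all pixels as border (flagged); stripes
leaving the image are edge-clamped and truncated-flagged; flat profiles
yield null extents; an empty sparse mask, a single-phase Chan–Vese result
or an annulus that collapses during hole synthesis raise a stage-named
detection error.  Zero-IQR features skip the quartile map and are flagged;
DOR with an empty error cell is reported as +∞ with no continuity
correction; Youden-cutoff ties take the lower threshold; the first local
minimum (nearest the peak) wins ties in the valley search.

## Problem sizes

The validation suite runs 50 detections for the width sweep (128² images,
15 mm lesions), 5 jagged confounder phantoms (192²), and 100-seed
simulations for the type-I, LASSO-retention and permuted-label checks, the
latter at the 169-sample reference design with a reduced CV budget (2 runs
× 3 evaluations; the selection rules are unchanged — the budget is
configuration, chosen to keep the whole suite around two minutes).
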