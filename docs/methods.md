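# Methods

## Problem and measurement model

The package quantifies how well an active ingredient (AI) penetrates skin
from vertical cryosection fluorescence micrographs, using fluorescent dyes as
AI surrogates (a hydrophilic, fluorescein-like dye applied in water and a
lipophilic, nile-red-like dye applied in oil).  Four per-image readouts drive
every downstream result:

* **SCT** (stratum corneum thickness, µm): measured along vertical lines from
  the detected skin surface to the SC lower boundary, converted with the
  pixel scale (2.84 µm/px by default).  SCT doubles as a hydration surrogate:
  a better hydrated SC is thicker.
* **AF-SC** (SC autofluorescence, grey/px): the mean intensity per pixel
  along each measured SCT line.  It rises with SC dehydration/optical
  density.  On dye-treated sections it is the sum of autofluorescence and dye
  that entered the SC — an inherent confound of the readout, not of this
  implementation.
* **AROSA** (grey/px): the mean grey value per pixel of the whole image after
  an automated threshold removed the skin's autofluorescence; a surrogate for
  the *total amount* of penetrated AI.
* **MPD** (µm): the unweighted mean depth below the local surface of all
  suprathreshold pixels.

Condition means are converted to relative values with the untreated skin
section fixed at exactly 100% within each (surrogate, application-timepoint)
stratum, and the penetrated compartment is classified by comparing MPD with
SCT and the epidermis thickness: MPD ≤ SCT stays within the SC,
SCT < MPD ≤ epidermis reaches the viable epidermis, MPD > epidermis counts as
transdermal.  The epidermis default is 110 µm, the upper end of the porcine
ear range, deliberately conservative for declaring transdermal delivery.

## Surface and SC-boundary detection

The original workflow measured SCT manually with an image-analysis scale
tool; here both boundaries are automated:

* **Surface**: per column, the background level is the 0.99 quantile of the
  top image margin (5 rows) plus an offset of 20 grey units; the first
  column-smoothed crossing (moving average, 5 px window) is refined to the
  first raw crossing nearby.  The refinement makes the detector exact on
  noise-free steps and keeps the mean error well below 1 px at the default
  noise level.
* **SC lower boundary**: per sampled line (10 evenly spaced valid columns by
  default), the first row below the surface where the smoothed profile drops
  under the midpoint between the local band level (rows just below the
  surface) and the deep-tissue level (median of the deepest quarter of the
  column).  With a centred odd smoothing window, the mid-level crossing of a
  clean step edge sits exactly at the true boundary, so the only systematic
  error on clean renders is the px→µm quantisation (≤ 1.42 µm at 2.84 µm/px).

On dye-laden images with a bright, smoothly decaying depth profile the
intensity-based boundary tracks the dye rather than the band, so SCT and
AF-SC from heavily dyed sections are profile-shaped quantities, mirroring the
confound noted above.  Accuracy claims for SCT therefore come from dye-free
renders.

## Autofluorescence-removal threshold

The default `control_stats` threshold pools the intensities of the tissue
section (every pixel at or below the detected surface, SC band included) over
an ear's dye-free blank images and returns mean + 3·SD.  Including the SC in
the pooled region is essential: the pooled SD is dominated by the SC/tissue
contrast, and with an SC fraction of ≳ 10% of the section the threshold ends
above the SC band, so dye-free skin retains essentially nothing (blank AROSA
< 1% of a dye-present control).  A per-image Otsu threshold (exhaustive
between-class variance over the integer histogram of the section) is the
fallback when no blanks exist.  The method, k and pixel count are recorded
with every measurement.

AROSA keeps zeros in its denominator (mean over *all* image pixels), so both
suprathreshold brightness and penetrated area raise it, matching its role as
a total-amount surrogate.  Retention uses a strict inequality: pixels exactly
at the threshold count as background.  MPD averages over pixels rather than
per-column maxima, which is robust to single deep outlier columns; images
with nothing retained enter condition means as 0 with a NO_SIGNAL flag
rather than being dropped, so rarely penetrating conditions are not biased
upward.

## Synthetic-image generator

No real micrographs are publicly available, so validation runs on renders
with exact ground truth.  An image is, top-down: background (2 grey units),
a surface at `surface_row_mean_px` with per-column Gaussian jitter
(SD 1 px), an SC band of thickness `sct_um` at `af_sc_level` (180), viable
tissue at `af_tissue_level` (40), a dye term `dye_amount ·
exp(−depth/dye_decay_um)` anchored at the surface, Poisson-count bright
hotspots near the surface (sebum/bacteria, level 120), and additive Gaussian
noise (SD 3), quantised to 16 bit by default.  The exponential depth profile
is the simplest monotone choice and makes every expected value computable by
brute force.

Hydration couples in linearly: `sct_eff = sct_um·(0.8 + 0.4·h)` and
`af_sc_eff = af_sc_level·(1.2 − 0.4·h)` for hydration index h ∈ [0, 1] —
directions fixed by the physics (hydrated SC: thicker, optically thinner),
magnitudes conventions.  Grey-level and dye magnitudes are likewise
conventions chosen once: hydrophilic base amplitude 5000 with a 110 µm decay
length reproduces a mean penetration depth > 150 µm (transdermal); the
lipophilic formulation (amplitude ×1.6, decay ×0.36, i.e. 8000 / 40 µm)
lands at ≈ 80 µm (viable epidermis).  Dye amplitudes sit far above the
threshold-minus-tissue gap so that thresholded AROSA stays nearly
proportional to the deposited amount; that is what makes relative-value
recovery within a few percentage points possible.

A study render follows the emulated design: 3 independent ears ×
12 conditions (3 skin sections × 2 surrogates × 2 application timepoints) ×
40 images per biopsy spread over 12 cuts, plus 20 dye-free blanks per ear
for thresholding.  Ears carry multiplicative log-normal (10%) random effects
on autofluorescence levels and SCT, shared across their images.  Treatment
presets (`data/presets.yaml`) scale the base parameters: AI applied during
the treatment is reduced (mask uptake; massage rubs more away — fractions
0.80/0.54 hydrophilic and 0.66/0.32 lipophilic for sections 2/3), AI applied
after the treatment benefits from massage (notably the lipophilic surrogate,
whose blocking water front massage removes) and is hindered on non-massaged
treated skin.  All randomness derives from one root seed through
`numpy.random.SeedSequence`, so studies are bit-reproducible.

What the generator does *not* emulate: optics (PSF, vignetting,
illumination gradients), histology artifacts (tears, folds, oblique cuts),
non-exponential depth profiles, and spatial correlation of camera noise.
Passing recovery tests therefore demonstrates the correctness and
calibration of the measurement chain, not robustness to every real-world
artifact.

## Statistics

Group comparisons follow the assumption-gated tree common in point-and-click
statistics packages: Shapiro–Wilk per group (α = 0.05; groups with n < 3,
zero variance or n > 5000 are refused and routed non-parametric), then —
if all groups pass — Levene's test (mean-centred by default) choosing
between classical ANOVA + Tukey HSD and Welch ANOVA + Games–Howell; any
non-normal group sends the comparison to Kruskal–Wallis + Dunn.  Dunn's p
values use the tie-corrected rank variance and Holm adjustment by default
(none/Bonferroni available); the adjustment is always recorded since the
emulated workflow does not pin it down.  Stars: ``***`` p < 0.001, ``**``
p < 0.01, ``*`` p < 0.05, strict inequalities.  Every rule firing lands in
an ordered decision trace in the output.

Statistics run on two units: pooled images (large n; canonical, matching
how such figures are usually annotated) and per-ear means (n = ears; the
honest independent unit).  Both appear in the report.  Calibration of the
full tree is checked by simulation: type-I error 0.05 ± 0.02 under a
three-group normal null (2000 reps, n = 20) and power ≥ 0.9 with one group
shifted 1.5 SD at n = 40.

## Problem sizes and numerical choices

Default renders are 128 × 160 px (≈ 364 × 454 µm at 2.84 µm/px) — deep
enough below the surface (≈ 335 µm) to hold the hydrophilic penetration
front.  Validation experiments use the design scale where it matters
(≥ 40 images per condition for effect-size recovery, 120 per condition for
depth summaries, 50 images for SCT recovery, 200 for surface recovery,
2000/500 replicates for the error-rate simulations); the full default study
(1500 images) runs in seconds.  Ties in thresholding are resolved toward
background (strict >); boundary rows use half-open [surface, bottom)
conventions; compartment boundaries are closed on the shallow side
(MPD = SCT is within SC, MPD = epidermis is viable epidermis).

## Known limitations

* SCT/AF-SC on brightly dyed sections follow the dye profile (see above);
  compartment calls built on measured SCT inherit that bias for strongly
  penetrating conditions.
* Relative AROSA tracks the deposited-amount fraction only while amplitudes
  are large against the threshold; near-threshold signals compress toward
  smaller relative values.
* The ear hierarchy is handled by reporting per-ear analyses, not by
  mixed-effects modelling.
* The control (untreated) presets are identity by construction, so
  time-dependent drying of untreated skin is exercised through the hydration
  parameter directly rather than through presets.
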