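# Methods

## Data model

A thermal frame is a 2-D float64 raster of surface temperatures in
degrees Celsius with NaN as the internal missing-pixel marker ("NA" in
CSV files, NaN in 32-bit float TIFF). Raster origin is top-left,
row-major; no geo-referencing. The default frame size is the study
camera's native 320 × 240 focal-plane array, configurable everywhere.
Missing pixels are excluded from every histogram, count and mean.
Frames are paired with acquisition metadata (species, variety, stage,
session, replicate, frame index) through a single study-level manifest
CSV rather than per-file sidecars, matching the plot/session sampling
design and simplifying globbing.

Temperatures are Celsius by contract, not convention: the stress index
divides by the raw soil temperature, so it is invariant neither to unit
changes nor to origin shifts, and it degenerates as `T_S → 0 °C`.
`compute_wsi` therefore rejects `T_S ≤ 0` outright and emits an
`OutOfRegimeWarning` outside `0 < T_W < T_S` instead of silently
returning an out-of-range value.

## Segmentation

Per frame (never per plot — each frame gets its own threshold):

1. **Histogram.** Uniform bins of 0.1 °C spanning the frame's valid
   range. The camera's noise-equivalent temperature difference is
   ~60 mK, so finer bins only resolve sensor noise.
2. **Peak detection.** Moving-average smoothing over 5 bins (edge mode
   "nearest", which preserves boundary maxima of monotone histograms),
   then local maxima with prominence ≥ 5 % of the tallest smoothed
   count and pairwise separation ≥ 1.0 °C. The smoothed array is padded
   below its minimum before peak finding so a mode at the first or last
   bin is detectable. All three knobs are exposed in
   `SegmentationParams`.
3. **Threshold.** Exactly two peaks → their arithmetic mean
   (`mean_of_peaks`). More than two → keep the two most prominent,
   then the mean. Zero or one peak → Otsu's criterion: the interior
   bin edge maximizing the between-class variance of the histogram
   (`otsu_fallback`). The field procedure for the continuous case is a
   visual comparison with an RGB photograph; Otsu is this package's
   deliberate, automatable substitution for that judgement call. A
   manual threshold always wins. A single-bin histogram has no
   threshold and raises.
4. **Classification.** Wheat where `T ≤ T_TH`, soil above. The
   published rule uses strict inequalities on both sides and leaves
   equality undefined; ties go to wheat here. Any fixed rule preserves
   the count invariants, and at 0.1 °C bins the choice is immaterial.

Numerical detail: thresholds separated only by empty histogram bins
induce the same partition, so their between-class variances tie up to
float rounding. Otsu candidates within a relative 1e-9 of the maximum
are treated as tied and the lowest edge is returned; the brute-force
oracle in the tests applies the same rule, making implementation/oracle
equivalence exact rather than seed-lucky.

Known limitation, inherited from the method itself: with overlapping
class distributions some wheat pixels sit above `T_TH` and some soil
pixels below it. No correction is applied; the working assumption is
that the two error sets roughly cancel in the counts. At ≥ 6-sd class
separation (the synthetic regime tested) misclassification is < 1 %.

## Indices and aggregation

WSI is computed **per frame** from that frame's class means, then
frames are averaged — not "pool all temperatures, compute one WSI".
The per-image acquisition makes the frame the natural replication unit
and gives an estimable dispersion; the alternative ordering differs
only at second order in the class-mean fluctuations. A frame whose
segmentation leaves one class empty has no defined WSI and is rejected
(the caller sees which frame and why).

WCI is restricted to stem-elongation frames — enforced, not advisory:
later in the season the canopy occludes the soil and the pixel ratio
stops measuring ground cover.

Aggregation: stage cell = unweighted mean of all frame-level WSI for
that variety × stage, pooled over sessions and replicates; `WSI_m` =
row mean over the four stages, `PP-WSI_m` = column mean over varieties
(empty cells excluded, with a logged warning). On a complete table the
grand means of rows and columns coincide — kept as a test invariant.
Dispersion for WCI is the standard error of the frame-level mean; the
published tables' ±-values have an unstated estimation method, so the
package reports its own SE and does not emulate them. Rounding
(half-up, 2 decimals) is applied only in rendered report tables; all
comparisons against the published tables use |computed − printed| ≤
0.01, the error the tables themselves state.

The packaged fixture tables carry the published per-variety `WSI_m`
column alongside the stage values. Reproduction-mode correlations use
that printed 2-decimal column (what the original analysis had on
paper); synthetic runs correlate full-precision row means.

## Correlation analysis

OLS fit `y = a + bx` (b = cov/var), Pearson R, and the two-tailed
t-test `t = R·√(n−2)/√(1−R²)` with df = n − 2 against Student's t.
p-values are binned into the conventional report levels {<0.001,
<0.005, <0.01, <0.025, <0.05, N.S.}. No multiple-testing correction is
applied by default — faithful to standard practice for these
nine-variety panels — but `holm=True` reports Holm-adjusted p-values
alongside. The modern-cultivar exclusion (PG, SV for durum; AX, AL for
common) drops rows before fitting and never alters the remaining
values; n = 9 becomes n = 7, df = 5.

As an independent check of the t approximation at these sample sizes,
`permutation_pvalue` enumerates all n! pairings exactly for n ≤ 9
(Monte Carlo with the +1 correction beyond) and reports
`P(|R_perm| ≥ |R_obs|)`. On the packaged tables the exact permutation
p agrees with the t-based p to 2·10⁻⁴ on the stress-index/yield
pairings. It does **not** agree to better than ~0.013 on some
cover-index pairings: the `WCI_m` vectors contain ties and skew, and at
n = 9 the discreteness of the exact null moves it visibly away from
the t curve. This is a property of the data, established by full
enumeration under both common two-sided definitions; the tests assert
the tight agreement where it holds and a 0.02 envelope elsewhere.
Neither definition changes any significance-bin conclusion.

One rounding-sensitivity case is deliberately left unasserted: common
wheat `WSI_m` vs biomass computed from the printed 2-decimal values
lands at p ≈ 0.052, a hair above the 0.05 line. Whether the original
full-precision values fell just below is unknowable from the tables;
the package reports the number and takes no side.

## Synthetic thermal fields

The generator emulates the study design, not canopy physics:

* **Mask.** Vertical crop-row bands of jittered width (default 4–12
  pixels) separated by soil gaps, placed to meet the requested cover
  fraction exactly at column granularity (±1/width). Histograms are
  bimodal while masks look like drilled rows — i.i.d. speckle would
  satisfy the histograms but not resemble a crop.
* **Temperatures.** Per-pixel Gaussian noise per class (default sd
  0.5 °C each). Gaussianity is a modelling choice, not a measured
  property of the fields.
* **Parameterization.** A cell spec fixes soil mean (default 25 °C, a
  plausible late-morning Mediterranean spring soil surface), target
  WSI and cover; the wheat mean is derived, `wheat_mean =
  soil_mean·(1 − target_wsi)`, so recovery targets are exact by
  construction.
* **Sessions.** Each session draws one additive offset
  Normal(0, 0.5 °C) applied to both class means of every plot measured
  in it, emulating morning/afternoon weather shifts. Adding the same
  offset to both means preserves the temperature difference exactly
  and the WSI only to first order (`WSI = Δ/(T_S+δ)`); at the study's
  scale this contributes ~0.004 of per-session WSI dispersion, which
  averages out over the default four sessions per stage. Plot-edge
  effects are treated as already cropped away.
* **Sampling effort.** Default 10 frames per crop per session (the
  per-replicate acquisition count of the field protocol, whose two
  descriptions — 30 images per crop, 10 per replicate, vs. 20 per
  crop — are inconsistent; both are reachable through the config) and
  4 sessions per stage.

What passing the synthetic recovery tests shows: the segmentation +
aggregation chain inverts the generator — two spatially coherent
Gaussian classes at ≥ 5 °C separation — to within the published ±0.01
per cell, including the bell-shaped stage profile. What it does not
show: robustness to mixed pixels, shadows, wind-driven temperature
streaks, partial occlusion or emissivity variation, none of which the
generator models.

## Problem sizes in the test and acceptance runs

End-to-end recovery of the published durum stage matrix runs at 4
sessions × 2 frames per variety × stage cell (288 frames, 320 × 240),
a sampling effort at which the session-offset dispersion is already an
order of magnitude inside the ±0.01 acceptance band; the generator's
defaults remain the full field protocol. The cover-recovery check uses
20 frames at the densest published coverage (0.93), matching the
per-session acquisition count. `scripts/acceptance.py` uses the same
20-frame design and reports the recovered mean WCI in percent; with
0.5 °C noise and 5 °C class separation the result is dominated by the
mask's column quantization (298/320 = 93.125 %), not by the seed.
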