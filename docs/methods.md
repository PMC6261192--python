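# Methods

## Overview

`adcstab` quantifies how robust radiomic features computed on ADC maps are
to misplacement of the region of interest, and whether they react at all
when the ROI no longer covers the lesion. The procedure: (1) translate each
subject's ROI in-plane by graded fractions of its bounding-box length;
(2) extract a fixed 69-feature catalog from the original and every
translated ROI, under three histogram discretizations; (3) score each
feature per translation entity with the percentage variation (Diff%) and the
two-way mixed-effects ICC over subjects; (4) derive selection thresholds
from kernel-density quantiles of the pooled ICC distributions; (5) label
every feature selected / unstable / non-discriminative.

## ADC mapping

ADC is the negative OLS slope of `ln S` on b (s/mm²), fitted per voxel with
equal weights. Non-positive signals are clamped to a floor (default
`1e-6 × max(S)` over the series) before the logarithm so the map is defined
everywhere; negative fitted ADCs are kept as computed — the downstream
histogram clamps them into the lowest bin, which avoids silently altering
data. All provided b values enter the fit, including b = 0 when present.

## Feature catalog (69 per discretization)

- **Signal statistics (23).** Energy (Σx²), kurtosis, mean absolute
  deviation, max, mean, median, min, range, RMS, skewness, SD, variance,
  plus 11 quantiles (0.01, 0.1–0.9, 0.99). Skewness and kurtosis use
  population (biased) moments with kurtosis non-excess (Gaussian → 3); SD
  and variance use the n−1 denominator — the default conventions of the
  common numerical platforms for these statistics. The quantiles are read
  off the discretized-histogram CDF (the centre of the first bin whose
  cumulative relative frequency reaches the level), which deliberately
  makes them bin-dependent; the other 12 signal statistics are the only
  features guaranteed identical across discretizations, giving the 57/12
  bin-dependence split of the catalog.
- **Histogram statistics (14).** Computed on the relative-frequency vector
  itself: entropy (−Σp log₂p), kurtosis, MAD, max, mean, median, min,
  range, RMS, skewness, SD, variance, uniformity (Σp²), plus the total
  frequency, which is the raw in-mask voxel count. Consequences worth
  noting: the histogram mean is exactly 1/n_bins for any input, and the
  histogram minimum is 0 whenever any bin is empty — both therefore score
  as non-discriminative, which is the behaviour the selection rule is
  designed to catch.
- **Discretization.** Uniform bins over the fixed range 0–4000·10⁻⁶ mm²/s
  (defaults 16/32/64 bins). Out-of-range values are clamped into the edge
  bins so the voxel count is conserved.
- **GLCM (21) and GLRLM (11).** Built on the 1-based bin indices at
  distance ρ = 1 voxel step (spacing anisotropy ignored for adjacency, the
  standard texture convention), along the 13 unique directions of the
  26-neighbourhood (one per antiparallel pair; both matrices are symmetric
  under direction reversal). Pairs count only when both voxels are in-mask;
  runs truncate at the mask boundary. Features are computed per direction
  and arithmetically averaged; degenerate directions (no valid pair) are
  excluded from the average. GLCM features follow the Haralick-style
  catalog; the four inverse-difference variants are kept distinct as
  homogeneity `Σp/(1+|i−j|)`, homogeneity 2 `Σp/(1+(i−j)²)`, and their
  level-normalized counterparts `Σp/(1+|i−j|/N)` and `Σp/(1+(i−j)²/N²)`;
  inertia and contrast are separate named outputs sharing the classical
  `Σ(i−j)²p` (the catalog lists both names, and they are emitted as two
  columns). GLRLM features follow the Galloway/Chu definitions. All
  entropies are base-2 with the 0·log 0 = 0 convention. Undefined values
  (correlation of a constant ROI, any feature of a degenerate matrix)
  propagate as NaN markers and are excluded pairwise downstream with
  logged counts — never reported as silent zeros.

## Translation protocol

Entities run 0.1–1.0 in steps of 0.1; each entity produces four transforms
(± shift along each in-plane axis; the slice axis is never translated). The
voxel offset is `round(entity × bbox_length)` along that axis, floored at
1 voxel so the perturbation is never a no-op; masks are shifted by whole
voxels (no resampling — masks are voxelized, and integer shifts keep the
value multiset exact). Voxels shifted off the grid are dropped with a
warning (a 100 % shift can legitimately exit the field of view); the
translation is rejected only if the whole mask leaves the grid.

## Stability statistics

Diff% is undefined when the reference value is 0 (excluded from means, with
a count). The ICC is McGraw–Wong C,1 (two-way mixed, single measurement,
consistency): the transformation is a fixed effect, subjects are random;
the absolute-agreement form A,1 is available via `icc_form="agreement"`.
Negative ICCs are kept unclamped. When both columns have zero variance the
ICC is defined as 1 (degenerate but perfect agreement) — required so that
constant features score as non-discriminative rather than noise; the
zero-variance test uses a 1e-12 relative tolerance because analytically
constant features still carry ~1e-17 float rounding. Per entity the package
records the 4 ICCs, the up-to-4×n Diff% values, their means (ICC_mean,
Diff%_mean) and t-based 95 % confidence intervals (the CI construction is a
package choice; nothing downstream depends on it).

## Thresholds and selection

ICC_10 values (minimal entity) and ICC_100 values (maximal entity) are
pooled across cohorts, discretizations and features into two samples. Each
is fitted with an equal-weight Gaussian kernel mixture — every kernel
centred on an observed value with SD equal to the bandwidth (default
0.05) — and the threshold is the point where the mixture CDF equals the
quantile (0.1 for ICC_min, 0.9 for ICC_max), solved by Brent's method to
1e-9 (well inside the 1e-6 contract). A χ² goodness-of-fit report for the
KDE is available as an optional diagnostic and never gates the analysis.
Classification order: unstable if `ICC_10 < ICC_min`; else
non-discriminative if `ICC_100 > ICC_max`; else selected. Comparisons are
inclusive (`≥`/`≤`) at the thresholds. Undefined ICCs flag the feature as
`undefined` instead of dropping it.

## Synthetic phantoms

Each phantom is a 3-D grid (default 48×48×16 voxels at 2×2×4 mm) with an
ellipsoidal lesion (semi-axes 6/5/3 voxels) whose exact voxelization is the
ROI. Voxel values are class mean plus correlated noise: Gaussian white
noise convolved with an isotropic Gaussian kernel (correlation length
1.2 voxels) and rescaled to the requested SD, then clipped to the ADC
histogram range — the correlation is what gives the co-occurrence matrices
non-trivial off-diagonal structure. Defaults place the lesion at
1.2·10⁻³ mm²/s inside a 0.7·10⁻³ background with noise SD 1.5·10⁻⁴: a solid
soft-tissue tumor surrounded by fat/bone-dominated tissue of *lower* ADC.
That orientation matters — a shifted ROI immediately captures low-ADC
outliers, which is what makes extreme-value statistics (signal minimum, low
quantiles) fragile in clinical data, and the phantom reproduces the three
qualitative robustness groups: averages degrade gradually and are selected;
extreme values collapse at small shifts (unstable); constant features keep
ICC = 1 (non-discriminative). The lesion must keep a margin of at least its
own bounding-box length from the grid edge per in-plane axis, so even the
100 % translation never clips. Cohorts draw per-subject jitter (default
±15 % on the radii, 8·10⁻⁵ mm²/s on the class means) from substream
`seed + i`, making subjects individually reproducible. DWI simulation is
mono-exponential `S = S₀·exp(−b·ADC)` with Rician noise (Gaussian on both
quadrature channels); σ = 0 gives the exact decay, and the ADC fit then
recovers the ground truth to float precision.

What the phantoms do **not** emulate: anatomy, multi-compartment diffusion
(IVIM/kurtosis), scanner artifacts, partial-volume boundaries, or the
heavy-tailed heterogeneity of real tissue. Passing tests therefore show the
*method* behaves correctly (protocol arithmetic, statistics, thresholding,
qualitative group behaviour), not that any specific clinical feature set
would be selected; real-data thresholds must be derived from real cohorts.

## Problem sizes and numerical choices

The default analysis (18 subjects, 10 entities, 3 discretizations, full
catalog) runs in a couple of minutes on one core; the test suite uses
smaller cohorts (2–6 subjects, 1–2 entities) except where the protocol
count itself is under test. Brute-force oracle comparisons use 5×5×3
fixtures at 4 gray levels, 50 of them, at 1e-10 relative tolerance.
Tie-breaks and edge cases: histogram quantile at a CDF tie takes the first
bin reaching the level; the bounding box is the tightest axis-aligned box;
`searchsorted(..., "left")` makes the quantile inclusive at exact CDF hits;
single-voxel ROIs yield NaN for n−1-denominator statistics and degenerate
texture matrices.

## Known limitations

- The ICC pools on synthetic cohorts produce much lower thresholds than
  clinical cohorts would (the phantom's features are either very stable or
  very unstable, with little middle ground); threshold *values* are
  cohort-specific by construction.
- Only in-plane translations are implemented; rotations, dilations and
  z-shifts are out of scope.
- Shape/size/location features are deliberately absent: the protocol keeps
  ROI geometry constant, so such features cannot be assessed by it.
- The GLCM/GLRLM dialect (notably the four inverse-difference variants) is
  one defensible reading of a catalog whose names overlap classically;
  the exact formulas are fixed and documented above for reproducibility.
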