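# adcstab

Stability and discrimination analysis of radiomic features on apparent
diffusion coefficient (ADC) maps.

## The problem

Radiomic studies extract dozens to hundreds of quantitative features from a
tumor region of interest (ROI) and feed them to clinical models. Many of
those features are unreliable: some change drastically under the small
delineation differences that separate two radiologists' contours of the same
tumor (*unstable* features), while others barely change even when the ROI is
moved entirely off the tumor — they carry no information about the lesion at
all (*non-discriminative* features). Both kinds should be removed before any
modelling, but classic stability screens need repeated acquisitions or
repeated manual delineations.

`adcstab` implements a screen that needs **one** acquisition and **one**
delineation. The ROI is translated in-plane by graded fractions ("entities")
of its bounding-box length, from 10 % (mimicking delineation variability) to
100 % (moving the ROI completely off its original footprint), one positive
and one negative shift along each in-plane axis. For every feature `F` and
every translation the package computes the absolute percentage variation

```
Diff% = |F_transf − F_original| / |F_original| · 100
```

and, over the cohort of subjects, the two-way mixed-effects single-measurement
consistency ICC (translation effect fixed, subject effect random; with n
subjects and k = 2 columns):

```
ICC = (MS_subjects − MS_error) / (MS_subjects + (k − 1)·MS_error)
```

Averaging the 4 ICCs per entity gives ICC_mean curves. Selection thresholds
are *data driven*: the ICC_mean values of the minimal (ICC_10) and maximal
(ICC_100) entities — pooled across cohorts, discretizations and features —
are each fitted with an equal-weight Gaussian kernel density (bandwidth
0.05), and

- `ICC_min` = 0.1 quantile of the ICC_10 pool,
- `ICC_max` = 0.9 quantile of the ICC_100 pool.

A feature is **stable** if `ICC_10 ≥ ICC_min`, **discriminative** if
`ICC_100 ≤ ICC_max`, and is *selected* only if it is both. Excluded sets can
be compared across discretizations or cohorts with the Jaccard index.

The feature catalog has 69 entries per histogram discretization (16/32/64
bins over the fixed ADC range 0–4000·10⁻⁶ mm²/s): 37 first-order statistics,
21 gray-level co-occurrence matrix (GLCM) features and 11 gray-level
run-length matrix (GLRLM) features, the texture matrices built at distance
ρ = 1 along the 13 unique 3-D directions and the features averaged across
directions. ADC maps can be computed from multi-b diffusion-weighted MRI by
the per-voxel OLS slope of log-signal against b value.

## Worked example

A synthetic cohort of 18 subjects, each an ADC-like phantom with an
ellipsoidal lesion (ADC ≈ 1.2·10⁻³ mm²/s) in a lower-ADC background:

```python
from adcstab import RoiStabilityModel

model = RoiStabilityModel.from_phantom_cohort(n_subjects=18, seed=1,
                                              binnings=(16, 32, 64))
res = model.fit()
print(res.summary())
```

```
Radiomic feature stability analysis
===================================================
subjects:            18
entities:            0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0
ICC form:            consistency
KDE bandwidth:       0.05
ICC_min (Q0.1 of ICC_10 pool, n=207): 0.0449
ICC_max (Q0.9 of ICC_100 pool, n=207): 0.2922
---------------------------------------------------
  bins  selected  unstable  non-disc.  undefined
    16        54         7          8          0
    32        56         7          6          0
    64        56         7          6          0
===================================================
```

Of the 69 features, 54–56 survive per discretization; 7 are unstable
(their ICC has already collapsed at the 10 % translation) and 6–8 are
non-discriminative (their ICC is still high at the 100 % translation).
The ICC_mean curves behind those labels:

```python
print(res.heatmap(16).loc[["signal_mean", "signal_minimum",
                           "histogram_mean"], [0.1, 0.5, 1.0]].round(3))
```

```
entity            0.1    0.5    1.0
feature_name
signal_mean     0.979  0.074 -0.210
signal_minimum  0.126 -0.037  0.009
histogram_mean  1.000  1.000  1.000
```

`signal_mean` is the well-behaved case — nearly perfectly reproduced under
small shifts, decorrelated once the ROI leaves the lesion (selected).
`signal_minimum` is an extreme-value statistic and collapses immediately
(unstable). `histogram_mean` equals 1/n_bins for any input, so its ICC stays
at 1 everywhere (non-discriminative).

`res.to_csv(out_dir)` writes the tidy feature table, per-entity stability
records, ICC/Diff% heat-map matrices and the selection report; the same
pipeline is scriptable via the `adcstab` CLI (`simulate`, `adc`, `extract`,
`perturb`, `assess`, `run`).

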