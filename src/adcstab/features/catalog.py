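"""The fixed 69-feature catalog: 37 FOS + 21 GLCM + 11 GLRLM.

Names are stable identifiers used in every table the package writes.  The 12
signal statistics computed directly from the raw intensities are independent
of the histogram discretization; the remaining 57 features (the 11
histogram-CDF quantiles, the 14 histogram statistics and all 32 texture
features) change with the number of bins.
"""

_QUANTILES = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)

#: raw-intensity statistics, independent of binning
SIGNAL_STAT_NAMES = (
    "signal_energy",
    "signal_kurtosis",
    "signal_mad",
    "signal_maximum",
    "signal_mean",
    "signal_median",
    "signal_minimum",
    "signal_range",
    "signal_rms",
    "signal_skewness",
    "signal_sd",
    "signal_variance",
)

#: quantiles read off the discretized-histogram CDF (bin-dependent)
SIGNAL_QUANTILE_NAMES = tuple(f"signal_quantile_{q}" for q in _QUANTILES)

#: statistics of the relative-frequency vector, plus the raw voxel count
HISTOGRAM_STAT_NAMES = (
    "histogram_entropy",
    "histogram_kurtosis",
    "histogram_mad",
    "histogram_maximum",
    "histogram_mean",
    "histogram_median",
    "histogram_minimum",
    "histogram_range",
    "histogram_rms",
    "histogram_skewness",
    "histogram_sd",
    "histogram_variance",
    "histogram_uniformity",
    "histogram_total_frequency",
)

FOS_NAMES = SIGNAL_STAT_NAMES + SIGNAL_QUANTILE_NAMES + HISTOGRAM_STAT_NAMES

GLCM_NAMES = (
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_entropy",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_homogeneity_2",
    "glcm_imoc1",
    "glcm_imoc2",
    "glcm_inverse_difference_moment",
    "glcm_inverse_difference_moment_2",
    "glcm_inertia",
    "glcm_inverse_variance",
    "glcm_max_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
)

GLRLM_NAMES = (
    "glrlm_gray_level_nonuniformity",
    "glrlm_high_gray_level_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_long_run_high_gray_level_emphasis",
    "glrlm_long_run_low_gray_level_emphasis",
    "glrlm_low_gray_level_emphasis",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage",
    "glrlm_short_run_emphasis",
    "glrlm_short_run_high_gray_level_emphasis",
    "glrlm_short_run_low_gray_level_emphasis",
)

ALL_FEATURE_NAMES = FOS_NAMES + GLCM_NAMES + GLRLM_NAMES

#: features whose value does not depend on the histogram discretization
BIN_INDEPENDENT_NAMES = SIGNAL_STAT_NAMES

assert len(FOS_NAMES) == 37
assert len(GLCM_NAMES) == 21
assert len(GLRLM_NAMES) == 11
assert len(ALL_FEATURE_NAMES) == 69
assert len(BIN_INDEPENDENT_NAMES) == 12
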