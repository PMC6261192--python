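"""First-order statistics: 23 signal statistics and 14 histogram statistics.

Signal statistics are computed on the raw in-mask intensities.  Skewness and
kurtosis use population (biased) moments with kurtosis reported non-excess
(a Gaussian scores 3); SD and variance use the n-1 denominator.  The 11
quantiles are read off the discretized-histogram CDF — the reported value is
the centre of the first bin whose cumulative relative frequency reaches the
requested level — which makes them depend on the binning.

Histogram statistics treat the relative-frequency vector itself as the data
(so with N bins the histogram mean is exactly 1/N), except for the total
frequency, which is the raw in-mask voxel count.  Statistics that are
undefined on the input (e.g. variance of a single voxel) are reported as
NaN markers, never as silent zeros.
"""

from __future__ import annotations

import numpy as np

from .binning import BinningSpec, discretize
from .catalog import _QUANTILES


def _moments(x: np.ndarray) -> tuple[float, float]:
    """Population skewness and non-excess kurtosis; NaN when variance is 0."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return float("nan"), float("nan")
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    return float(m3 / m2**1.5), float(m4 / m2**2)


def _vector_stats(x: np.ndarray, prefix: str) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    skew, kurt = _moments(x)
    if x.size > 1:
        sd = float(np.std(x, ddof=1))
        var = float(np.var(x, ddof=1))
    else:
        sd = var = float("nan")
    return {
        f"{prefix}_kurtosis": kurt,
        f"{prefix}_mad": float(np.mean(np.abs(x - x.mean()))),
        f"{prefix}_maximum": float(x.max()),
        f"{prefix}_mean": float(x.mean()),
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_minimum": float(x.min()),
        f"{prefix}_range": float(x.max() - x.min()),
        f"{prefix}_rms": float(np.sqrt(np.mean(x**2))),
        f"{prefix}_skewness": skew,
        f"{prefix}_sd": sd,
        f"{prefix}_variance": var,
    }


def compute_fos(roi_values, binning: BinningSpec) -> dict[str, float]:
    """Compute the 37 first-order features of an ROI for one discretization."""
    x = np.asarray(roi_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("ROI contains no voxels")
    _, counts, freqs = discretize(x, binning)

    out = _vector_stats(x, "signal")
    out["signal_energy"] = float(np.sum(x**2))

    # histogram-CDF quantiles: centre of the first bin reaching level q
    cdf = np.cumsum(freqs)
    centers = binning.bin_centers()
    for q in _QUANTILES:
        j = int(np.searchsorted(cdf, q, side="left"))
        j = min(j, binning.n_bins - 1)
        out[f"signal_quantile_{q}"] = float(centers[j])

    hist = _vector_stats(freqs, "histogram")
    p = freqs[freqs > 0]
    hist["histogram_entropy"] = float(-np.sum(p * np.log2(p)))
    hist["histogram_uniformity"] = float(np.sum(freqs**2))
    hist["histogram_total_frequency"] = float(counts.sum())
    out.update(hist)
    return out
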