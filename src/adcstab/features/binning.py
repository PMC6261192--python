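"""Uniform discretization of ADC values over the fixed histogram range.

The histogram is always evaluated on [0, 4000e-6] mm^2/s with N equal-width
bins (study values N = 16, 32, 64).  Out-of-range values are clamped into
the edge bins so every voxel is counted: values below the range fall in bin
1, values at or above the upper edge fall in bin N.  Bin indices are 1-based
and double as the gray levels of the texture matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BinningSpec:
    """Histogram discretization: ``n_bins`` equal bins over [range_low, range_high)."""

    n_bins: int
    range_low: float = 0.0
    range_high: float = 4000e-6

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if not self.range_low < self.range_high:
            raise ValueError(f"range_low must be < range_high, got [{self.range_low}, {self.range_high}]")

    @property
    def width(self) -> float:
        return (self.range_high - self.range_low) / self.n_bins

    def bin_centers(self) -> np.ndarray:
        return self.range_low + (np.arange(self.n_bins) + 0.5) * self.width


def discretize(values, binning: BinningSpec):
    """Assign each value to a 1-based bin and build the histograms.

    Returns
    -------
    bin_index : ndarray of int
        1-based bin per input value, same shape as input.
    counts : ndarray, shape (n_bins,)
        Raw counts per bin; sums to the number of input values.
    frequencies : ndarray, shape (n_bins,)
        Relative-frequency histogram; sums to 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty set of values")
    idx = np.floor((values - binning.range_low) / binning.width).astype(np.int64) + 1
    idx = np.clip(idx, 1, binning.n_bins)
    counts = np.bincount(idx.ravel() - 1, minlength=binning.n_bins).astype(np.int64)
    freqs = counts / counts.sum()
    return idx, counts, freqs
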