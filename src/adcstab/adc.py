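"""Pixel-wise ADC mapping from multi-b DWI.

The apparent diffusion coefficient is estimated per voxel as minus the slope
of the ordinary-least-squares regression of log-signal on b value:

    ln S(b) = ln S0 - b * ADC

Plain (unweighted) OLS is used.  Non-positive signals are clamped to a small
floor before the logarithm so the map is defined at every voxel; negative
fitted ADC values are kept as computed (downstream histogram clamping puts
them in the lowest bin rather than silently altering the data).
"""

from __future__ import annotations

import numpy as np

from .phantom import DwiSeries
from .volume import ImageVolume

__all__ = ["DwiSeries", "compute_adc"]


def compute_adc(dwi: DwiSeries, signal_floor: float | None = None) -> ImageVolume:
    """Compute the ADC map (mm^2/s) from a multi-b DWI series.

    Parameters
    ----------
    dwi : DwiSeries
        Aligned volumes with >= 2 distinct b values (s/mm^2).
    signal_floor : float, optional
        Signals below this are clamped before taking logs.  Default:
        ``1e-6 * max(signal)`` over the whole series.

    Returns
    -------
    ImageVolume
        ADC per voxel, same grid as the input.
    """
    b = np.asarray(dwi.b_values, dtype=float)
    stack = np.stack([v.voxels for v in dwi.volumes], axis=-1)  # (..., nb)
    if signal_floor is None:
        signal_floor = 1e-6 * float(stack.max())
    if signal_floor <= 0:
        raise ValueError("signal_floor must be positive")
    logs = np.log(np.maximum(stack, signal_floor))
    # OLS slope via centred normal equations, vectorised over voxels
    bc = b - b.mean()
    denom = float(np.dot(bc, bc))
    slope = np.tensordot(logs, bc, axes=([-1], [0])) / denom
    ref = dwi.volumes[0]
    return ImageVolume(-slope, ref.spacing_mm, ref.origin_mm)
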