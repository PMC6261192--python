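"""Full-catalog extraction: 69 features per ROI per discretization.

Texture features are computed separately on each of the 13 direction
matrices and then arithmetically averaged across directions; directions
whose matrix is degenerate (no valid pair) are excluded from the average
and counted.  First-order features are computed once per discretization.
"""

from __future__ import annotations

import numpy as np

from ..volume import ImageVolume, RoiMask
from .binning import BinningSpec
from .catalog import ALL_FEATURE_NAMES, GLCM_NAMES, GLRLM_NAMES
from .directions import direction_set
from .fos import compute_fos
from .texture import build_glcm, build_glrlm, glcm_features, glrlm_features

_CLASSES = ("fos", "glcm", "glrlm")


def _average_over_directions(per_direction: list[dict[str, float]], names) -> dict[str, float]:
    out = {}
    for name in names:
        vals = np.array([d[name] for d in per_direction], dtype=float)
        defined = vals[~np.isnan(vals)]
        out[name] = float(defined.mean()) if defined.size else float("nan")
    return out


def extract_all(
    volume: ImageVolume,
    mask: RoiMask,
    binnings,
    classes: tuple[str, ...] = _CLASSES,
) -> dict[int, dict[str, float]]:
    """Extract the feature catalog for every discretization.

    Parameters
    ----------
    volume, mask : aligned ADC volume and ROI.
    binnings : iterable of BinningSpec (or ints, taken as bin counts over
        the default ADC range).
    classes : subset of {"fos", "glcm", "glrlm"} to compute; features of
        omitted classes are absent from the result.

    Returns
    -------
    dict mapping ``n_bins`` to ``{feature_name: value}`` (69 entries when
    all classes are requested; NaN marks undefined values).
    """
    unknown = set(classes) - set(_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    binnings = [b if isinstance(b, BinningSpec) else BinningSpec(int(b)) for b in binnings]
    values = mask.values_in(volume)
    dirs = direction_set()
    result: dict[int, dict[str, float]] = {}
    for binning in binnings:
        feats: dict[str, float] = {}
        if "fos" in classes:
            feats.update(compute_fos(values, binning))
        if "glcm" in classes:
            per_dir = [
                glcm_features(build_glcm(volume, mask, binning, d)) for d in dirs
            ]
            feats.update(_average_over_directions(per_dir, GLCM_NAMES))
        if "glrlm" in classes:
            per_dir = [
                glrlm_features(build_glrlm(volume, mask, binning, d)) for d in dirs
            ]
            feats.update(_average_over_directions(per_dir, GLRLM_NAMES))
        if set(classes) == set(_CLASSES):
            feats = {name: feats[name] for name in ALL_FEATURE_NAMES}
        result[binning.n_bins] = feats
    return result
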