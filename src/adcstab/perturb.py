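"""Graded in-plane translations of an ROI mask.

The perturbation protocol translates the ROI along the two in-plane axes
(x = axis 0, medial-lateral; y = axis 1, antero-posterior) by a fraction
("entity") of the ROI bounding-box length along that axis: entities run from
10% (mimicking delineation variability) to 100% (moving the box entirely
off its original footprint) in steps of 10%, each applied with both signs.
Offsets are rounded to the nearest integer voxel and floored at 1 so the
perturbation is never a no-op; voxels shifted off the grid are dropped
(with a count kept on the returned mask's log) rather than aborting, since
a 100% shift can legitimately exit the field of view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volume import RoiMask

logger = logging.getLogger(__name__)

DEFAULT_ENTITIES = tuple(round(0.1 * k, 1) for k in range(1, 11))
_IN_PLANE_AXES = {"x": 0, "y": 1}


def bounding_box(mask: RoiMask) -> tuple[int, int, int]:
    """Per-axis lengths (voxel counts) of the tightest box enclosing the ROI."""
    coords = np.argwhere(mask.voxels)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    return tuple(int(h - l + 1) for l, h in zip(lo, hi))


@dataclass(frozen=True)
class TranslationSpec:
    """One translation: axis, sign, entity (bbox fraction) and the voxel offset."""

    axis: str  # "x" | "y"
    sign: int  # +1 | -1
    entity: float
    voxel_offset: int

    def __post_init__(self) -> None:
        if self.axis not in _IN_PLANE_AXES:
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if not 0 < self.entity <= 1:
            raise ValueError(f"entity must lie in (0, 1], got {self.entity}")
        if self.voxel_offset < 1:
            raise ValueError(f"voxel_offset must be >= 1, got {self.voxel_offset}")

    @property
    def transform_id(self) -> str:
        pct = int(round(self.entity * 100))
        s = "+" if self.sign > 0 else "-"
        return f"t{pct:03d}{s}{self.axis}"


def _offset_for(entity: float, bbox_length: int) -> int:
    # nearest integer, half away from zero, never below one voxel
    return max(1, int(np.floor(entity * bbox_length + 0.5)))


def translation_suite(mask: RoiMask, entities=DEFAULT_ENTITIES) -> list[TranslationSpec]:
    """Build the full protocol: for each entity, the four signed in-plane shifts."""
    entities = [float(e) for e in entities]
    if any(not 0 < e <= 1 for e in entities):
        raise ValueError(f"entities must lie in (0, 1], got {entities}")
    lengths = bounding_box(mask)
    specs = []
    for entity in sorted(entities):
        for axis in ("x", "y"):
            offset = _offset_for(entity, lengths[_IN_PLANE_AXES[axis]])
            for sign in (1, -1):
                specs.append(TranslationSpec(axis, sign, entity, offset))
    return specs


def shift_mask(mask: RoiMask, axis_index: int, shift: int) -> RoiMask:
    """Shift a mask by an integer number of voxels along one axis.

    Voxels leaving the grid are dropped; ``shift=0`` returns an identical
    mask.  Raises if every in-mask voxel would leave the grid.
    """
    n = mask.shape[axis_index]
    if shift >= n or shift <= -n:
        raise ValueError("shift moves the entire mask off the grid")
    if shift == 0:
        return RoiMask(mask.voxels.copy(), mask.spacing_mm, mask.origin_mm)
    out = np.zeros_like(mask.voxels)
    src = [slice(None)] * 3
    tgt = [slice(None)] * 3
    if shift > 0:
        src[axis_index] = slice(0, n - shift)
        tgt[axis_index] = slice(shift, n)
    else:
        src[axis_index] = slice(-shift, n)
        tgt[axis_index] = slice(0, n + shift)
    out[tuple(tgt)] = mask.voxels[tuple(src)]
    if not out.any():
        raise ValueError("shift moves the entire mask off the grid")
    return RoiMask(out, mask.spacing_mm, mask.origin_mm)


def translate_mask(mask: RoiMask, spec: TranslationSpec) -> RoiMask:
    """Shift every in-mask voxel by ``sign * voxel_offset`` along the spec axis.

    The slice axis is untouched.  Voxels leaving the grid are dropped with a
    logged count; if the whole mask would leave the grid the translation is
    rejected.
    """
    ax = _IN_PLANE_AXES[spec.axis]
    try:
        out = shift_mask(mask, ax, spec.sign * spec.voxel_offset)
    except ValueError:
        raise ValueError(
            f"translation {spec.transform_id} shifts the entire mask off the grid"
        ) from None
    n_dropped = mask.n_voxels - out.n_voxels
    if n_dropped:
        logger.warning(
            "translation %s clipped %d of %d ROI voxels at the grid edge",
            spec.transform_id, n_dropped, mask.n_voxels,
        )
    return out
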