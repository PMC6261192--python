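"""Synthetic ADC phantoms: ellipsoidal lesions with controllable texture.

The generator produces reproducible cohorts of ADC-like 3-D volumes, each
containing one ellipsoidal "tumor" whose mean intensity and texture contrast
with the background, plus the exact ellipsoid voxelization as the ROI mask.
Optionally a noisy mono-exponential DWI series with known ground-truth ADC
can be simulated from any ADC volume.

Texture is modelled as Gaussian white noise convolved with an isotropic
Gaussian kernel (correlation length ``texture_corr_len_vox``) and rescaled
to the requested standard deviation, which gives the co-occurrence matrices
non-trivial off-diagonal structure.  All intensities are clipped to the
ADC histogram range [0, 4000e-6] mm^2/s after noise is added.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import ImageVolume, RoiMask, write_nifti

ADC_RANGE_HIGH = 4000e-6  # mm^2/s, upper edge of the histogram range


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single ellipsoidal-lesion ADC phantom.

    ADC means are in mm^2/s.  Defaults emulate a solid soft-tissue tumor
    (ADC around 1.2e-3) embedded in fat/bone-dominated surroundings whose
    ADC is lower (around 0.7e-3), the contrast situation of limb and
    head-and-neck lesions; it is this low-ADC surround that makes
    extreme-value statistics fragile under ROI misplacement.  ``noise_sd``
    is the standard deviation of the correlated texture field added to both
    compartments.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 4.0)
    lesion_center_vox: tuple[float, float, float] = (24.0, 24.0, 8.0)
    lesion_radii_vox: tuple[float, float, float] = (6.0, 5.0, 3.0)
    lesion_mean: float = 1.2e-3
    background_mean: float = 0.7e-3
    noise_sd: float = 1.5e-4
    texture_corr_len_vox: float = 1.2
    seed: int = 0

    def validate(self) -> None:
        if any(r < 2 for r in self.lesion_radii_vox):
            raise ValueError(f"all lesion radii must be >= 2 voxels, got {self.lesion_radii_vox}")
        for mean, name in ((self.lesion_mean, "lesion_mean"), (self.background_mean, "background_mean")):
            if not 0 <= mean <= ADC_RANGE_HIGH:
                raise ValueError(f"{name}={mean} outside [0, {ADC_RANGE_HIGH}] mm^2/s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # the lesion must stay inside the grid with margin >= its own
        # bounding-box length per in-plane axis, so that even a 100%
        # bounding-box translation of the mask stays on-grid
        for ax in range(3):
            c, r, n = self.lesion_center_vox[ax], self.lesion_radii_vox[ax], self.grid_shape[ax]
            margin = 2 * r + 1 if ax < 2 else 0  # in-plane axes carry translations
            if c - r - margin < 0 or c + r + margin > n - 1:
                raise ValueError(
                    f"lesion violates the grid margin on axis {ax}: centre {c}, radius {r}, "
                    f"required margin {margin} voxels, grid extent {n}"
                )


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.grid_shape, dtype=float)
    d2 = sum(
        ((idx[ax] - spec.lesion_center_vox[ax]) / spec.lesion_radii_vox[ax]) ** 2
        for ax in range(3)
    )
    return d2 <= 1.0


def _texture_field(shape, corr_len: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape)
    if corr_len > 0:
        fld = gaussian_filter(white, sigma=corr_len, mode="reflect")
    else:
        fld = white
    s = fld.std()
    if s > 0:
        fld = fld * (sd / s)
    return fld


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, RoiMask]:
    """Generate one ADC phantom volume and its exact ellipsoid ROI mask.

    The volume is ``class mean + correlated noise``, clipped to the ADC
    histogram range.  Identical specs (including seed) give bit-identical
    output.
    """
    spec.validate()
    inside = _ellipsoid_mask(spec)
    adc = np.where(inside, spec.lesion_mean, spec.background_mean).astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        adc = adc + _texture_field(spec.grid_shape, spec.texture_corr_len_vox, spec.noise_sd, rng)
    adc = np.clip(adc, 0.0, ADC_RANGE_HIGH)
    vol = ImageVolume(adc, spec.spacing_mm)
    mask = RoiMask(inside, spec.spacing_mm)
    return vol, mask


@dataclass(frozen=True)
class DwiSeries:
    """Multi-b diffusion-weighted series on one common grid."""

    volumes: tuple[ImageVolume, ...]
    b_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.b_values):
            raise ValueError("one volume per b value required")
        if len(set(self.b_values)) < 2:
            raise ValueError(
                f"at least 2 distinct b values required (slope undefined), got {self.b_values}"
            )
        if any(b < 0 for b in self.b_values):
            raise ValueError(f"b values must be non-negative, got {self.b_values}")
        ref = self.volumes[0]
        for v in self.volumes[1:]:
            if not ref.same_grid(v):
                raise ValueError("all DWI volumes must share shape, spacing and origin")
        object.__setattr__(self, "volumes", tuple(self.volumes))
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))


def generate_dwi(
    adc: ImageVolume,
    s0: float,
    b_values,
    rician_sigma: float = 0.0,
    seed: int = 0,
) -> DwiSeries:
    """Simulate a DWI series from an ADC map by mono-exponential decay.

    Per voxel and b value, the noiseless signal is ``S = s0 * exp(-b * ADC)``.
    Rician noise of scale ``rician_sigma`` is applied as independent Gaussian
    perturbations on both quadrature channels; ``rician_sigma=0`` returns the
    exact decay.
    """
    b_values = [float(b) for b in b_values]
    if len(set(b_values)) < 2:
        raise ValueError("at least 2 distinct b values required (slope undefined)")
    if any(b < 0 for b in b_values):
        raise ValueError("b values must be non-negative")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    rng = np.random.default_rng(seed)
    vols = []
    for b in b_values:
        signal = s0 * np.exp(-b * adc.voxels)
        if rician_sigma > 0:
            re = signal + rng.normal(0.0, rician_sigma, adc.shape)
            im = rng.normal(0.0, rician_sigma, adc.shape)
            signal = np.hypot(re, im)
        vols.append(ImageVolume(signal, adc.spacing_mm, adc.origin_mm))
    return DwiSeries(tuple(vols), tuple(b_values))


@dataclass(frozen=True)
class CohortVariation:
    """Per-subject jitter applied to a template :class:`PhantomSpec`.

    ``radii_frac`` draws a single multiplicative factor per subject uniform
    in ``1 +/- radii_frac`` applied to all three semi-axes; ``mean_sd``
    perturbs lesion and background means with independent Gaussian draws.
    """

    radii_frac: float = 0.15
    mean_sd: float = 8.0e-5


def generate_cohort(
    n_subjects: int,
    spec_template: PhantomSpec = PhantomSpec(),
    variation: CohortVariation = CohortVariation(),
    seed: int = 0,
) -> list[tuple[ImageVolume, RoiMask]]:
    """Generate a cohort of phantom subjects with per-subject jitter.

    Subject ``i`` consumes the deterministic substream ``seed + i`` for its
    jitter and its texture noise, so cohorts are reproducible and individual
    subjects can be regenerated in isolation.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects (ICC is undefined below that)")
    cohort = []
    for i in range(n_subjects):
        sub_seed = int(seed) + i
        rng = np.random.default_rng(sub_seed)
        factor = 1.0 + variation.radii_frac * rng.uniform(-1.0, 1.0)
        radii = tuple(r * factor for r in spec_template.lesion_radii_vox)
        lesion_mean = spec_template.lesion_mean + variation.mean_sd * rng.standard_normal()
        background_mean = spec_template.background_mean + variation.mean_sd * rng.standard_normal()
        spec = replace(
            spec_template,
            lesion_radii_vox=radii,
            lesion_mean=float(lesion_mean),
            background_mean=float(background_mean),
            seed=sub_seed,
        )
        try:
            cohort.append(generate_phantom(spec))
        except ValueError as exc:
            raise ValueError(f"subject {i}: jitter produced an invalid phantom spec: {exc}") from exc
    return cohort


def write_cohort(cohort, out_dir, specs=None) -> Path:
    """Persist a cohort as NIfTI-1 files plus a JSON manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for i, (vol, mask) in enumerate(cohort):
        vid = f"subject_{i:03d}"
        vol_path = out_dir / f"{vid}_adc.nii.gz"
        mask_path = out_dir / f"{vid}_mask.nii.gz"
        write_nifti(vol, vol_path)
        write_nifti(mask, mask_path)
        entry = {"adc": vol_path.name, "mask": mask_path.name}
        if specs is not None:
            s = specs[i]
            entry["ground_truth"] = {
                "lesion_mean": s.lesion_mean,
                "background_mean": s.background_mean,
                "lesion_radii_vox": list(s.lesion_radii_vox),
                "noise_sd": s.noise_sd,
                "seed": s.seed,
            }
        manifest[vid] = entry
    manifest_path = out_dir / "cohort_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
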