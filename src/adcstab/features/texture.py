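"""Gray-level co-occurrence and run-length matrices and their features.

Both matrices are built on the discretized ADC values (1-based bin indices
serve as gray levels) at distance rho = 1, measured in voxel index steps —
anisotropic spacing is ignored for adjacency, the standard texture-matrix
convention.  A voxel pair is counted only when both ends lie inside the ROI
mask; runs are confined to in-mask collinear segments and truncate at the
mask boundary.

Feature dialect
---------------
GLCM features follow the Haralick-style catalog with four distinct
inverse-difference variants (the plain and squared-difference forms plus
their level-normalized counterparts); inertia and contrast are separate
named outputs sharing the classical sum of squared level differences.
GLRLM features follow the Galloway/Chu run-length definitions.  Log terms
use the 0*log(0) = 0 convention with base-2 logarithms.  Degenerate
matrices (no valid pair/run in a direction) yield NaN markers for every
feature, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import ImageVolume, RoiMask
from .binning import BinningSpec, discretize
from .catalog import GLCM_NAMES, GLRLM_NAMES


@dataclass(frozen=True)
class TextureMatrix:
    """A GLCM (N x N probabilities) or GLRLM (N x R run counts) for one direction."""

    kind: str  # "GLCM" | "GLRLM"
    matrix: np.ndarray
    direction: tuple[int, int, int]
    n_levels: int
    degenerate: bool = False
    n_voxels_traversed: int = 0  # GLRLM only: in-mask voxels covered by the runs


def _check_grid(volume: ImageVolume, mask: RoiMask) -> None:
    if not mask.same_grid(volume):
        raise ValueError("mask and volume must share the same grid")


def _binned(volume: ImageVolume, binning: BinningSpec) -> np.ndarray:
    idx, _, _ = discretize(volume.voxels, binning)
    return idx


def _shift_slices(shape, d):
    """Source/target slice pairs so that src voxel v pairs with tgt voxel v + d."""
    src, tgt = [], []
    for n, step in zip(shape, d):
        if step >= 0:
            src.append(slice(0, n - step))
            tgt.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            tgt.append(slice(0, n + step))
    return tuple(src), tuple(tgt)


def build_glcm(
    volume: ImageVolume, mask: RoiMask, binning: BinningSpec, direction
) -> TextureMatrix:
    """Build the symmetric, normalized co-occurrence matrix for one offset.

    Element (i, j) is the probability that a pair of in-mask voxels one step
    apart along ``direction`` has gray levels (i+1, j+1); each pair is
    counted in both orders, so the matrix is symmetric and sums to 1.
    """
    _check_grid(volume, mask)
    d = tuple(int(c) for c in direction)
    bins = _binned(volume, binning)
    N = binning.n_bins
    src, tgt = _shift_slices(volume.shape, d)
    valid = mask.voxels[src] & mask.voxels[tgt]
    i = bins[src][valid] - 1
    j = bins[tgt][valid] - 1
    if i.size == 0:
        return TextureMatrix("GLCM", np.zeros((N, N)), d, N, degenerate=True)
    counts = np.bincount(i * N + j, minlength=N * N).reshape(N, N).astype(float)
    counts = counts + counts.T  # count each ordered pair in both orders
    return TextureMatrix("GLCM", counts / counts.sum(), d, N)


def build_glrlm(
    volume: ImageVolume, mask: RoiMask, binning: BinningSpec, direction
) -> TextureMatrix:
    """Build the run-length matrix for one offset.

    Element (i, j) counts the maximal runs of j+1 consecutive in-mask voxels
    of gray level i+1 along ``direction``; runs truncate at the mask
    boundary.  Every in-mask voxel belongs to exactly one run, so
    sum_ij (j+1) * matrix[i, j] equals the mask voxel count.
    """
    _check_grid(volume, mask)
    d = tuple(int(c) for c in direction)
    bins = _binned(volume, binning)
    N = binning.n_bins
    coords = np.argwhere(mask.voxels)  # (M, 3)
    if coords.shape[0] == 0:
        return TextureMatrix("GLRLM", np.zeros((N, 1)), d, N, degenerate=True)
    g = bins[mask.voxels]
    dv = np.asarray(d)
    axis = int(np.nonzero(dv)[0][0])
    # position along the line and a per-line invariant key
    t = coords[:, axis] * dv[axis]
    key = coords - t[:, None] * dv[None, :]
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    t_s, key_s, g_s = t[order], key[order], g[order]
    new_run = np.ones(t_s.size, dtype=bool)
    if t_s.size > 1:
        same_line = np.all(key_s[1:] == key_s[:-1], axis=1)
        contiguous = t_s[1:] == t_s[:-1] + 1
        same_gray = g_s[1:] == g_s[:-1]
        new_run[1:] = ~(same_line & contiguous & same_gray)
    run_id = np.cumsum(new_run) - 1
    run_len = np.bincount(run_id)
    run_gray = g_s[new_run]
    R = int(run_len.max())
    counts = np.zeros((N, R), dtype=float)
    np.add.at(counts, (run_gray - 1, run_len - 1), 1.0)
    return TextureMatrix("GLRLM", counts, d, N, n_voxels_traversed=coords.shape[0])


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(glcm: TextureMatrix) -> dict[str, float]:
    """The 21 co-occurrence features of one normalized GLCM."""
    if glcm.kind != "GLCM":
        raise ValueError("expected a GLCM")
    if glcm.degenerate:
        return {name: float("nan") for name in GLCM_NAMES}
    p = glcm.matrix
    N = glcm.n_levels
    lv = np.arange(1, N + 1, dtype=float)
    ii = lv[:, None]
    jj = lv[None, :]
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.dot(lv, px))
    var = float(np.dot((lv - mu) ** 2, px))
    sigma = np.sqrt(var)

    diff = np.abs(ii - jj)
    diff2 = (ii - jj) ** 2
    ssq = float(np.sum(diff2 * p))  # classical contrast/inertia

    # p_{x+y}(k), k = 2..2N and p_{x-y}(k), k = 0..N-1
    ksum = (ii + jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * N + 1)[2:]
    kdiff = diff.astype(int)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=N)

    hxy = float(-np.sum(_xlog2(p)))
    pxy = px[:, None] * px[None, :]
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-np.sum(p * log_pxy))
    hxy2 = float(-np.sum(_xlog2(pxy)))
    hx = float(-np.sum(_xlog2(px)))

    acorr = float(np.sum(ii * jj * p))
    corr = (acorr - mu * mu) / var if var > 0 else float("nan")
    imoc1 = (hxy - hxy1) / hx if hx > 0 else float("nan")
    imoc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = diff2 > 0
    inv_var = float(np.sum(p[off] / diff2[off]))

    ks = np.arange(2, 2 * N + 1, dtype=float)
    return {
        "glcm_autocorrelation": acorr,
        "glcm_cluster_prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "glcm_cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "glcm_cluster_tendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "glcm_contrast": ssq,
        "glcm_correlation": corr,
        "glcm_difference_entropy": float(-np.sum(_xlog2(p_diff))),
        "glcm_dissimilarity": float(np.sum(diff * p)),
        "glcm_energy": float(np.sum(p**2)),
        "glcm_entropy": hxy,
        "glcm_homogeneity": float(np.sum(p / (1.0 + diff))),
        "glcm_homogeneity_2": float(np.sum(p / (1.0 + diff2))),
        "glcm_imoc1": imoc1,
        "glcm_imoc2": imoc2,
        "glcm_inverse_difference_moment": float(np.sum(p / (1.0 + diff / N))),
        "glcm_inverse_difference_moment_2": float(np.sum(p / (1.0 + diff2 / N**2))),
        "glcm_inertia": ssq,
        "glcm_inverse_variance": inv_var,
        "glcm_max_probability": float(p.max()),
        "glcm_sum_average": float(np.dot(ks, p_sum)),
        "glcm_sum_entropy": float(-np.sum(_xlog2(p_sum))),
    }


def glrlm_features(glrlm: TextureMatrix) -> dict[str, float]:
    """The 11 run-length features of one GLRLM."""
    if glrlm.kind != "GLRLM":
        raise ValueError("expected a GLRLM")
    r = glrlm.matrix
    n_runs = float(r.sum())
    if glrlm.degenerate or n_runs == 0:
        return {name: float("nan") for name in GLRLM_NAMES}
    N, R = r.shape
    i2 = (np.arange(1, N + 1, dtype=float) ** 2)[:, None]
    j2 = (np.arange(1, R + 1, dtype=float) ** 2)[None, :]
    np_vox = float(glrlm.n_voxels_traversed)
    return {
        "glrlm_gray_level_nonuniformity": float(np.sum(r.sum(axis=1) ** 2) / n_runs),
        "glrlm_high_gray_level_emphasis": float(np.sum(r * i2) / n_runs),
        "glrlm_long_run_emphasis": float(np.sum(r * j2) / n_runs),
        "glrlm_long_run_high_gray_level_emphasis": float(np.sum(r * i2 * j2) / n_runs),
        "glrlm_long_run_low_gray_level_emphasis": float(np.sum(r * j2 / i2) / n_runs),
        "glrlm_low_gray_level_emphasis": float(np.sum(r / i2) / n_runs),
        "glrlm_run_length_nonuniformity": float(np.sum(r.sum(axis=0) ** 2) / n_runs),
        "glrlm_run_percentage": n_runs / np_vox,
        "glrlm_short_run_emphasis": float(np.sum(r / j2) / n_runs),
        "glrlm_short_run_high_gray_level_emphasis": float(np.sum(r * i2 / j2) / n_runs),
        "glrlm_short_run_low_gray_level_emphasis": float(np.sum(r / (i2 * j2)) / n_runs),
    }
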