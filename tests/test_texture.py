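"""Direction set, texture matrices and their features vs brute-force oracles."""

import numpy as np
import pytest

from adcstab import ImageVolume, RoiMask
from adcstab.features import (
    BinningSpec,
    build_glcm,
    build_glrlm,
    direction_set,
    glcm_features,
    glrlm_features,
)
from adcstab.features.catalog import GLCM_NAMES, GLRLM_NAMES
from adcstab.features.texture import TextureMatrix

from conftest import random_roi_fixture
from oracles import (
    glcm_features_oracle,
    glcm_oracle,
    glrlm_features_oracle,
    glrlm_oracle,
)

B4 = BinningSpec(4, 0.0, 4e-3)  # bin width 1e-3


class TestDirections:
    def test_thirteen_unique_non_antiparallel_offsets(self):
        dirs = direction_set()
        assert len(dirs) == 13
        assert (1, 0, 0) in dirs and (1, 1, 1) in dirs
        assert (0, 0, 0) not in dirs
        for d in dirs:
            assert tuple(-c for c in d) not in dirs

    def test_union_with_negations_covers_26_neighborhood(self):
        dirs = direction_set()
        full = set(dirs) | {tuple(-c for c in d) for d in dirs}
        assert len(full) == 26


class TestGlcm:
    def test_strip_pair_counts(self, strip_volume_mask):
        vol, mask = strip_volume_mask
        glcm = build_glcm(vol, mask, B4, (1, 0, 0))
        # bins [1,1,2]: ordered pairs (1,1),(1,2) counted both ways -> 4 total
        expected = np.zeros((4, 4))
        expected[0, 0] = 2 / 4
        expected[0, 1] = expected[1, 0] = 1 / 4
        assert np.allclose(glcm.matrix, expected)

    def test_constant_roi_single_diagonal_entry(self):
        vol = ImageVolume(np.full((4, 4, 4), 0.3e-3))
        mask = RoiMask(np.ones((4, 4, 4), dtype=bool))
        glcm = build_glcm(vol, mask, B4, (1, 0, 0))
        assert glcm.matrix[0, 0] == 1.0
        assert glcm.matrix.sum() == 1.0

    def test_single_voxel_roi_degenerate(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        glcm = build_glcm(ImageVolume(np.ones((3, 3, 3)) * 1e-3), RoiMask(m), B4, (1, 0, 0))
        assert glcm.degenerate
        assert np.all(glcm.matrix == 0)
        feats = glcm_features(glcm)
        assert all(np.isnan(v) for v in feats.values())

    def test_point_mass_features(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = glcm_features(TextureMatrix("GLCM", p, (1, 0, 0), 4))
        assert f["glcm_energy"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_max_probability"] == 1.0
        assert f["glcm_contrast"] == 0.0

    def test_uniform_2x2_features(self):
        p = np.full((2, 2), 0.25)
        f = glcm_features(TextureMatrix("GLCM", p, (1, 0, 0), 2))
        assert f["glcm_energy"] == pytest.approx(0.25)
        assert f["glcm_entropy"] == pytest.approx(2.0)  # bits

    def test_normalization_symmetry_and_bounds(self, rng):
        for _ in range(10):
            bins, mask = random_roi_fixture(rng)
            vol = ImageVolume((bins - 0.5) * 1e-3)
            glcm = build_glcm(vol, RoiMask(mask), B4, (1, 1, 0))
            if glcm.degenerate:
                continue
            assert glcm.matrix.sum() == pytest.approx(1.0)
            assert np.allclose(glcm.matrix, glcm.matrix.T)
            f = glcm_features(glcm)
            assert f["glcm_entropy"] >= 0
            assert 0 <= f["glcm_energy"] <= 1
            assert 0 < f["glcm_max_probability"] <= 1


class TestGlrlm:
    def test_strip_runs(self, strip_volume_mask):
        vol, mask = strip_volume_mask
        glrlm = build_glrlm(vol, mask, B4, (1, 0, 0))
        # runs: gray 1 length 2, gray 2 length 1
        assert glrlm.matrix[0, 1] == 1
        assert glrlm.matrix[1, 0] == 1
        assert glrlm.matrix.sum() == 2

    def test_constant_collinear_roi_is_one_run(self):
        m = np.zeros((6, 3, 3), dtype=bool)
        m[:, 1, 1] = True
        vol = ImageVolume(np.full((6, 3, 3), 0.2e-3))
        glrlm = build_glrlm(vol, RoiMask(m), B4, (1, 0, 0))
        assert glrlm.matrix[0, 5] == 1
        assert glrlm.matrix.sum() == 1

    def test_run_length_conservation_every_direction(self, rng):
        bins, mask = random_roi_fixture(rng, shape=(6, 5, 4))
        vol = ImageVolume((bins - 0.5) * 1e-3)
        for d in direction_set():
            glrlm = build_glrlm(vol, RoiMask(mask), B4, d)
            lengths = np.arange(1, glrlm.matrix.shape[1] + 1)
            assert np.sum(glrlm.matrix * lengths) == mask.sum()

    def test_single_run_features(self):
        mat = np.zeros((4, 1))
        mat[2, 0] = 1
        f = glrlm_features(TextureMatrix("GLRLM", mat, (1, 0, 0), 4, n_voxels_traversed=1))
        assert f["glrlm_short_run_emphasis"] == 1.0
        assert f["glrlm_long_run_emphasis"] == 1.0
        assert f["glrlm_run_percentage"] == 1.0

    def test_all_unit_runs_give_sre_one(self):
        mat = np.zeros((4, 3))
        mat[:, 0] = [3, 1, 4, 2]
        f = glrlm_features(TextureMatrix("GLRLM", mat, (1, 0, 0), 4, n_voxels_traversed=10))
        assert f["glrlm_short_run_emphasis"] == 1.0


class TestOracleSuites:
    """Every texture feature vs the scalar brute-force oracles on >= 50
    random 5x5x3 fixtures, to 1e-10 relative."""

    N_FIXTURES = 50

    def _fixtures(self):
        rng = np.random.default_rng(1234)
        dirs = direction_set()
        for k in range(self.N_FIXTURES):
            bins, mask = random_roi_fixture(rng, shape=(5, 5, 3), n_levels=4)
            vol = ImageVolume((bins - 0.5) * 1e-3)
            yield bins, mask, vol, dirs[k % len(dirs)]

    def test_glcm_features_match_oracle(self):
        checked = 0
        for bins, mask, vol, d in self._fixtures():
            glcm = build_glcm(vol, RoiMask(mask), B4, d)
            p_oracle = glcm_oracle(bins, mask, d, 4)
            if glcm.degenerate:
                assert p_oracle is None
                continue
            assert np.allclose(glcm.matrix, np.array(p_oracle), atol=1e-15)
            got = glcm_features(glcm)
            want = glcm_features_oracle(p_oracle)
            for name in GLCM_NAMES:
                if np.isnan(want[name]):
                    assert np.isnan(got[name])
                else:
                    assert got[name] == pytest.approx(want[name], rel=1e-10, abs=1e-12), name
            checked += 1
        assert checked >= 45

    def test_glrlm_features_match_oracle(self):
        for bins, mask, vol, d in self._fixtures():
            glrlm = build_glrlm(vol, RoiMask(mask), B4, d)
            mat_oracle, n_vox = glrlm_oracle(bins, mask, d, 4)
            assert np.allclose(glrlm.matrix, np.array(mat_oracle))
            assert glrlm.n_voxels_traversed == n_vox
            got = glrlm_features(glrlm)
            want = glrlm_features_oracle(mat_oracle, n_vox)
            for name in GLRLM_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-10), name
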