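"""GLCM, run-length and GTDM features against brute-force enumerators."""

import numpy as np
import pytest

from dcect_radiomics.features import (
    discretize_intensities, glcm_features, glcm_matrix,
    run_length_features, run_length_matrix, gtdm_features,
)
from dcect_radiomics.features.glcm import _features_from_matrix, DIRECTIONS_2D
from dcect_radiomics.features.runlength import (run_length_features_single,
                                                DIRECTIONS_2D as RL_DIRS)
from dcect_radiomics.features.quantize import QuantizedVolume

from conftest import random_small_quantized
from _oracles import (glcm_matrix_bruteforce, glcm_features_bruteforce,
                      runs_bruteforce, run_length_features_bruteforce,
                      gtdm_features_bruteforce)


def _const_q(value=3, shape=(1, 4, 4)):
    labels = np.full(shape, 1)
    mask = np.ones(shape, bool)
    return QuantizedVolume(labels, mask, 1, 25.0, float(value))


class TestGLCM:
    def test_constant_voi_limits(self):
        f = glcm_features(_const_q())
        assert f["GLCM Contrast"] == 0
        assert f["GLCM ASM"] == 1
        assert f["GLCM Max Prob"] == 1
        assert f["GLCM Entropy"] == 0

    def test_checkerboard_contrast_one(self):
        """Distance-1 axial/vertical pairs of a two-level checkerboard all
        differ by one level, so Contrast = 1 in those directions."""
        board = (np.indices((4, 4)).sum(axis=0) % 2) + 1
        mask = np.ones((4, 4), bool)
        for d in ((0, 1), (1, 0)):
            mat = glcm_matrix(board, mask, d, 2)
            f = _features_from_matrix(mat)
            oracle = glcm_features_bruteforce(glcm_matrix_bruteforce(board, mask, d, 2))
            assert f["GLCM Contrast"] == pytest.approx(1.0)
            assert f["GLCM Contrast"] == pytest.approx(oracle["GLCM Contrast"])

    def test_bounds_properties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            q = random_small_quantized(rng)
            try:
                f = glcm_features(q)
            except ValueError:
                continue
            assert 0 < f["GLCM ASM"] <= 1
            assert f["GLCM Entropy"] >= 0
            assert 0 < f["GLCM Max Prob"] <= 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        q = random_small_quantized(rng)
        for z in range(q.labels.shape[0]):
            for d in DIRECTIONS_2D:
                mine = glcm_matrix(q.labels[z], q.mask[z], d, q.n_levels)
                ref = glcm_matrix_bruteforce(q.labels[z], q.mask[z], d, q.n_levels)
                if mine is None:
                    assert ref is None
                    continue
                assert np.allclose(mine, ref, rtol=1e-12)
                f = _features_from_matrix(mine)
                g = glcm_features_bruteforce(ref)
                for k, v in g.items():
                    assert f[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k


class TestRunLength:
    def test_single_run_closed_form(self):
        n = 7
        row = np.ones((1, n), int)
        mask = np.ones((1, n), bool)
        mat = run_length_matrix(row, mask, (0, 1), 1)
        f = run_length_features_single(mat, n)
        assert f["RLR Emphasis"] == pytest.approx(n ** 2)
        assert f["RSR Emphasis"] == pytest.approx(1 / n ** 2)

    def test_alternating_row_all_short(self):
        row = np.array([[1, 2, 1, 2, 1, 2]])
        mask = np.ones_like(row, bool)
        f = run_length_features_single(run_length_matrix(row, mask, (0, 1), 2), 6)
        assert f["RSR Emphasis"] == pytest.approx(1.0)
        assert f["RLR Emphasis"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_run_listing(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = random_small_quantized(rng)
        for z in range(q.labels.shape[0]):
            for d in RL_DIRS:
                mat = run_length_matrix(q.labels[z], q.mask[z], d, q.n_levels)
                runs = runs_bruteforce(q.labels[z], q.mask[z], d)
                assert mat.sum() == len(runs)  # run count conserved
                # row/col sums against the explicit run listing
                for g in range(1, q.n_levels + 1):
                    assert mat[g - 1].sum() == sum(1 for rg, _ in runs if rg == g)
                if runs:
                    f = run_length_features_single(mat, int(q.mask[z].sum()))
                    g = run_length_features_bruteforce(runs, int(q.mask[z].sum()))
                    for k, v in g.items():
                        assert f[k] == pytest.approx(v, rel=1e-9), k


class TestGTDM:
    def test_constant_voi_zero_strength_complexity(self):
        f = gtdm_features(_const_q())
        assert f["GTDM Strength"] == 0
        assert f["GTDM Complexity"] == 0

    def test_single_center_hand_example(self):
        """3x3 slice, center level 2 in a field of 1s: s_2 = |2 - 1| = 1."""
        labels = np.ones((1, 3, 3), int)
        labels[0, 1, 1] = 2
        mask = np.ones((1, 3, 3), bool)
        q = QuantizedVolume(labels, mask, 2, 25.0, 0.0)
        from dcect_radiomics.features.gtdm import gtdm_matrix
        s, n = gtdm_matrix(q)
        assert s[2] == pytest.approx(1.0)
        assert n[2] == 1 and n[1] == 8
        mine = gtdm_features(q)
        ref = gtdm_features_bruteforce(labels, mask)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, rel=1e-9), k

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_enumerator(self, seed):
        rng = np.random.default_rng(200 + seed)
        q = random_small_quantized(rng)
        try:
            mine = gtdm_features(q)
        except ValueError:
            return
        ref = gtdm_features_bruteforce(q.labels, q.mask)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_shift_invariance_via_binning(self):
        rng = np.random.default_rng(3)
        vol = rng.uniform(0, 150, (2, 6, 6))
        mask = np.ones((2, 6, 6), bool)
        f1 = gtdm_features(discretize_intensities(vol, mask))
        f2 = gtdm_features(discretize_intensities(vol + 500.0, mask))
        assert f1 == f2
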