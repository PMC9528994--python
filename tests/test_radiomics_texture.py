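"""Texture matrices vs brute-force enumeration oracles on tiny ROIs."""

import itertools

import numpy as np
import pytest

from fwlomics.core import BinaryMask, ScalarVolume
from fwlomics.radiomics import discretize_fixed_bin_count, texture_features
from fwlomics.radiomics.texture import (
    ANGLES,
    FAMILY_NAMES,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)


def _disc(levels):
    """Wrap an integer level array as a DiscretizedROI (identity binning)."""
    levels = np.asarray(levels)
    if levels.ndim == 2:
        levels = levels[..., None]
    vol = ScalarVolume(levels.astype(float))
    mask = BinaryMask(levels > 0)
    nb = max(int(levels.max()), 2)
    return discretize_fixed_bin_count(vol, mask, nb)


# ---------------------------------------------------------------------------
# Brute-force oracles (explicit python loops)
# ---------------------------------------------------------------------------

def oracle_glcm(levels, mask, offset, vals):
    idx = {v: i for i, v in enumerate(vals)}
    ng = len(vals)
    P = np.zeros((ng, ng))
    it = np.ndindex(*levels.shape)
    for pos in it:
        for sgn in (1, -1):
            nb = tuple(p + sgn * o for p, o in zip(pos, offset))
            if any(c < 0 or c >= s for c, s in zip(nb, levels.shape)):
                continue
            if mask[pos] and mask[nb]:
                P[idx[levels[pos]], idx[levels[nb]]] += 1
    return P


def oracle_runs(levels, mask, offset):
    """All maximal runs (level, length) along +-offset lines."""
    shape = levels.shape
    runs = []
    visited = set()
    for start in np.ndindex(*shape):
        prev = tuple(p - o for p, o in zip(start, offset))
        inside = all(0 <= c < s for c, s in zip(prev, shape))
        if inside:
            continue  # not a line start
        # walk the line
        pos = start
        line = []
        while all(0 <= c < s for c, s in zip(pos, shape)):
            line.append(pos)
            pos = tuple(p + o for p, o in zip(pos, offset))
        seq = [(levels[p] if mask[p] else 0) for p in line]
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if seq[i] > 0:
                runs.append((seq[i], j - i))
            i = j
    return runs


def oracle_zones(levels, mask, g):
    """Sizes of 26-connected components of level g (BFS)."""
    todo = {tuple(p) for p in np.argwhere((levels == g) & True)}
    sizes = []
    while todo:
        stack = [todo.pop()]
        size = 0
        while stack:
            pos = stack.pop()
            size += 1
            for off in itertools.product((-1, 0, 1), repeat=3):
                if off == (0, 0, 0):
                    continue
                nb = tuple(p + o for p, o in zip(pos, off))
                if nb in todo:
                    todo.remove(nb)
                    stack.append(nb)
        sizes.append(size)
    return sorted(sizes)


def oracle_dependence(levels, mask, pos, alpha=0):
    dep = 1
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        nb = tuple(p + o for p, o in zip(pos, off))
        if any(c < 0 or c >= s for c, s in zip(nb, levels.shape)):
            continue
        if mask[nb] and abs(int(levels[nb]) - int(levels[pos])) <= alpha:
            dep += 1
    return dep


def _rand_levels(seed, shape=(3, 3, 3), ng=3):
    rng = np.random.default_rng(seed)
    return rng.integers(1, ng + 1, size=shape)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_hand_enumerated_2x2_plane(self):
        lv = np.array([[1, 2], [2, 1]])[..., None]
        d = _disc(lv)
        mats, vals = glcm_matrices(d.levels, d.mask)
        np.testing.assert_array_equal(vals, [1, 2])
        # in-plane x-offset (1,0,0): pairs (1,2),(2,1) twice -> symmetric
        k = ANGLES.index((1, 0, 0))
        np.testing.assert_array_equal(mats[k], [[0, 2], [2, 0]])
        # main diagonal (1,1,0): the single (1,1) pair, counted both ways
        k = ANGLES.index((1, 1, 0))
        np.testing.assert_array_equal(mats[k], [[2, 0], [0, 0]])
        # anti-diagonal (1,-1,0): the single (2,2) pair
        k = ANGLES.index((1, -1, 0))
        np.testing.assert_array_equal(mats[k], [[0, 0], [0, 2]])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pair_counting_oracle(self, seed):
        lv = _rand_levels(seed)
        mask = _rand_levels(seed + 100, ng=2) > 1
        lv = np.where(mask, lv, 0)
        if not mask.any():
            pytest.skip("empty mask draw")
        d_levels = lv
        mats, vals = glcm_matrices(d_levels, mask)
        for k, off in enumerate(ANGLES):
            np.testing.assert_array_equal(
                mats[k], oracle_glcm(d_levels, mask, off, list(vals))
            )

    def test_constant_roi_degenerate(self):
        d = _disc(np.full((2, 2, 2), 1))
        f = texture_features(d, "glcm")
        assert f["JointEntropy"] == 0.0
        assert f["MaximumProbability"] == 1.0
        assert f["Contrast"] == 0.0


class TestGLRLM:
    def test_single_row_single_run(self):
        lv = np.zeros((5, 1, 1), dtype=int)
        lv[:, 0, 0] = 2
        d = _disc(lv)
        mats, vals = glrlm_matrices(d.levels, d.mask)
        k = ANGLES.index((1, 0, 0))
        assert mats[k][0, 4] == 1  # one run of length 5
        assert mats[k].sum() == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_run_oracle(self, seed):
        lv = _rand_levels(seed, shape=(3, 3, 2))
        mask = lv > 0
        mats, vals = glrlm_matrices(lv, mask)
        vidx = {v: i for i, v in enumerate(vals)}
        for k, off in enumerate(ANGLES):
            expected = np.zeros_like(mats[k])
            for level, length in oracle_runs(lv, mask, off):
                expected[vidx[level], length - 1] += 1
            np.testing.assert_array_equal(mats[k], expected)

    def test_feature_sre_formula(self):
        lv = _rand_levels(7)
        d = _disc(lv)
        f = texture_features(d, "glrlm")
        mats, vals = glrlm_matrices(d.levels, d.mask)
        sre = []
        for P in mats:
            nr = P.sum()
            acc = sum(
                P[i, j] / (j + 1) ** 2
                for i in range(P.shape[0])
                for j in range(P.shape[1])
            )
            sre.append(acc / nr)
        assert f["ShortRunEmphasis"] == pytest.approx(np.mean(sre))


class TestGLSZM:
    def test_constant_roi_one_zone(self):
        d = _disc(np.full((2, 3, 2), 1))
        P, vals = glszm_matrix(d.levels, d.mask)
        assert P.sum() == 1
        assert P[0, 11] == 1  # one 12-voxel zone

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bfs_zone_oracle(self, seed):
        lv = _rand_levels(seed)
        mask = lv > 0
        P, vals = glszm_matrix(lv, mask)
        for gi, g in enumerate(vals):
            sizes = oracle_zones(lv, mask, g)
            expected = np.zeros(P.shape[1])
            for s in sizes:
                expected[s - 1] += 1
            np.testing.assert_array_equal(P[gi], expected)


class TestGLDM:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_neighbour_count_oracle(self, seed):
        lv = _rand_levels(seed)
        mask = _rand_levels(seed + 50, ng=4) > 1
        lv = np.where(mask, lv, 0)
        if not mask.any():
            pytest.skip("empty mask draw")
        P, vals = gldm_matrix(lv, mask)
        vidx = {v: i for i, v in enumerate(vals)}
        expected = np.zeros_like(P)
        for pos in np.argwhere(mask):
            pos = tuple(pos)
            dep = oracle_dependence(lv, mask, pos)
            expected[vidx[lv[pos]], dep - 1] += 1
        np.testing.assert_array_equal(P, expected)


class TestNGTDM:
    def test_matches_hand_computation_2d(self):
        # 3x3 single-slice example, all voxels in ROI
        lv = np.array([[1, 2, 2], [3, 1, 1], [1, 1, 1]])[..., None]
        mask = np.ones_like(lv, dtype=bool)
        n_i, p_i, s_i, vals = ngtdm_table(lv, mask)
        # per-voxel neighbour means computed by hand loops
        s_expected = np.zeros(len(vals))
        vidx = {v: i for i, v in enumerate(vals)}
        for pos in np.argwhere(mask):
            pos = tuple(pos)
            nbs = []
            for off in itertools.product((-1, 0, 1), repeat=3):
                if off == (0, 0, 0):
                    continue
                nb = tuple(p + o for p, o in zip(pos, off))
                if all(0 <= c < s for c, s in zip(nb, lv.shape)):
                    nbs.append(lv[nb])
            s_expected[vidx[lv[pos]]] += abs(lv[pos] - np.mean(nbs))
        np.testing.assert_allclose(s_i, s_expected)
        np.testing.assert_allclose(n_i, [6, 2, 1])

    def test_constant_roi_coarseness_capped(self):
        d = _disc(np.full((2, 2, 2), 3))
        f = texture_features(d, "ngtdm")
        assert f["Coarseness"] == 1e6
        assert f["Contrast"] == 0.0


class TestFamilyContracts:
    @pytest.mark.parametrize("family", FAMILY_NAMES)
    def test_name_sets_and_counts(self, family):
        d = _disc(_rand_levels(1))
        f = texture_features(d, family)
        assert tuple(f) == FAMILY_NAMES[family]

    def test_family_sizes(self):
        sizes = {k: len(v) for k, v in FAMILY_NAMES.items()}
        assert sizes == {"glcm": 22, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=(4, 4, 4))
        vol1 = ScalarVolume(x)
        vol2 = ScalarVolume(x + 57.3)
        mask = BinaryMask(np.ones_like(x, dtype=bool))
        d1 = discretize_fixed_bin_count(vol1, mask, 8)
        d2 = discretize_fixed_bin_count(vol2, mask, 8)
        for family in FAMILY_NAMES:
            f1 = texture_features(d1, family)
            f2 = texture_features(d2, family)
            for k in f1:
                assert f1[k] == pytest.approx(f2[k]), (family, k)

    def test_single_voxel_roi_degenerate_not_crashing(self):
        lv = np.zeros((3, 3, 3), dtype=int)
        lv[1, 1, 1] = 1
        d = _disc(lv)
        for family in FAMILY_NAMES:
            f = texture_features(d, family)
            assert all(np.isfinite(v) for v in f.values()), family
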