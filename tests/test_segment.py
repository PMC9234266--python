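"""Atlas selection and joint label fusion, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from striatseg.imgio import LabelVolume, Volume
from striatseg.segment import (
    FusionParams,
    joint_label_fusion,
    mse,
    select_atlases,
    solve_fusion_weights,
)

AFF = np.eye(4)


class TestMSE:
    def test_identical_images(self, small_volume):
        assert mse(small_volume, small_volume, np.ones(small_volume.shape)) == 0.0

    def test_constant_offset(self, small_volume):
        other = Volume(small_volume.voxels + 3.0, AFF)
        assert mse(small_volume, other, np.ones(small_volume.shape)) == pytest.approx(9.0)

    def test_hand_case(self):
        a = Volume(np.array([1.0, 2.0]).reshape(2, 1, 1), AFF)
        b = Volume(np.array([3.0, 5.0]).reshape(2, 1, 1), AFF)
        assert mse(a, b, np.ones((2, 1, 1))) == pytest.approx(6.5)

    def test_empty_mask_rejected(self, small_volume):
        with pytest.raises(ValueError, match="empty"):
            mse(small_volume, small_volume, np.zeros(small_volume.shape))


def _toy_db(global_imgs, local_imgs, ids):
    """Assemble a minimal AtlasDatabase from given template-space images."""
    from striatseg.atlasdb import Atlas, AtlasDatabase
    from striatseg.phantom import CAUDATE, PUTAMEN

    shape = global_imgs[0].shape
    codes = np.zeros(shape, dtype=np.int16)
    codes[...] = 1  # brain everywhere
    codes[2:4, 2:4, 2:4] = PUTAMEN
    codes[4:5, 2:4, 2:4] = CAUDATE
    labels = LabelVolume(codes, AFF)
    atlases = [
        Atlas(i, "HC", g, labels, g, l)
        for i, g, l in zip(ids, global_imgs, local_imgs)
    ]
    params = {
        "settings": {"smooth_fwhm_mm": [0, 0, 0], "n_quantiles": 16},
        "global_reference_quantiles": list(np.linspace(0, 1, 16)),
        "local_reference_quantiles": list(np.linspace(0, 1, 16)),
    }
    template = Volume(np.zeros(shape), AFF)
    return AtlasDatabase(template, labels, atlases, params)


class TestSelection:
    shape = (8, 8, 8)

    def _vol(self, value):
        return Volume(np.full(self.shape, float(value)), AFF)

    def test_exact_match_ranks_first_with_zero_mse(self):
        db = _toy_db([self._vol(v) for v in (1, 2, 3)],
                     [self._vol(v) for v in (5, 6, 7)], ["a", "b", "c"])
        sel = select_atlases(self._vol(2), self._vol(6), db)
        assert sel.step1[0] == ("b", 0.0)
        assert sel.step2[0] == ("b", 0.0)

    def test_clamping_when_few_atlases(self):
        db = _toy_db([self._vol(v) for v in (1, 2, 3)],
                     [self._vol(v) for v in (1, 2, 3)], ["a", "b", "c"])
        sel = select_atlases(self._vol(0), self._vol(0), db, k1=10, k2=5)
        assert len(sel.step1) == 3
        assert len(sel.step2) == 3

    def test_globally_poor_atlas_excluded_despite_best_local(self):
        # atlas c: worst global MSE but perfect local match; k1=2 excludes it
        db = _toy_db(
            [self._vol(1), self._vol(2), self._vol(9)],
            [self._vol(4), self._vol(5), self._vol(6)],
            ["a", "b", "c"],
        )
        sel = select_atlases(self._vol(1.4), self._vol(6), db, k1=2, k2=2)
        # hand enumeration: global MSEs a:0.16 b:0.36 c:57.76 -> step1 = [a, b]
        assert sel.step1_ids == ["a", "b"]
        # local MSEs among survivors: a:4, b:1 -> b first; c absent
        assert sel.step2_ids == ["b", "a"]

    def test_ties_break_by_id(self):
        db = _toy_db([self._vol(1)] * 3, [self._vol(1)] * 3, ["z", "m", "a"])
        sel = select_atlases(self._vol(1), self._vol(1), db, k1=2, k2=2)
        assert sel.step1_ids == ["a", "m"]

    def test_k2_greater_than_k1_rejected(self):
        db = _toy_db([self._vol(1)] * 2, [self._vol(1)] * 2, ["a", "b"])
        with pytest.raises(ValueError, match="k2"):
            select_atlases(self._vol(1), self._vol(1), db, k1=2, k2=3)


def _brute_force_jlf(target, atlas_pets, atlas_labels, params):
    """Literal per-voxel implementation of the fusion rule (no shortcuts)."""
    T = np.asarray(target.voxels, dtype=np.float32)
    A = [np.asarray(p.voxels, dtype=np.float32) for p in atlas_pets]
    L = [lab.codes for lab in atlas_labels]
    n = len(A)
    pr, sr = params.patch_radius, params.search_radius
    shape = T.shape
    out = np.zeros(shape, dtype=np.int32)

    def val(arr, i, j, k):
        if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
            return float(arr[i, j, k])
        return 0.0

    patch = list(itertools.product(range(-pr, pr + 1), repeat=3))
    search = list(itertools.product(range(-sr, sr + 1), repeat=3))
    for x, y, z in itertools.product(*map(range, shape)):
        labels_here = [L[i][x, y, z] for i in range(n)]
        if len(set(labels_here)) == 1:
            out[x, y, z] = labels_here[0]
            continue
        Y = np.zeros((n, len(patch)))
        for i in range(n):
            best, best_err = None, np.inf
            for d in search:
                err = 0.0
                for p in patch:
                    err += (
                        val(A[i], x + d[0] + p[0], y + d[1] + p[1], z + d[2] + p[2])
                        - val(T, x + p[0], y + p[1], z + p[2])
                    ) ** 2
                err /= len(patch)
                if err < best_err:
                    best, best_err = d, err
            for pi, p in enumerate(patch):
                a = val(A[i], x + best[0] + p[0], y + best[1] + p[1], z + best[2] + p[2])
                t = val(T, x + p[0], y + p[1], z + p[2])
                Y[i, pi] = abs(a - t) ** params.beta
        M = Y @ Y.T
        w = solve_fusion_weights(M, params.lam)
        codes = sorted(set(labels_here))
        scores = [sum(w[i] for i in range(n) if labels_here[i] == c) for c in codes]
        out[x, y, z] = codes[int(np.argmax(scores))]
    return out


class TestJointLabelFusion:
    def test_unanimous_labels_pass_through(self, rng):
        T = Volume(rng.random((6, 6, 6)), AFF)
        pets = [Volume(rng.random((6, 6, 6)), AFF) for _ in range(3)]
        codes = rng.integers(0, 4, (6, 6, 6))
        labels = [LabelVolume(codes.copy(), AFF) for _ in range(3)]
        out = joint_label_fusion(T, pets, labels)
        np.testing.assert_array_equal(out.codes, codes)

    def test_single_atlas_verbatim(self, rng):
        T = Volume(rng.random((6, 6, 6)), AFF)
        pet = Volume(rng.random((6, 6, 6)), AFF)
        lab = LabelVolume(rng.integers(0, 3, (6, 6, 6)), AFF)
        out = joint_label_fusion(T, [pet], [lab])
        np.testing.assert_array_equal(out.codes, lab.codes)

    def test_two_atlas_hand_case(self):
        # patch radius 0, one voxel: |A1-T| = 1, |A2-T| = 2, beta = 2, lam = 0
        # M = [[1, 2], [2, 4]] (+ eps); solving favors atlas 1 entirely
        T = Volume(np.zeros((1, 1, 1)), AFF)
        A1 = Volume(np.ones((1, 1, 1)), AFF)
        A2 = Volume(np.full((1, 1, 1), 2.0), AFF)
        L1 = LabelVolume(np.full((1, 1, 1), 1), AFF)
        L2 = LabelVolume(np.full((1, 1, 1), 2), AFF)
        out = joint_label_fusion(
            T, [A1, A2], [L1, L2],
            FusionParams(patch_radius=0, search_radius=0, beta=2, lam=0),
        )
        assert out.codes[0, 0, 0] == 1

    def test_equal_errors_reduce_to_majority_vote(self):
        # all |A_i - T| equal -> M proportional to all-ones -> equal weights
        T = Volume(np.zeros((3, 3, 3)), AFF)
        pets = [Volume(np.ones((3, 3, 3)), AFF) for _ in range(3)]
        c1 = np.zeros((3, 3, 3), int); c1[1, 1, 1] = 5
        c2 = np.zeros((3, 3, 3), int); c2[1, 1, 1] = 5
        c3 = np.zeros((3, 3, 3), int); c3[1, 1, 1] = 7
        labels = [LabelVolume(c, AFF) for c in (c1, c2, c3)]
        out = joint_label_fusion(T, pets, labels)
        assert out.codes[1, 1, 1] == 5  # two votes beat one

    def test_weights_are_convex_combination(self, rng):
        M = rng.random((50, 4, 4))
        M = M @ M.transpose(0, 2, 1)  # PSD
        w = solve_fusion_weights(M, 0.1)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        shape = (8, 8, 8)
        T = Volume(rng.random(shape).astype(np.float32), AFF)
        pets = [Volume(rng.random(shape).astype(np.float32), AFF) for _ in range(3)]
        labels = [LabelVolume(rng.integers(0, 3, shape), AFF) for _ in range(3)]
        params = FusionParams(patch_radius=1, search_radius=1, beta=2.0, lam=0.1)
        fast = joint_label_fusion(T, pets, labels, params)
        brute = _brute_force_jlf(T, pets, labels, params)
        np.testing.assert_array_equal(fast.codes, brute)

    def test_deterministic(self, rng):
        shape = (8, 8, 8)
        T = Volume(rng.random(shape), AFF)
        pets = [Volume(rng.random(shape), AFF) for _ in range(3)]
        labels = [LabelVolume(rng.integers(0, 3, shape), AFF) for _ in range(3)]
        a = joint_label_fusion(T, pets, labels)
        b = joint_label_fusion(T, pets, labels)
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_zero_atlases_rejected(self, small_volume):
        with pytest.raises(ValueError, match="at least one"):
            joint_label_fusion(small_volume, [], [])

    def test_geometry_mismatch_rejected(self, small_volume, rng):
        pet = Volume(rng.random((4, 4, 4)), AFF)
        lab = LabelVolume(rng.integers(0, 2, (4, 4, 4)), AFF)
        with pytest.raises(ValueError, match="geometry"):
            joint_label_fusion(small_volume, [pet], [lab])
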