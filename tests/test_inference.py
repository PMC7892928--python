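"""Slice assembly, consensus fusion, thresholding and component cleanup."""

import numpy as np
import pytest
from scipy import ndimage

from triseg.exceptions import ConfigError, EnsembleError, ShapeError
from triseg.inference import (
    ActivationVolume,
    ConsensusConfig,
    ConstantStub,
    IdentityStub,
    binarize,
    consensus,
    keep_largest_components,
    predict_orientation,
    segment,
)
from triseg.volumes import ORIENTATIONS, ImageVolume, LabelVolume


def _rand_vol(shape, seed=0):
    return ImageVolume(
        np.random.default_rng(seed).random(shape).astype(np.float32), np.eye(4)
    )


class TestPredictOrientation:
    @pytest.mark.parametrize("orientation", ORIENTATIONS)
    def test_identity_stub_reproduces_volume_exactly(self, orientation):
        """With an identity network the assembled activations equal the input."""
        v = _rand_vol((32, 32, 32))
        act = predict_orientation(IdentityStub(depth=4), v, orientation)
        assert act.data.shape == v.shape
        assert np.array_equal(act.data, v.data)

    @pytest.mark.parametrize("orientation", ORIENTATIONS)
    def test_odd_shape_crops_then_pads_back_with_zeros(self, orientation):
        """On a 70x65x63 grid, values inside the crop window match the input
        exactly and everything outside is exactly zero."""
        v = _rand_vol((70, 65, 63), seed=1)
        act = predict_orientation(IdentityStub(depth=4), v, orientation)
        assert act.data.shape == v.shape
        inside = act.data != 0
        assert np.array_equal(act.data[inside], v.data[inside])
        # the zero region is exactly the complement of a centered box
        diff = act.data != v.data
        assert (act.data[diff] == 0).all()

    def test_constant_stub_fills_crop_window(self):
        v = _rand_vol((32, 32, 32), seed=2)
        act = predict_orientation(ConstantStub(0.7, depth=4), v, "axial")
        assert np.allclose(act.data, 0.7)

    def test_batching_invariance(self):
        v = _rand_vol((32, 32, 32), seed=3)
        a = predict_orientation(IdentityStub(4), v, "coronal", ConsensusConfig(batch_slices=5))
        b = predict_orientation(IdentityStub(4), v, "coronal", ConsensusConfig(batch_slices=32))
        assert np.array_equal(a.data, b.data)


class TestConsensus:
    def test_identity_when_all_agree(self):
        v = _rand_vol((8, 8, 8))
        acts = [ActivationVolume(v.data, o, v.affine) for o in ORIENTATIONS]
        fused = consensus(*acts)
        assert np.allclose(fused.data, v.data, atol=1e-7)

    def test_mean_of_constants(self):
        aff = np.eye(4)
        acts = [
            ActivationVolume(np.full((4, 4, 4), val, dtype=np.float32), o, aff)
            for val, o in zip((0.2, 0.4, 0.9), ORIENTATIONS)
        ]
        assert np.allclose(consensus(*acts).data, 0.5)

    def test_order_invariant(self):
        rng = np.random.default_rng(4)
        arrs = [rng.random((5, 5, 5)).astype(np.float32) for _ in range(3)]
        acts = [ActivationVolume(a, o, np.eye(4)) for a, o in zip(arrs, ORIENTATIONS)]
        assert np.allclose(consensus(*acts).data, consensus(*acts[::-1]).data)

    def test_shape_mismatch(self):
        a = ActivationVolume(np.zeros((4, 4, 4), dtype=np.float32), "axial", np.eye(4))
        b = ActivationVolume(np.zeros((5, 4, 4), dtype=np.float32), "coronal", np.eye(4))
        with pytest.raises(ShapeError):
            consensus(a, b)

    def test_out_of_range_activation_rejected(self):
        with pytest.raises(ShapeError):
            ActivationVolume(np.full((2, 2, 2), 1.5, dtype=np.float32), "axial", np.eye(4))


class TestBinarize:
    def test_strict_inequality_at_threshold(self):
        data = np.array([[[0.4999, 0.5, 0.5001]]], dtype=np.float32)
        m = binarize(ActivationVolume(data, "consensus", np.eye(4)))
        assert m.data.tolist() == [[[0, 0, 1]]]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        act = ActivationVolume(rng.random((6, 6, 6)).astype(np.float32), "consensus", np.eye(4))
        lo = binarize(act, ConsensusConfig(threshold=0.3))
        hi = binarize(act, ConsensusConfig(threshold=0.7))
        assert (hi.data <= lo.data).all()

    def test_invalid_threshold(self):
        act = ActivationVolume(np.zeros((2, 2, 2), dtype=np.float32), "consensus", np.eye(4))
        with pytest.raises(ConfigError):
            binarize(act, ConsensusConfig(threshold=1.0))


def _brute_force_keep(mask: np.ndarray, max_components: int) -> np.ndarray:
    """Oracle: enumerate 26-connected components by BFS, keep the largest
    ``max_components`` with ties resolved by earliest scan-order appearance."""
    comps = []
    seen = np.zeros(mask.shape, dtype=bool)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for idx in np.ndindex(mask.shape):
        if mask[idx] and not seen[idx]:
            comp = []
            stack = [idx]
            seen[idx] = True
            while stack:
                cur = stack.pop()
                comp.append(cur)
                for off in offsets:
                    nb = tuple(c + o for c, o in zip(cur, off))
                    if all(0 <= n < s for n, s in zip(nb, mask.shape)) and mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            comps.append(comp)
    # stable sort by descending size keeps first-appearing component on ties
    comps.sort(key=len, reverse=True)
    out = np.zeros(mask.shape, dtype=np.uint8)
    for comp in comps[:max_components]:
        for idx in comp:
            out[idx] = 1
    return out


class TestKeepLargestComponents:
    def test_two_blobs_plus_speckle(self):
        m = np.zeros((12, 12, 12), dtype=np.uint8)
        m[1:4, 1:4, 1:4] = 1        # 27 voxels
        m[7:10, 7:10, 7:10] = 1     # 27 voxels
        m[0, 11, 11] = 1            # speckle
        out = keep_largest_components(LabelVolume(m, np.eye(4)))
        expect = m.copy(); expect[0, 11, 11] = 0
        assert np.array_equal(out.data, expect)

    def test_empty_passthrough(self):
        m = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4))
        assert keep_largest_components(m).data.sum() == 0

    def test_single_component_untouched(self):
        m = np.zeros((6, 6, 6), dtype=np.uint8)
        m[2:5, 2:5, 2:5] = 1
        out = keep_largest_components(LabelVolume(m, np.eye(4)))
        assert np.array_equal(out.data, m)

    def test_diagonal_touch_is_one_component(self):
        """26-connectivity joins voxels sharing only a corner."""
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[0, 0, 0] = 1
        m[1, 1, 1] = 1
        m[3, 3, 3] = 1  # separate
        out = keep_largest_components(LabelVolume(m, np.eye(4)), max_components=1)
        assert out.data.sum() == 2 and out.data[3, 3, 3] == 0

    def test_size_tie_keeps_scan_order_component(self):
        """Three single-voxel components, keep 2: the two first in scan order."""
        m = np.zeros((9, 9, 9), dtype=np.uint8)
        m[0, 0, 0] = m[4, 4, 4] = m[8, 8, 8] = 1
        out = keep_largest_components(LabelVolume(m, np.eye(4)), max_components=2)
        assert out.data[0, 0, 0] == 1 and out.data[4, 4, 4] == 1 and out.data[8, 8, 8] == 0

    def test_random_masks_match_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(25):
            m = (rng.random((9, 9, 9)) > 0.82).astype(np.uint8)
            for k in (1, 2, 3):
                got = keep_largest_components(LabelVolume(m, np.eye(4)), max_components=k)
                assert np.array_equal(got.data, _brute_force_keep(m, k)), (trial, k)

    def test_output_component_count_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = (rng.random((10, 10, 10)) > 0.8).astype(np.uint8)
            out = keep_largest_components(LabelVolume(m, np.eye(4)), max_components=2)
            _, n = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
            assert n <= 2


class TestSegment:
    def _stub_models(self, stub):
        return {o: stub for o in ORIENTATIONS}

    def test_zero_stub_gives_empty_mask(self, small_phantom):
        img, _ = small_phantom
        out = segment(img, self._stub_models(ConstantStub(0.0, depth=2)))
        assert out.data.sum() == 0
        assert out.data.shape == img.shape
        assert np.allclose(out.affine, img.affine)

    def test_missing_orientation_named_in_error(self, small_phantom):
        img, _ = small_phantom
        with pytest.raises(EnsembleError, match="coronal"):
            segment(img, {"sagittal": ConstantStub(0, 2), "axial": ConstantStub(0, 2)})

    def test_trained_ensemble_segments_phantom(self, tiny_ensemble, small_cohort):
        """End-to-end on a held-out subject: mask is valid and has <=2 components."""
        models, _, plan, subjects = tiny_ensemble
        sid = plan.test[0]
        out = segment(subjects[sid].image, models)
        assert set(np.unique(out.data)) <= {0, 1}
        _, n = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
        assert n <= 2

    def test_native_space_round_trip(self, tiny_ensemble):
        """A permuted-axis copy of the input segments to the permuted mask."""
        models, _, plan, subjects = tiny_ensemble
        sid = plan.test[0]
        img = subjects[sid].image
        base = segment(img, models)
        perm_aff = np.zeros((4, 4))
        perm_aff[0, 2], perm_aff[1, 0], perm_aff[2, 1], perm_aff[3, 3] = 1, -1, 1, 1
        # data permuted so that (perm_aff, permuted data) is the same physical image
        permuted = ImageVolume(np.flip(img.data.transpose(1, 2, 0), 0).copy(), perm_aff)
        out = segment(permuted, models)
        assert out.data.shape == permuted.shape
        back = np.transpose(np.flip(out.data, 0), (2, 0, 1))
        assert np.array_equal(back, base.data)
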