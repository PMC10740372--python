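import numpy as np
import pytest

from mammoseg.cascade import (
    CascadeError,
    crop_to_mask,
    gaussian_weight_map,
    largest_component,
    make_patch_grid,
    sliding_window_predict,
)
from mammoseg.io import ImageVolume, LabelMask


class TestPatchGrid:
    @pytest.mark.parametrize(
        "length,patch,expected",
        [(128, 64, [0, 32, 64]), (64, 64, [0]), (100, 64, [0, 32, 36])],
    )
    def test_axis_origins(self, length, patch, expected):
        grid = make_patch_grid((length, patch, patch), patch)
        axis0 = sorted({o[0] for o in grid.origins})
        assert axis0 == expected

    def test_stride_is_half_patch(self):
        grid = make_patch_grid((64, 64, 64), 32)
        assert grid.stride == 16

    def test_patch_too_large(self):
        with pytest.raises(ValueError):
            make_patch_grid((32, 32, 32), 64)

    def test_odd_patch_rejected(self):
        with pytest.raises(ValueError):
            make_patch_grid((32, 32, 32), 15)

    def test_coverage_oracle(self):
        """Every voxel covered by at least one patch, 100 random cases."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            patch = int(rng.choice([4, 8, 16]))
            shape = tuple(int(rng.integers(patch, 40)) for _ in range(3))
            grid = make_patch_grid(shape, patch)
            covered = np.zeros(shape, dtype=bool)
            for o in grid.origins:
                covered[tuple(slice(i, i + patch) for i in o)] = True
            assert covered.all(), (shape, patch)


class TestWeightMap:
    def test_center_is_max(self):
        w = gaussian_weight_map(16)
        assert w.max() == w[8, 8, 8] or w.max() == w[7, 7, 7]
        assert (w > 0).all()

    def test_reflection_symmetry(self):
        w = gaussian_weight_map(12)
        for ax in range(3):
            assert np.allclose(w, np.flip(w, axis=ax))

    def test_corner_hits_floor(self):
        w = gaussian_weight_map(32, sigma_fraction=1 / 8)
        assert w[0, 0, 0] / w.max() < 0.01
        assert w[0, 0, 0] >= 1e-3 * w.max() * (1 - 1e-12)


class _ConstantModel:
    """Predicts the same probability vector everywhere."""

    def __init__(self, p, patch_size):
        self.p = np.asarray(p, dtype=float)

        class _Cfg:
            pass

        self.config = _Cfg()
        self.config.patch_size = patch_size

    def predict_proba(self, patch):
        out = np.empty((len(self.p),) + patch.shape)
        out[:] = self.p[:, None, None, None]
        return out


class TestSlidingWindow:
    def test_constant_model_fuses_to_constant(self, rng):
        vol = ImageVolume(data=rng.normal(size=(20, 20, 20)), spacing=(1, 1, 1))
        model = _ConstantModel([0.3, 0.7], 8)
        fused = sliding_window_predict(model, vol)
        assert np.allclose(fused[0], 0.3, atol=1e-12)
        assert np.allclose(fused[1], 0.7, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        class _NoisyModel(_ConstantModel):
            def predict_proba(self, patch):
                r = np.random.default_rng(int(abs(patch.sum() * 1000)) % 2**31)
                a = r.uniform(0.1, 0.9, size=patch.shape)
                return np.stack([a, 1 - a])

        vol = ImageVolume(data=rng.normal(size=(20, 20, 20)), spacing=(1, 1, 1))
        fused = sliding_window_predict(_NoisyModel([0.5, 0.5], 8), vol)
        assert np.allclose(fused.sum(axis=0), 1.0, atol=1e-9)
        assert fused.min() >= 0.1 - 1e-9 and fused.max() <= 0.9 + 1e-9

    def test_single_patch_equals_model_output(self, rng):
        vol = ImageVolume(data=rng.normal(size=(8, 8, 8)), spacing=(1, 1, 1))
        model = _ConstantModel([0.2, 0.8], 8)
        fused = sliding_window_predict(model, vol)
        assert np.allclose(fused, model.predict_proba(vol.data))


class TestLargestComponent:
    def _mask(self, *blobs, shape=(16, 16, 16)):
        data = np.zeros(shape, dtype=np.uint8)
        for sl in blobs:
            data[sl] = 1
        return LabelMask(data=data, spacing=(1, 1, 1))

    def test_keeps_largest_only(self):
        big = (slice(1, 3), slice(1, 6), slice(1, 2))  # 10 voxels
        small = (slice(10, 11), slice(10, 13), slice(10, 11))  # 3 voxels
        out = largest_component(self._mask(big, small))
        assert out.data.sum() == 10
        assert out.data[1, 1, 1] == 1 and out.data[10, 10, 10] == 0

    def test_single_blob_identity(self):
        m = self._mask((slice(2, 5), slice(2, 5), slice(2, 5)))
        out = largest_component(m)
        assert np.array_equal(out.data, m.data)

    def test_equal_blobs_deterministic_tiebreak(self):
        b1 = (slice(0, 1), slice(0, 5), slice(0, 1))
        b2 = (slice(10, 11), slice(10, 15), slice(10, 11))
        outs = [largest_component(self._mask(b1, b2)).data for _ in range(3)]
        assert all(np.array_equal(outs[0], o) for o in outs)
        assert outs[0].sum() == 5
        assert outs[0][0, 0, 0] == 1  # lowest-index component wins

    def test_empty_mask_returns_empty(self):
        out = largest_component(self._mask())
        assert out.data.sum() == 0

    def test_never_increases_foreground(self, rng):
        for _ in range(10):
            data = (rng.random((12, 12, 12)) > 0.7).astype(np.uint8)
            m = LabelMask(data=data, spacing=(1, 1, 1))
            assert largest_component(m).data.sum() <= data.sum()


class TestCropToMask:
    def test_full_mask_identity(self, random_volume):
        mask = LabelMask(
            data=np.ones(random_volume.shape, dtype=np.uint8),
            spacing=random_volume.spacing,
        )
        crop, offset = crop_to_mask(random_volume, mask, margin_mm=0)
        assert offset == (0, 0, 0)
        assert np.array_equal(crop.data, random_volume.data)

    def test_single_voxel(self, random_volume):
        data = np.zeros(random_volume.shape, dtype=np.uint8)
        data[5, 5, 5] = 1
        crop, offset = crop_to_mask(
            random_volume, LabelMask(data=data, spacing=random_volume.spacing), margin_mm=0
        )
        assert crop.shape == (1, 1, 1)
        assert offset == (5, 5, 5)
        assert crop.data[0, 0, 0] == random_volume.data[5, 5, 5]

    def test_back_mapping_round_trip(self, random_volume):
        data = np.zeros(random_volume.shape, dtype=np.uint8)
        data[3:9, 2:7, 4:11] = 1
        crop, offset = crop_to_mask(
            random_volume, LabelMask(data=data, spacing=random_volume.spacing), margin_mm=2
        )
        sl = tuple(slice(o, o + s) for o, s in zip(offset, crop.shape))
        assert np.array_equal(random_volume.data[sl], crop.data)

    def test_empty_mask_rejected(self, random_volume):
        empty = LabelMask(
            data=np.zeros(random_volume.shape, dtype=np.uint8),
            spacing=random_volume.spacing,
        )
        with pytest.raises(CascadeError):
            crop_to_mask(random_volume, empty)
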