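import numpy as np
import pytest

from mammoseg.fusion import (
    EncodingError,
    FusionNetConfig,
    MarkerVector,
    build_fusion_net,
    crop_resample_lesion,
    dilate_lesion,
    encode_markers,
    load_fusion_net,
    predict_pcr,
    save_fusion_net,
    train_fusion,
)
from mammoseg.io import ImageVolume, LabelMask, PatientRecord


def _record(**kw):
    base = dict(patient_id="p0", her2=1, er=0, pr=1, ki67=0.3,
                pcr_label=1, center_id="A")
    base.update(kw)
    return PatientRecord(**base)


SMALL_CFG = FusionNetConfig(num_stages=3, image_channels=(4, 8, 8), input_cube=8)


class TestEncodeMarkers:
    def test_order_and_values(self):
        mv = encode_markers(_record())
        assert np.allclose(mv.values, [1, 0, 1, 0.3])

    def test_all_zero(self):
        mv = encode_markers(_record(her2=0, pr=0, ki67=0.0))
        assert np.allclose(mv.values, [0, 0, 0, 0])

    def test_missing_marker_named(self):
        with pytest.raises(EncodingError, match="ki67"):
            encode_markers({"her2": 1, "er": 0, "pr": 1})


class TestDilateLesion:
    def _single_voxel(self, side=24):
        data = np.zeros((side, side, side), dtype=np.uint8)
        data[side // 2, side // 2, side // 2] = 1
        return LabelMask(data=data, spacing=(1, 1, 1))

    def test_radius_zero_identity(self):
        m = self._single_voxel()
        out = dilate_lesion(m, 0)
        assert np.array_equal(out.data, m.data)

    @pytest.mark.parametrize("radius", [1, 2, 5])
    def test_ball_voxel_count(self, radius):
        """Dilating a point gives exactly the discrete ball."""
        expected = sum(
            1
            for x in range(-radius, radius + 1)
            for y in range(-radius, radius + 1)
            for z in range(-radius, radius + 1)
            if x * x + y * y + z * z <= radius * radius
        )
        out = dilate_lesion(self._single_voxel(), radius)
        assert int(out.data.sum()) == expected

    def test_monotone(self, blob_mask):
        out = dilate_lesion(blob_mask, 2)
        assert np.all(out.data >= blob_mask.data)

    def test_negative_radius(self, blob_mask):
        with pytest.raises(ValueError):
            dilate_lesion(blob_mask, -1)


class TestCropResample:
    def test_output_contract(self, rng):
        vol = ImageVolume(data=rng.normal(100, 20, (30, 30, 30)), spacing=(1, 1, 1))
        mask = np.zeros((30, 30, 30), dtype=np.uint8)
        mask[10:20, 8:19, 12:25] = 1
        out = crop_resample_lesion(vol, LabelMask(data=mask, spacing=(1, 1, 1)), cube=16)
        assert out.shape == (16, 16, 16)
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1) < 1e-6

    def test_exact_cube_mask_is_identity_resample(self, rng):
        vol = ImageVolume(data=rng.normal(size=(20, 20, 20)), spacing=(1, 1, 1))
        mask = np.zeros((20, 20, 20), dtype=np.uint8)
        mask[2:10, 3:11, 4:12] = 1  # exactly 8^3
        out = crop_resample_lesion(vol, LabelMask(data=mask, spacing=(1, 1, 1)), cube=8)
        ref = vol.data[2:10, 3:11, 4:12]
        ref = (ref - ref.mean()) / ref.std()
        assert np.abs(out.data - ref).max() < 1e-4

    def test_empty_mask_rejected(self, rng):
        vol = ImageVolume(data=rng.normal(size=(10, 10, 10)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            crop_resample_lesion(
                vol, LabelMask(data=np.zeros((10, 10, 10), np.uint8), spacing=(1, 1, 1)), 8
            )


class TestGating:
    def test_config_requires_matching_widths(self):
        with pytest.raises(ValueError, match="gating"):
            FusionNetConfig(num_stages=3, image_channels=(4, 8, 8),
                            fc_widths=(4, 8, 16), input_cube=8)

    def test_ones_gates_ignore_markers(self, rng):
        """With gates forced to one the markers cannot influence output."""
        model = build_fusion_net(SMALL_CFG, seed=0)
        img = rng.normal(size=(8, 8, 8))
        m1 = MarkerVector(np.array([1, 0, 1, 0.3]))
        m2 = MarkerVector(np.array([0, 1, 0, 0.9]))
        p1 = model.predict_proba(img, m1, gate_mode="ones")
        p2 = model.predict_proba(img, m2, gate_mode="ones")
        assert np.array_equal(p1, p2)

    def test_zero_gate_blinds_image(self, rng):
        """Zeroing the stage-1 gate makes output image-independent."""
        model = build_fusion_net(SMALL_CFG, seed=0)
        mv = MarkerVector(np.array([1, 0, 1, 0.3]))
        p1 = model.predict_proba(rng.normal(size=(8, 8, 8)), mv, gate_mode="zeros")
        p2 = model.predict_proba(rng.normal(size=(8, 8, 8)) * 5, mv, gate_mode="zeros")
        assert np.allclose(p1, p2, atol=1e-12)

    def test_normal_mode_uses_both(self, rng):
        model = build_fusion_net(SMALL_CFG, seed=0)
        img = rng.normal(size=(8, 8, 8))
        m1 = MarkerVector(np.array([1, 0, 1, 0.3]))
        m2 = MarkerVector(np.array([0, 1, 0, 0.9]))
        assert not np.allclose(
            model.predict_proba(img, m1), model.predict_proba(img, m2)
        )

    def test_softmax_output(self, rng):
        model = build_fusion_net(SMALL_CFG, seed=1)
        p = model.predict_proba(rng.normal(size=(8, 8, 8)),
                                MarkerVector(np.zeros(4)))
        assert p.shape == (2,)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


def _samples(rng, n=8):
    out = []
    for i in range(n):
        out.append(
            (
                rng.normal(size=(8, 8, 8)),
                MarkerVector(rng.random(4).round(1)),
                i % 2,
            )
        )
    return out


class TestTrainPredict:
    def test_loss_decreases(self, rng):
        samples = _samples(rng)
        model = build_fusion_net(SMALL_CFG, seed=2)
        res = train_fusion(model, samples, lr=1e-2, epochs=20, seed=3)
        assert res.losses[-1] < res.losses[0]

    def test_deterministic(self, rng):
        samples = _samples(rng)
        finals = []
        for _ in range(2):
            model = build_fusion_net(SMALL_CFG, seed=2)
            res = train_fusion(model, samples, lr=1e-2, epochs=3, seed=3)
            finals.append(res.losses[-1])
        assert finals[0] == finals[1]

    def test_single_class_rejected(self, rng):
        samples = [(s[0], s[1], 1) for s in _samples(rng)]
        model = build_fusion_net(SMALL_CFG, seed=2)
        with pytest.raises(ValueError, match="single-class"):
            train_fusion(model, samples, epochs=1)

    def test_predict_threshold_consistency(self, rng):
        model = build_fusion_net(SMALL_CFG, seed=4)
        for i in range(5):
            res = predict_pcr(
                model, rng.normal(size=(8, 8, 8)), MarkerVector(rng.random(4)),
                patient_id=f"p{i}",
            )
            assert 0.0 <= res.p_pcr <= 1.0
            assert res.predicted_label == int(res.p_pcr >= 0.5)

    def test_wrong_crop_shape_rejected(self, rng):
        model = build_fusion_net(SMALL_CFG, seed=4)
        with pytest.raises(ValueError, match="crop"):
            model.predict_proba(rng.normal(size=(6, 6, 6)), MarkerVector(np.zeros(4)))

    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_fusion_net(SMALL_CFG, seed=5)
        path = tmp_path / "fusion.npz"
        save_fusion_net(model, path)
        back = load_fusion_net(path)
        img = rng.normal(size=(8, 8, 8))
        mv = MarkerVector(np.array([1, 0, 0, 0.5]))
        assert np.allclose(model.predict_proba(img, mv), back.predict_proba(img, mv))
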