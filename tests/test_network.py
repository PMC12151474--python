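"""Architecture contracts: receptive fields, attention, DAC, shapes, counts."""

import numpy as np
import pytest

from plaqueseg import (DACNet, DilationSpec, NetworkConfig,
                       branch_receptive_fields, cascade_receptive_field,
                       count_parameters, dac_parameter_count, load_checkpoint,
                       plain_stack_parameter_count, receptive_field,
                       save_checkpoint, stage_shapes)
from plaqueseg.autodiff import Tensor, relu
from plaqueseg.network import CBAM, Conv2d, DACBlock


class TestReceptiveField:
    @pytest.mark.parametrize("k,r,expected", [
        (3, 1, 3),    # r=1 is standard convolution
        (3, 2, 5),    # the 5x5-equivalent dilated kernel
        (3, 3, 7),
        (3, 5, 11),
        (1, 1, 1),
    ])
    def test_single_layer_formula(self, k, r, expected):
        assert receptive_field(DilationSpec(k, r)) == expected

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DilationSpec(2, 1)           # even kernel
        with pytest.raises(ValueError):
            DilationSpec(3, 0)           # dilation below 1

    @pytest.mark.parametrize("layers,expected", [
        ([(3, 1)], 3),
        ([(3, 1), (3, 3)], 9),
        ([(3, 1), (3, 3), (3, 5)], 19),
        ([(3, 3)], 7),
    ])
    def test_cascade_composition(self, layers, expected):
        specs = [DilationSpec(k, r) for k, r in layers]
        assert cascade_receptive_field(specs) == expected

    def test_empty_cascade_rejected(self):
        with pytest.raises(ValueError):
            cascade_receptive_field([])

    def test_default_dac_plan_receptive_fields(self):
        assert branch_receptive_fields() == (3, 7, 9, 19)


def test_relu_values():
    x = Tensor(np.array([-2.0, 0.0, 3.0], np.float32))
    np.testing.assert_array_equal(relu(x).data, [0.0, 0.0, 3.0])


class TestChannelAttention:
    def _cbam(self, c=2, reduction=1):
        return CBAM(c, reduction, 7, np.random.default_rng(0))

    def test_shape_and_sigmoid_range(self, rng):
        cb = self._cbam(c=4)
        x = Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
        mc = cb.channel_map(x)
        assert mc.shape == (2, 4, 1, 1)
        assert (mc.data > 0).all() and (mc.data < 1).all()

    def test_zero_mlp_gives_half_everywhere(self, rng):
        cb = self._cbam(c=3)
        for p in (cb.w1, cb.b1, cb.w2, cb.b2):
            p.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(cb.channel_map(x).data, 0.5)

    def test_identical_channels_get_identical_weights(self, rng):
        """With swap-equivariant MLP weights, duplicated channels tie."""
        cb = self._cbam(c=2, reduction=1)
        cb.w1.data = np.eye(2, dtype=np.float32)
        cb.w2.data = np.eye(2, dtype=np.float32)
        cb.b1.data[...] = 0.1
        cb.b2.data[...] = -0.2
        ch = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        x = Tensor(np.concatenate([ch, ch], axis=1))
        mc = cb.channel_map(x).data
        assert mc[0, 0, 0, 0] == pytest.approx(mc[0, 1, 0, 0])


class TestSpatialAttention:
    def test_shape_and_zero_conv_half(self, rng):
        cb = CBAM(3, 1, 7, np.random.default_rng(1))
        x = Tensor(rng.standard_normal((2, 3, 5, 5)).astype(np.float32))
        ms = cb.spatial_map(x)
        assert ms.shape == (2, 1, 5, 5)
        cb.spatial_conv.weight.data[...] = 0.0
        cb.spatial_conv.bias.data[...] = 0.0
        np.testing.assert_allclose(cb.spatial_map(x).data, 0.5)

    def test_spatially_constant_input_gives_constant_map(self):
        cb = CBAM(3, 1, 7, np.random.default_rng(2))
        x = Tensor(np.full((1, 3, 5, 5), 0.3, np.float32) *
                   np.arange(1, 4, dtype=np.float32).reshape(1, 3, 1, 1))
        ms = cb.spatial_map(x).data
        np.testing.assert_allclose(ms, ms.flat[0], rtol=1e-5)


class TestCBAM:
    def test_zero_input_maps_to_zero_and_shape_kept(self, rng):
        cb = CBAM(4, 2, 7, np.random.default_rng(3))
        z = Tensor(np.zeros((1, 4, 8, 8), np.float32))
        np.testing.assert_array_equal(cb(z).data, 0.0)
        x = Tensor(rng.standard_normal((2, 4, 8, 8)).astype(np.float32))
        assert cb(x).shape == x.shape

    def test_attention_never_amplifies(self, rng):
        cb = CBAM(4, 2, 7, np.random.default_rng(4))
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        assert (np.abs(cb(x).data) <= np.abs(x.data) + 1e-7).all()


class TestDACBlock:
    def test_zero_weights_is_identity(self, rng):
        block = DACBlock(3, NetworkConfig(input_size=32, base_width=4,
                                          cbam_reduction=2),
                         np.random.default_rng(5))
        for p in block.parameters():
            p.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_shape_preserved(self, rng):
        block = DACBlock(5, NetworkConfig(input_size=32, base_width=4,
                                          cbam_reduction=2),
                         np.random.default_rng(6))
        x = Tensor(rng.standard_normal((2, 5, 8, 8)).astype(np.float32))
        assert block(x).shape == x.shape


class TestForward:
    def test_full_scale_shape_plan(self):
        """512 input: 32x32 bottleneck at 1024 channels, 2-channel head."""
        shapes = dict((name, (c, s)) for name, c, s in
                      stage_shapes(NetworkConfig()))
        assert shapes["input"] == (3, 512)
        assert shapes["bottleneck"] == (1024, 32)
        assert shapes["output"] == (2, 512)

    def test_tiny_model_output_shape(self, rng):
        cfg = NetworkConfig(input_size=64, base_width=8, cbam_reduction=4)
        model = DACNet(cfg)
        x = Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
        assert model(x).shape == (1, 2, 64, 64)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=100, depth=4)
        cfg = NetworkConfig(input_size=64, base_width=4, cbam_reduction=2)
        model = DACNet(cfg)
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 3, 24, 24), np.float32)))


class TestParameterCounts:
    def test_single_conv_counts(self):
        conv = Conv2d(1, 1, 3, np.random.default_rng(0))
        assert conv.num_parameters() == 10            # 3*3*1*1 + 1
        dilated = Conv2d(1, 1, 3, np.random.default_rng(0), dilation=5)
        assert dilated.num_parameters() == 10         # dilation is free

    @pytest.mark.parametrize("kwargs", [
        dict(input_size=32, base_width=4, depth=4, cbam_reduction=2),
        dict(input_size=32, base_width=8, depth=2, cbam_reduction=4),
        dict(input_size=48, base_width=6, depth=3, cbam_reduction=2,
             cbam_spatial_kernel=5),
    ])
    def test_analytic_count_equals_built_model(self, kwargs):
        cfg = NetworkConfig(**kwargs)
        assert count_parameters(cfg) == DACNet(cfg).num_parameters()

    def test_dilated_cascade_beats_plain_stack_at_rf19(self):
        for c in (8, 64, 1024):
            assert dac_parameter_count(c) < plain_stack_parameter_count(c, 19)

    def test_dac_count_matches_built_block(self):
        cfg = NetworkConfig(input_size=32, base_width=4, cbam_reduction=2)
        block = DACBlock(6, cfg, np.random.default_rng(0))
        assert block.num_parameters() == dac_parameter_count(6)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        cfg = NetworkConfig(input_size=32, base_width=4, cbam_reduction=2,
                            seed=11)
        model = DACNet(cfg)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(restored.predict_proba(x), before)

    def test_config_mismatch_fails_loudly(self, tmp_path):
        cfg = NetworkConfig(input_size=32, base_width=4, cbam_reduction=2)
        path = tmp_path / "model.npz"
        save_checkpoint(DACNet(cfg), path)
        other = NetworkConfig(input_size=32, base_width=8, cbam_reduction=2)
        with pytest.raises(ValueError):
            load_checkpoint(path, expected_config=other)
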