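"""Architecture contracts: GRN arithmetic, partitioning, attention, MBConv,
and whole-network behavior of the tiny configuration."""

import numpy as np
import pytest

from maxgrnet import nn
from maxgrnet.architecture import (AttentionBlock, GRNParams, MaxGRNet, MBConv,
                                   ModelConfig, WindowAttention, grn_apply,
                                   relative_position_index,
                                   scaled_dot_attention, window_partition,
                                   window_unpartition)
from maxgrnet.autodiff import Tensor
from maxgrnet.errors import ConfigurationError, ShapeError, ValidationError

RNG = np.random.default_rng(42)


# ----------------------------------------------------------------------
class TestGRN:
    def test_zero_input_zero_params_gives_zero(self):
        x = Tensor(np.zeros((1, 2, 2, 2), np.float32))
        p = GRNParams(np.zeros(2), np.zeros(2))
        assert np.all(grn_apply(x, p).data == 0)

    def test_zero_params_is_identity_for_any_input(self):
        x = Tensor(RNG.normal(size=(2, 5, 4, 4)).astype(np.float32))
        p = GRNParams(np.zeros(5), np.zeros(5))
        np.testing.assert_allclose(grn_apply(x, p).data, x.data, atol=1e-7)

    def test_hand_arithmetic_two_channel_case(self):
        # channel 1 holds (3,4) on a 1x2 grid -> L2 norm 5; channel 2 zeros;
        # mean norm 2.5 -> n = (2, 0); gamma=1, beta=0 -> (9,12) and (0,0)
        x = np.zeros((1, 2, 1, 2), np.float32)
        x[0, 0, 0] = (3.0, 4.0)
        out = grn_apply(Tensor(x), GRNParams(np.ones(2), np.zeros(2)), eps=1e-12)
        expected = np.zeros_like(x)
        expected[0, 0, 0] = (3 * 2 + 3, 4 * 2 + 4)   # gamma*(x*n) + x
        np.testing.assert_allclose(out.data, expected, rtol=1e-5)

    def test_hand_case_matches_independent_per_element_script(self):
        x = RNG.normal(size=(3, 4, 5, 6))
        gamma, beta = RNG.normal(size=4), RNG.normal(size=4)
        out = grn_apply(Tensor(x), GRNParams(gamma, beta), eps=1e-6).data
        for n in range(3):
            g = np.array([np.sqrt((x[n, c] ** 2).sum()) for c in range(4)])
            nrm = g / (g.mean() + 1e-6)
            for c in range(4):
                np.testing.assert_allclose(
                    out[n, c], gamma[c] * x[n, c] * nrm[c] + beta[c] + x[n, c],
                    rtol=2e-5)

    def test_normalization_scale_covariance(self):
        # scaling x by s > 0 leaves n = g / mean(g) unchanged as eps -> 0
        x = RNG.normal(size=(1, 3, 4, 4))
        def norms(arr):
            g = np.sqrt((arr ** 2).sum(axis=(2, 3)))
            return g / g.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(norms(x), norms(7.3 * x), rtol=1e-10)

    def test_channel_mismatch_and_nonfinite_rejected(self):
        x = Tensor(np.ones((1, 3, 2, 2), np.float32))
        with pytest.raises(ConfigurationError):
            grn_apply(x, GRNParams(np.zeros(4), np.zeros(4)))
        bad = np.ones((1, 3, 2, 2), np.float32)
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            grn_apply(Tensor(bad), GRNParams(np.zeros(3), np.zeros(3)))


# ----------------------------------------------------------------------
class TestPartitioning:
    @pytest.mark.parametrize("grid", [False, True])
    def test_degenerate_single_window_equals_input_tokens(self, grid):
        x = Tensor(RNG.normal(size=(1, 3, 4, 4)).astype(np.float32))
        tokens = window_partition(x, 4, grid=grid)
        assert tokens.shape == (1, 16, 3)

    @pytest.mark.parametrize("grid", [False, True])
    @pytest.mark.parametrize("h,w,p", [(8, 8, 4), (8, 12, 2), (6, 6, 3)])
    def test_round_trip_is_bit_identical(self, grid, h, w, p):
        x = Tensor(RNG.normal(size=(2, 5, h, w)).astype(np.float32))
        tokens = window_partition(x, p, grid=grid)
        back = window_unpartition(tokens, p, 2, h, w, grid=grid)
        assert np.array_equal(back.data, x.data)

    def test_block_windows_match_exhaustive_index_oracle(self):
        # 4x4 single-channel input, P=2: enumerate expected window contents
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        tokens = window_partition(Tensor(x), 2).data[:, :, 0]
        expected = []
        for wi in range(2):
            for wj in range(2):
                win = [x[0, 0, wi * 2 + a, wj * 2 + b]
                       for a in range(2) for b in range(2)]
                expected.append(win)
        np.testing.assert_array_equal(tokens, np.array(expected))

    def test_grid_windows_sample_strided_positions(self):
        # grid mode with P=2 on 4x4: group (b, d) holds pixels (b + 2a, d + 2c)
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        tokens = window_partition(Tensor(x), 2, grid=True).data[:, :, 0]
        expected = []
        for b in range(2):
            for d in range(2):
                grp = [x[0, 0, b + 2 * a, d + 2 * c]
                       for a in range(2) for c in range(2)]
                expected.append(grp)
        np.testing.assert_array_equal(tokens, np.array(expected))

    def test_indivisible_dimensions_raise_without_padding(self):
        x = Tensor(np.zeros((1, 1, 6, 6), np.float32))
        with pytest.raises(ShapeError):
            window_partition(x, 4)


# ----------------------------------------------------------------------
class TestAttention:
    def test_two_token_attention_matches_hand_computation(self):
        d = 2
        q = Tensor(np.array([[[[1.0, 0.0], [0.0, 1.0]]]], np.float32))
        k = Tensor(np.array([[[[1.0, 0.0], [0.0, 2.0]]]], np.float32))
        v = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], np.float32))
        out, attn = scaled_dot_attention(q, k, v)
        scores = q.data[0, 0] @ k.data[0, 0].T / np.sqrt(d)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        w = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(attn.data[0, 0], w, rtol=1e-6)
        np.testing.assert_allclose(out.data[0, 0], w @ v.data[0, 0], rtol=1e-6)

    def test_singleton_window_attention_weight_is_exactly_one(self):
        q = Tensor(RNG.normal(size=(1, 1, 1, 4)).astype(np.float32))
        _, attn = scaled_dot_attention(q, q, q)
        assert attn.data.item() == 1.0

    def test_attention_rows_sum_to_one_in_full_model(self):
        model = MaxGRNet(ModelConfig.tiny(), seed=0)
        model.forward(RNG.random((2, 3, 64, 64)).astype(np.float32))
        checked = 0
        for blocks in model.stages:
            for block in blocks:
                for attn_block in (block.block_attn, block.grid_attn):
                    rows = attn_block.attn.last_attention.sum(axis=-1)
                    np.testing.assert_allclose(rows, 1.0, atol=1e-5)
                    checked += 1
        assert checked == 8

    def test_zero_value_and_projection_weights_give_identity_block(self):
        cfg = ModelConfig.tiny()
        rng = np.random.default_rng(0)
        block = AttentionBlock(8, cfg, "block", rng)
        qkv = block.attn.qkv.weight.data
        qkv[2 * 8:] = 0.0                  # value projection rows
        block.attn.qkv.bias.data[2 * 8:] = 0.0
        block.attn.proj.bias.data[:] = 0.0
        block.mlp.fc2.weight.data[:] = 0.0
        block.mlp.fc2.bias.data[:] = 0.0
        x = Tensor(RNG.normal(size=(1, 8, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)

    def test_relative_position_index_is_translation_consistent(self):
        idx = relative_position_index(3)
        assert idx.shape == (9, 9)
        # same spatial offset -> same table entry
        assert idx[0, 4] == idx[4, 8]      # offset (+1, +1)
        assert idx[1, 1] == idx[5, 5]      # offset (0, 0)

    def test_width_not_divisible_by_head_dim_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowAttention(12, 8, 2, np.random.default_rng(0))


# ----------------------------------------------------------------------
class TestMBConv:
    def _block(self, downsample=False, se_enabled=True, in_ch=6, out_ch=6):
        return MBConv(in_ch, out_ch, ModelConfig.tiny(), downsample,
                      np.random.default_rng(3), se_enabled=se_enabled)

    def test_zero_projection_no_downsample_is_identity(self):
        block = self._block()
        block.project.weight.data[:] = 0.0
        block.project.bias.data[:] = 0.0
        x = Tensor(RNG.normal(size=(2, 6, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-6)

    def test_downsample_halves_spatial_size(self):
        block = self._block(downsample=True)
        out = block(Tensor(np.zeros((1, 6, 8, 8), np.float32)))
        assert out.shape == (1, 6, 4, 4)

    def test_saturated_se_gate_matches_block_without_se(self):
        with_se = self._block(se_enabled=True)
        without = self._block(se_enabled=False)
        plain = dict(without.named_parameters())
        for name, p in with_se.named_parameters():
            if name in plain:
                p.data = plain[name].data.copy()
        with_se.se.fc2.weight.data[:] = 0.0
        with_se.se.fc2.bias.data[:] = 30.0   # sigmoid(30) ~ 1: identity gate
        x = Tensor(RNG.normal(size=(2, 6, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(with_se(x).data, without(x).data, atol=1e-5)


# ----------------------------------------------------------------------
class TestModelConfig:
    def test_defaults_follow_the_tiny_tier_design(self):
        cfg = ModelConfig()
        assert cfg.stage_depths == (2, 2, 5, 2)
        assert cfg.stage_channels == (64, 128, 256, 512)
        assert cfg.partition_size == 7 and cfg.head_dim == 32
        assert cfg.stage_resolutions() == (56, 28, 14, 7)

    @pytest.mark.parametrize("kwargs", [
        {"stage_depths": (1, 1, 1)},
        {"num_classes": 0},
        {"input_size": 100},               # stage resolutions not divisible by 7
        {"head_dim": 48},                  # 64 not divisible
        {"se_ratio": 0.0},
        {"grn_scope": "everywhere"},
    ])
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ModelConfig.tiny(num_classes=10, grn_enabled=False)
        cfg.to_yaml(tmp_path / "m.yaml")
        assert ModelConfig.from_yaml(tmp_path / "m.yaml") == cfg


# ----------------------------------------------------------------------
class TestMaxGRNet:
    def test_logit_shape_and_parameter_budget(self):
        model = MaxGRNet(ModelConfig.tiny(), seed=0)
        assert model.n_parameters() < 200_000
        logits = model.forward(RNG.random((3, 3, 64, 64)).astype(np.float32))
        assert logits.shape == (3, 4)
        assert np.isfinite(logits.data).all()

    def test_batch_permutation_equivariance(self):
        model = MaxGRNet(ModelConfig.tiny(), seed=0)
        x = RNG.random((5, 3, 64, 64)).astype(np.float32)
        perm = np.array([3, 1, 4, 0, 2])
        base = model.forward(x).data
        permuted = model.forward(x[perm]).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-5)

    def test_forward_is_deterministic_given_seeded_weights(self):
        x = RNG.random((2, 3, 64, 64)).astype(np.float32)
        a = MaxGRNet(ModelConfig.tiny(), seed=7).forward(x).data
        b = MaxGRNet(ModelConfig.tiny(), seed=7).forward(x).data
        assert np.array_equal(a, b)

    def test_grn_zeroed_matches_grn_disabled_exactly(self):
        x = RNG.random((2, 3, 64, 64)).astype(np.float32)
        on = MaxGRNet(ModelConfig.tiny(grn_enabled=True), seed=0)
        off = MaxGRNet(ModelConfig.tiny(grn_enabled=False), seed=0)
        off_params = dict(off.named_parameters())
        for name, p in on.named_parameters():
            if ".grn." in name:
                assert np.all(p.data == 0)      # zero-initialized
            else:
                p.data = off_params[name].data.copy()
        np.testing.assert_allclose(on.forward(x).data, off.forward(x).data,
                                   atol=1e-6)

    def test_wrong_input_size_names_expected_size(self):
        model = MaxGRNet(ModelConfig.tiny(), seed=0)
        with pytest.raises(ValidationError, match="64"):
            model.forward(np.zeros((1, 3, 32, 32), np.float32))

    def test_checkpoint_round_trip(self, tmp_path):
        from maxgrnet.architecture import load_checkpoint, save_checkpoint

        model = MaxGRNet(ModelConfig.tiny(), seed=0)
        x = RNG.random((1, 3, 64, 64)).astype(np.float32)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        assert np.array_equal(model.forward(x).data, restored.forward(x).data)
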