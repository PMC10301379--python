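"""Partition mechanics, attention properties, MBConv contracts, and the
full classifier's shape/determinism behaviour."""

import numpy as np
import pytest

from symaxion.autodiff import Tensor
from symaxion.model import (
    AttentionBlock,
    FusionConv,
    MBConv,
    ModelConfig,
    MultiAxisClassifier,
    MultiHeadSelfAttention,
    grid_partition,
    grid_unpartition,
    load_checkpoint,
    save_checkpoint,
    window_partition,
    window_unpartition,
)


def t(arr):
    return Tensor(np.asarray(arr, dtype=float))


class TestPartitions:
    def test_window_partition_counts(self, rng):
        x = t(rng.standard_normal((1, 3, 8, 8)))
        tokens = window_partition(x, 4)
        assert tokens.shape == (4, 16, 3)  # (8/4)*(8/4) windows of 4x4

    def test_window_roundtrip_identity(self, rng):
        x = rng.standard_normal((2, 5, 8, 12))
        back = window_unpartition(window_partition(t(x), 4), 4, 8, 12)
        assert np.array_equal(back.data, x)

    def test_single_window_when_p_equals_size(self, rng):
        tokens = window_partition(t(rng.standard_normal((1, 2, 4, 4))), 4)
        assert tokens.shape == (1, 16, 2)

    def test_grid_partition_counts(self, rng):
        x = t(rng.standard_normal((1, 3, 8, 8)))
        groups = grid_partition(x, 4)
        assert groups.shape == (16, 4, 3)  # g*g groups of (8/4)*(8/4) tokens

    def test_grid_roundtrip_identity(self, rng):
        x = rng.standard_normal((2, 5, 8, 12))
        back = grid_unpartition(grid_partition(t(x), 4), 4, 8, 12)
        assert np.array_equal(back.data, x)

    def test_grid_groups_gather_one_element_per_tile(self, rng):
        """Group (a, b) holds exactly the offset-(a, b) element of every tile."""
        h = w = 8
        g = 4
        x = np.arange(h * w, dtype=float).reshape(1, 1, h, w)
        groups = grid_partition(t(x), g).data  # (g*g, (h/g)*(w/g), 1)
        for a in range(g):
            for b in range(g):
                expected = x[0, 0, a::g, b::g].ravel()
                assert np.array_equal(groups[a * g + b, :, 0], expected)

    def test_grid_equals_window_of_block_transposed_tensor(self, rng):
        """Index-permutation duality between the two partition axes."""
        h = w = 8
        g = 4
        x = rng.standard_normal((2, 3, h, w))
        # swap tile index and intra-tile offset on both spatial axes
        swapped = np.zeros_like(x)
        for t1 in range(h // g):
            for g1 in range(g):
                for t2 in range(w // g):
                    for g2 in range(g):
                        swapped[:, :, g1 * (h // g) + t1, g2 * (w // g) + t2] = x[
                            :, :, t1 * g + g1, t2 * g + g2
                        ]
        grid_tokens = grid_partition(t(x), g).data
        win_tokens = window_partition(t(swapped), h // g).data
        assert np.allclose(grid_tokens, win_tokens)

    def test_divisibility_violation_raises(self, rng):
        with pytest.raises(ValueError):
            window_partition(t(rng.standard_normal((1, 1, 6, 6))), 4)
        with pytest.raises(ValueError):
            grid_partition(t(rng.standard_normal((1, 1, 6, 6))), 4)


class TestSelfAttention:
    def test_single_token_passes_through_value_path(self, rng):
        attn = MultiHeadSelfAttention(rng, dim=8, heads=2)
        tokens = t(rng.standard_normal((3, 1, 8)))
        out, weights = attn.forward(tokens, return_weights=True)
        assert np.allclose(weights.data, 1.0)
        v = attn.wv.forward(tokens)
        expected = attn.wo.forward(v)
        assert np.allclose(out.data, expected.data, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        attn = MultiHeadSelfAttention(rng, dim=8, heads=4)
        tokens = t(rng.standard_normal((2, 16, 8)))
        _, weights = attn.forward(tokens, return_weights=True)
        assert np.abs(weights.data.sum(axis=-1) - 1.0).max() < 1e-6

    def test_permutation_equivariance(self, rng):
        """No positional term inside attention: permuting tokens permutes outputs."""
        attn = MultiHeadSelfAttention(rng, dim=8, heads=2)
        tokens = rng.standard_normal((1, 9, 8))
        perm = rng.permutation(9)
        out = attn.forward(t(tokens)).data
        out_perm = attn.forward(t(tokens[:, perm])).data
        assert np.allclose(out[:, perm], out_perm, atol=1e-10)

    def test_token_count_preserved(self, rng):
        attn = MultiHeadSelfAttention(rng, dim=12, heads=3)
        out = attn.forward(t(rng.standard_normal((4, 7, 12))))
        assert out.shape == (4, 7, 12)


class TestMBConv:
    def test_stride1_preserves_shape(self, rng):
        block = MBConv(rng, 8, 8, stride=1)
        out = block.forward(t(rng.standard_normal((2, 8, 16, 16)).astype(np.float32)))
        assert out.shape == (2, 8, 16, 16)

    def test_stride2_halves_spatial(self, rng):
        block = MBConv(rng, 8, 12, stride=2)
        out = block.forward(t(rng.standard_normal((2, 8, 16, 16)).astype(np.float32)))
        assert out.shape == (2, 12, 8, 8)

    def test_zeroed_se_gate_kills_projection_input(self, rng):
        """Forcing the SE gate to zero reduces the block to residual only."""
        block = MBConv(rng, 8, 8, stride=1)
        block.se.fc2.weight.data[:] = 0.0
        block.se.fc2.bias.data[:] = -1e4  # sigmoid -> 0
        block.eval()
        x = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        out = block.forward(t(x))
        # gated branch contributes only the (constant) projection bias response
        zero_in = block.forward(t(np.zeros_like(x)))
        assert np.allclose(out.data - x, zero_in.data, atol=1e-5)


class TestAttentionBlockAndFusionConv:
    def test_fusion_conv_keeps_spatial(self, rng):
        fc = FusionConv(rng, 200, 16)
        out = fc.forward(t(rng.standard_normal((2, 200, 16, 16)).astype(np.float32)))
        assert out.shape == (2, 16, 16, 16)

    def test_fusion_conv_zero_input_gives_bias_response(self, rng):
        fc = FusionConv(rng, 10, 4)
        fc.eval()
        out1 = fc.forward(t(np.zeros((2, 10, 8, 8), dtype=np.float32)))
        out2 = fc.forward(t(np.zeros((2, 10, 8, 8), dtype=np.float32)))
        assert np.array_equal(out1.data, out2.data)
        assert np.allclose(out1.data, out1.data[0, :, :1, :1])  # spatially constant

    def test_batch_permutation_equivariance(self, rng):
        fc = FusionConv(rng, 10, 4)
        fc.eval()
        x = rng.standard_normal((4, 10, 8, 8)).astype(np.float32)
        perm = np.array([2, 0, 3, 1])
        assert np.allclose(fc.forward(t(x)).data[perm], fc.forward(t(x[perm])).data)

    @pytest.mark.parametrize("axis", ["window", "grid"])
    def test_attention_block_preserves_shape(self, rng, axis):
        blk = AttentionBlock(rng, dim=8, heads=2, size=4, axis=axis)
        out = blk.forward(t(rng.standard_normal((2, 8, 8, 8))))
        assert out.shape == (2, 8, 8, 8)


SMALL_CFG = dict(in_depth=20, spatial=32, num_classes=3, stage_channels=(4, 8), heads=2)


class TestClassifier:
    def test_logit_shape(self, rng):
        model = MultiAxisClassifier(ModelConfig(**SMALL_CFG), seed=0)
        x = rng.standard_normal((2, 20, 32, 32)).astype(np.float32)
        logits = model.forward(x)
        assert logits.shape == (2, 3)
        probs = logits.softmax(-1).data
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_final_stage_spatial_is_4x4(self):
        cfg = ModelConfig()  # default 64-input, three stages
        assert cfg.stage_spatial() == [16, 8, 4]
        cfg_small = ModelConfig(**SMALL_CFG)
        assert cfg_small.stage_spatial()[-1] == 4

    def test_forward_deterministic_under_fixed_seed(self, rng):
        x = rng.standard_normal((2, 20, 32, 32)).astype(np.float32)
        a = MultiAxisClassifier(ModelConfig(**SMALL_CFG), seed=3).forward(x).data
        b = MultiAxisClassifier(ModelConfig(**SMALL_CFG), seed=3).forward(x).data
        assert np.array_equal(a, b)

    def test_shape_mismatch_raises(self, rng):
        model = MultiAxisClassifier(ModelConfig(**SMALL_CFG), seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.standard_normal((2, 20, 16, 16)).astype(np.float32))

    def test_config_divisibility_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(spatial=24, stage_channels=(4, 8))  # 24 -> 12 -> 6, not /4
        with pytest.raises(ValueError):
            ModelConfig(window_size=4, grid_size=2)
        with pytest.raises(ValueError):
            ModelConfig(stage_channels=(5,), heads=2)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = MultiAxisClassifier(ModelConfig(**SMALL_CFG), seed=1)
        x = rng.standard_normal((2, 20, 32, 32)).astype(np.float32)
        model.eval()
        before = model.forward(x).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        restored.eval()
        assert np.allclose(restored.forward(x).data, before, atol=1e-7)
        assert restored.config.stage_channels == (4, 8)
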