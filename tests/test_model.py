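"""Architecture contracts: CBAM gates, even-kernel downsampling, shrink head,
clinical fusion, and whole-network invariants."""

import dataclasses

import numpy as np
import pytest

from pelvistrat.errors import ConfigurationError, ShapeError
from pelvistrat.model import (
    CBAM,
    Bottleneck,
    ChannelAttention,
    DifficultyNet,
    NetworkConfig,
    ShrinkHead,
    SpatialAttention,
    contains_pooling,
    desk_config,
    full_config,
)
from pelvistrat.nn import Tensor


def zeroed(module):
    for p in module.parameters():
        p.data[:] = 0.0
    return module


class TestChannelAttention:
    def test_zero_input_zero_weights_give_half_gate(self, rng):
        ca = zeroed(ChannelAttention(8, reduction=4, rng=rng))
        out = ca(Tensor(np.zeros((2, 8, 3, 3, 3), dtype=np.float32)))
        assert out.data.shape == (2, 8, 1, 1, 1)
        np.testing.assert_allclose(out.data, 0.5)

    def test_gate_values_strictly_in_unit_interval(self, rng):
        ca = ChannelAttention(8, reduction=4, rng=rng)
        out = ca(Tensor(rng.standard_normal((3, 8, 4, 4, 4)).astype(np.float32)))
        assert ((out.data > 0) & (out.data < 1)).all()

    def test_indivisible_reduction_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ChannelAttention(6, reduction=4, rng=rng)


class TestSpatialAttention:
    def test_zero_conv_gives_uniform_half_map(self, rng):
        sa = zeroed(SpatialAttention(3, rng=rng))
        x = rng.standard_normal((2, 8, 5, 5, 5)).astype(np.float32)
        out = sa(Tensor(x))
        assert out.data.shape == (2, 1, 5, 5, 5)
        np.testing.assert_allclose(out.data, 0.5)

    def test_bounded_and_shape_preserving(self, rng):
        sa = SpatialAttention(3, rng=rng)
        out = sa(Tensor(rng.standard_normal((1, 4, 6, 6, 6)).astype(np.float32)))
        assert out.data.shape == (1, 1, 6, 6, 6)
        assert ((out.data > 0) & (out.data < 1)).all()

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            SpatialAttention(4, rng=rng)


class TestCBAM:
    def test_shape_preserved_and_magnitude_never_amplified(self, rng):
        cbam = CBAM(8, reduction=4, kernel=3, rng=rng)
        x = rng.standard_normal((2, 8, 4, 4, 4)).astype(np.float32)
        out = cbam(Tensor(x))
        assert out.data.shape == x.shape
        # both gates are sigmoid outputs < 1, so attention can only attenuate
        assert (np.abs(out.data) <= np.abs(x) + 1e-6).all()


class TestShrinkHead:
    def test_output_vector_length_matches_shrink_width(self, rng):
        head = ShrinkHead(64, shrink=32, spatial=2, ds_kernel=2, rng=rng)
        out = head(Tensor(rng.standard_normal((1, 64, 2, 2, 2)).astype(np.float32)))
        assert out.data.shape == (1, 32)

    def test_positionally_sensitive_unlike_global_average_pooling(self, rng):
        head = ShrinkHead(4, shrink=8, spatial=4, ds_kernel=2, rng=rng)
        a = np.zeros((1, 4, 4, 4, 4), dtype=np.float32)
        b = np.zeros((1, 4, 4, 4, 4), dtype=np.float32)
        a[0, 0, 0, 0, 0] = 1.0
        b[0, 0, 3, 3, 3] = 1.0  # same content, different corner
        out_a = head(Tensor(a)).data
        out_b = head(Tensor(b)).data
        assert not np.allclose(out_a, out_b)

    def test_non_power_of_two_spatial_rejected(self, rng):
        with pytest.raises(ShapeError):
            ShrinkHead(8, shrink=8, spatial=3, ds_kernel=2, rng=rng)


class TestDownsamplingContract:
    def test_stage_transitions_halve_spatial_dims_exactly(self, rng):
        net = DifficultyNet(desk_config(), seed=0).eval()
        res = net.forward(rng.integers(0, 2, (1, 32, 32, 32)).astype(np.float32), np.full((1, 3), 0.5))
        shapes = {k: v.data.shape[2:] for k, v in res.stages.items()}
        assert shapes == {"layer1": (16,) * 3, "layer2": (8,) * 3, "layer3": (4,) * 3, "layer4": (2,) * 3}

    def test_odd_input_to_downsample_rejected(self, rng):
        block = Bottleneck(4, 8, 2, downsample=True, reduction=4, sa_kernel=3, ds_kernel=2, rng=rng)
        with pytest.raises(ShapeError):
            block(Tensor(rng.standard_normal((1, 4, 5, 5, 5)).astype(np.float32)))

    def test_odd_downsample_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(desk_config(), downsample_kernel=3).validate()

    def test_input_incompatible_with_head_rejected(self):
        with pytest.raises(ConfigurationError):
            dataclasses.replace(desk_config(), input_shape=(48, 48, 48)).validate()


class TestClinicalFusion:
    def test_covariates_change_the_logit(self, rng):
        net = DifficultyNet(desk_config(), seed=1).eval()
        vol = rng.integers(0, 2, (1, 32, 32, 32)).astype(np.float32)
        a = net.forward(vol, np.array([[0.2, 0.999, 0.001]]))
        b = net.forward(vol, np.array([[0.8, 0.001, 0.999]]))
        assert not np.allclose(a.logit.data, b.logit.data)

    def test_identity_reweight_makes_logit_clinical_independent(self, rng):
        net = DifficultyNet(desk_config(), seed=1).eval()
        net.reweight.weight.data[:] = 0.0
        net.reweight.bias.data[:] = 1.0
        vol = rng.integers(0, 2, (1, 32, 32, 32)).astype(np.float32)
        a = net.forward(vol, np.array([[0.2, 0.999, 0.001]]))
        b = net.forward(vol, np.array([[0.8, 0.001, 0.999]]))
        np.testing.assert_allclose(a.logit.data, b.logit.data, atol=1e-6)

    def test_zero_image_features_leave_classifier_bias(self, rng):
        net = DifficultyNet(desk_config(), seed=1).eval()
        net.classifier.bias.data[:] = 0.37
        # zero features short-circuit the multiplicative fusion
        from pelvistrat.nn import Tensor as T

        fused = T(np.zeros((1, net.head.out_dim), dtype=np.float32))
        logit = net.classifier(net.dropout(fused))
        assert logit.data.reshape(()) == pytest.approx(0.37)


class TestWholeNetwork:
    def test_score_in_unit_interval_and_eval_deterministic(self, rng):
        net = DifficultyNet(desk_config(), seed=2).eval()
        vol = rng.integers(0, 2, (2, 32, 32, 32)).astype(np.float32)
        clin = rng.random((2, 3)).astype(np.float32)
        s1 = net.forward(vol, clin).score.data
        s2 = net.forward(vol, clin).score.data
        assert ((s1 > 0) & (s1 < 1)).all()
        np.testing.assert_array_equal(s1, s2)

    def test_mirrored_input_changes_score(self, rng):
        net = DifficultyNet(desk_config(), seed=3).eval()
        vol = rng.integers(0, 2, (1, 32, 32, 32)).astype(np.float32)
        clin = np.full((1, 3), 0.5, dtype=np.float32)
        a = net.forward(vol, clin).score.data
        b = net.forward(vol[:, ::-1].copy(), clin).score.data
        assert not np.allclose(a, b)

    def test_wrong_input_shape_rejected(self, rng):
        net = DifficultyNet(desk_config(), seed=0)
        with pytest.raises(ShapeError):
            net.forward(np.zeros((1, 16, 16, 16), dtype=np.float32), np.full((1, 3), 0.5))

    def test_no_pooling_and_cbam_in_every_block_desk(self):
        net = DifficultyNet(desk_config(), seed=0)
        assert not contains_pooling(net)
        assert net.cbam_count() == sum(desk_config().stage_block_counts)

    def test_full_scale_graph_has_sixteen_cbam_blocks(self):
        cfg = full_config(input_side=64)
        net = DifficultyNet(cfg, seed=0)
        assert net.cbam_count() == 3 + 4 + 6 + 3
        assert not contains_pooling(net)
        assert net.n_parameters() > 10**6

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = DifficultyNet(desk_config(), seed=4).eval()
        vol = rng.integers(0, 2, (1, 32, 32, 32)).astype(np.float32)
        clin = np.full((1, 3), 0.5, dtype=np.float32)
        before = net.forward(vol, clin).score.data.copy()
        net.save(tmp_path / "ckpt.npz")
        other = DifficultyNet(desk_config(), seed=99).eval()
        other.load(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(other.forward(vol, clin).score.data, before, atol=1e-7)
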