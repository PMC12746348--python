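"""Network blocks against loop-based oracles, identity limits, shape and
connectivity contracts, receptive-field algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scdunet import (ChannelAttention, CoordinateAttention, DenseASPP,
                     NetworkConfig, ResidualStage, SCAttention, build_scdunet,
                     denseaspp_input_sets, dilated_receptive_field,
                     encoder_conv_count, stacked_receptive_field)
from scdunet.model import ResidualBlock, load_checkpoint, save_checkpoint
from scdunet.nn import Tensor

from oracles import (naive_batchnorm_eval, naive_channel_attention,
                     naive_conv2d, naive_coordinate_attention)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


# ---------------------------------------------------------------------------
# receptive-field algebra

@pytest.mark.parametrize("k,d,expected", [(3, 1, 3), (3, 2, 5), (3, 3, 7),
                                          (5, 1, 5), (5, 2, 9)])
def test_dilated_receptive_field(k, d, expected):
    assert dilated_receptive_field(k, d) == expected


@pytest.mark.parametrize("k1,k2,expected", [(7, 7, 13), (1, 9, 9), (3, 5, 7)])
def test_stacked_receptive_field(k1, k2, expected):
    assert stacked_receptive_field(k1, k2) == expected


def test_max_receptive_field_dense_chain():
    from scdunet import max_receptive_field
    # branch fields 3/5/7; the d3 branch sits on the d1->d2 chain (field 7),
    # so the pyramid maximum is 7 + 7 - 1 = 13
    assert max_receptive_field(3, [1, 2, 3]) == 13
    assert max_receptive_field(3, [1]) == 3
    assert max_receptive_field(3, [1, 2]) == 7
    assert max_receptive_field(3, [2, 5]) == 5 + 11 - 1


def test_receptive_field_rejects_bad_args():
    with pytest.raises(ValueError):
        dilated_receptive_field(0, 1)
    with pytest.raises(ValueError):
        dilated_receptive_field(4, 1)   # even kernel
    with pytest.raises(ValueError):
        stacked_receptive_field(0, 3)


# ---------------------------------------------------------------------------
# channel attention (cSE)

class TestChannelAttention:
    def test_global_pool_values(self):
        att = ChannelAttention(1, 1, dtype=np.float64)
        x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]))
        z = x.mean(axis=(2, 3))
        assert z.data[0, 0] == pytest.approx(2.5)
        ones = Tensor(np.ones((1, 1, 3, 3)))
        assert ones.mean(axis=(2, 3)).data[0, 0] == pytest.approx(1.0)

    def test_matches_loop_oracle_and_gate_bounds(self, rng):
        att = ChannelAttention(4, 2, rng=np.random.default_rng(5), dtype=np.float64)
        x = rng.standard_normal((2, 4, 8, 8))
        out = att(Tensor(x)).data
        expected = naive_channel_attention(
            x, att.fc1.weight.data, att.fc1.bias.data,
            att.fc2.weight.data, att.fc2.bias.data)
        assert np.allclose(out, expected, atol=1e-6)
        gates = att.gates(Tensor(x)).data
        assert ((gates > 0) & (gates < 1)).all()


# ---------------------------------------------------------------------------
# coordinate attention (CA)

class TestCoordinateAttention:
    def test_directional_pools(self):
        x = Tensor(np.array([[[[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]]]))
        zh = x.mean(axis=3).data[0, 0]
        zw = x.mean(axis=2).data[0, 0]
        assert np.allclose(zh, [2.0, 5.0])
        assert np.allclose(zw, [2.5, 3.5, 4.5])

    def test_all_ones_gates_are_identity(self, rng):
        att = CoordinateAttention(4, 2, dtype=np.float64)
        # saturate both branch sigmoids towards 1
        att.fc_h.weight.data[:] = 0
        att.fc_h.bias.data[:] = 40.0
        att.fc_w.weight.data[:] = 0
        att.fc_w.bias.data[:] = 40.0
        x = rng.standard_normal((1, 4, 3, 5))
        assert np.allclose(att(Tensor(x)).data, x, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        att = CoordinateAttention(8, 2, rng=np.random.default_rng(6), dtype=np.float64)
        x = rng.standard_normal((2, 8, 6, 5))
        out = att(Tensor(x)).data
        expected = naive_coordinate_attention(
            x, att.shared.weight.data, att.shared.bias.data,
            att.fc_h.weight.data, att.fc_h.bias.data,
            att.fc_w.weight.data, att.fc_w.bias.data)
        assert np.allclose(out, expected, atol=1e-6)


# ---------------------------------------------------------------------------
# SC fusion

class TestSCAttention:
    def test_sum_of_branches_exact(self, rng):
        att = SCAttention(4, 2, rng=np.random.default_rng(3), dtype=np.float64)
        x = Tensor(rng.standard_normal((2, 4, 5, 5)))
        fused = att(x).data
        assert np.array_equal(fused, att.channel(x).data + att.coordinate(x).data)

    def test_all_ones_gates_double_input(self, rng):
        att = SCAttention(4, 2, dtype=np.float64)
        for lin in (att.channel.fc2, att.coordinate.fc_h, att.coordinate.fc_w):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 40.0
        x = rng.standard_normal((1, 4, 4, 6))
        assert np.allclose(att(Tensor(x)).data, 2 * x, atol=1e-10)

    def test_matches_composed_oracle(self, rng):
        att = SCAttention(8, 4, rng=np.random.default_rng(8), dtype=np.float64)
        x = rng.standard_normal((2, 8, 7, 6))
        cse = naive_channel_attention(
            x, att.channel.fc1.weight.data, att.channel.fc1.bias.data,
            att.channel.fc2.weight.data, att.channel.fc2.bias.data)
        ca = naive_coordinate_attention(
            x, att.coordinate.shared.weight.data, att.coordinate.shared.bias.data,
            att.coordinate.fc_h.weight.data, att.coordinate.fc_h.bias.data,
            att.coordinate.fc_w.weight.data, att.coordinate.fc_w.bias.data)
        assert np.allclose(att(Tensor(x)).data, cse + ca, atol=1e-6)


# ---------------------------------------------------------------------------
# residual stage

def _eval_block_oracle(block, x):
    """Loop-conv + eval-BN + ReLU reference for one residual block."""
    y = x
    for body in (block.body1, block.body2):
        conv, bn = body[0], body[1]
        y = naive_conv2d(y, conv.weight.data, conv.bias.data, padding=1)
        y = naive_batchnorm_eval(y, bn.gamma.data, bn.beta.data,
                                 bn.running_mean, bn.running_var, bn.eps)
        y = np.maximum(y, 0.0)
    return x + y


class TestResidualStage:
    def test_zeroed_branches_identity(self, rng):
        stage = ResidualStage(3, dtype=np.float64).eval()
        for block in (stage.block1, stage.block2):
            for body in (block.body1, block.body2):
                body[0].weight.data[:] = 0
                body[0].bias.data[:] = 0
        x = rng.standard_normal((2, 3, 6, 6))
        assert np.array_equal(stage(Tensor(x)).data, x)

    def test_matches_loop_oracle(self, rng):
        stage = ResidualStage(2, rng=np.random.default_rng(2), dtype=np.float64)
        stage.eval()
        # give running stats non-trivial values
        for block in (stage.block1, stage.block2):
            for body in (block.body1, block.body2):
                body[1].running_mean[:] = rng.normal(0, 0.2, 2)
                body[1].running_var[:] = rng.uniform(0.5, 2.0, 2)
        x = rng.standard_normal((1, 2, 8, 8))
        expected = _eval_block_oracle(stage.block2,
                                      _eval_block_oracle(stage.block1, x))
        assert np.allclose(stage(Tensor(x)).data, expected, atol=1e-5)

    def test_shape_preserved(self, rng):
        stage = ResidualStage(4)
        x = rng.standard_normal((3, 4, 10, 12)).astype(np.float32)
        assert stage(Tensor(x)).shape == x.shape

    def test_channel_mismatch_raises(self, rng):
        stage = ResidualStage(4)
        with pytest.raises(ValueError):
            stage(Tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32)))


# ---------------------------------------------------------------------------
# dense ASPP

class TestDenseASPP:
    def test_connectivity_123(self):
        sched = denseaspp_input_sets([1, 2, 3])
        assert sched.input_sets == (frozenset(), frozenset({1}), frozenset({1, 2}))

    def test_single_layer(self):
        assert denseaspp_input_sets([5]).input_sets == (frozenset(),)

    def test_equal_dilations_rejected(self):
        with pytest.raises(ValueError):
            denseaspp_input_sets([2, 2])
        with pytest.raises(ValueError):
            denseaspp_input_sets([3, 1])
        with pytest.raises(ValueError):
            denseaspp_input_sets([])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=40), min_size=1,
                    max_size=6, unique=True))
    def test_connectivity_property(self, dils):
        dils = sorted(dils)
        sched = denseaspp_input_sets(dils)
        assert sched.input_sets[0] == frozenset()
        for l, s in enumerate(sched.input_sets, start=1):
            assert s == frozenset(i + 1 for i, d in enumerate(dils)
                                  if d < dils[l - 1])

    def test_layer3_input_channels(self):
        aspp = DenseASPP(16, dilations=(1, 2, 3), growth=4)
        assert aspp.branch_input_channels(3, 16) == 16 + 2 * 4
        assert aspp.branches[2][0].weight.shape == (4, 24, 3, 3)

    @pytest.mark.parametrize("dilations", [(1,), (1, 2), (1, 2, 3)])
    def test_spatial_size_preserved(self, rng, dilations):
        aspp = DenseASPP(8, dilations=dilations, growth=2)
        x = rng.standard_normal((1, 8, 14, 14)).astype(np.float32)
        assert aspp(Tensor(x)).shape == (1, 8, 14, 14)

    def test_matches_loop_oracle(self, rng):
        aspp = DenseASPP(4, dilations=(1, 2, 3), growth=2,
                         rng=np.random.default_rng(4), dtype=np.float64).eval()
        x = rng.standard_normal((1, 4, 10, 10))
        outputs = []
        for l, branch in enumerate(aspp.branches, start=1):
            feeds = [x] + [outputs[i - 1]
                           for i in sorted(aspp.schedule.input_sets[l - 1])]
            inp = np.concatenate(feeds, axis=1)
            conv, bn = branch[0], branch[1]
            y = naive_conv2d(inp, conv.weight.data, conv.bias.data,
                             dilation=conv.dilation, padding=conv.padding)
            y = naive_batchnorm_eval(y, bn.gamma.data, bn.beta.data,
                                     bn.running_mean, bn.running_var, bn.eps)
            outputs.append(np.maximum(y, 0.0))
        concat_all = np.concatenate([x] + outputs, axis=1)
        conv, bn = aspp.project[0], aspp.project[1]
        y = naive_conv2d(concat_all, conv.weight.data, conv.bias.data)
        y = naive_batchnorm_eval(y, bn.gamma.data, bn.beta.data,
                                 bn.running_mean, bn.running_var, bn.eps)
        expected = np.maximum(y, 0.0)
        assert np.allclose(aspp(Tensor(x)).data, expected, atol=1e-5)


# ---------------------------------------------------------------------------
# full network

class TestSCDUNet:
    def test_logit_shapes(self):
        cfg = NetworkConfig(base_channels=8, reduction_ratio=4)
        model = build_scdunet(cfg).eval()
        x = np.zeros((1, 1, 64, 64), np.float32)
        assert model(Tensor(x)).shape == (1, 3, 64, 64)

    def test_indivisible_input_rejected(self):
        model = build_scdunet(NetworkConfig(base_channels=8)).eval()
        with pytest.raises(ValueError, match="divisible"):
            model(Tensor(np.zeros((1, 1, 60, 60), np.float32)))

    def test_eval_forward_deterministic(self, rng):
        model = build_scdunet(NetworkConfig(base_channels=8, reduction_ratio=4)).eval()
        x = rng.standard_normal((1, 1, 32, 32)).astype(np.float32)
        a = model(Tensor(x)).data
        b = model(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_same_init_seed_same_weights(self):
        cfg = NetworkConfig(base_channels=8, init_seed=11)
        a = build_scdunet(cfg)
        b = build_scdunet(cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_sc_placement_variants(self, rng):
        x = Tensor(rng.standard_normal((1, 1, 16, 16)).astype(np.float32))
        for placement in ("encoder", "decoder", "both"):
            cfg = NetworkConfig(base_channels=4, stages=2, reduction_ratio=2,
                                sc_placement=placement)
            model = build_scdunet(cfg).eval()
            assert model(x).shape == (1, 3, 16, 16)

    def test_bilinear_upsample_variant(self, rng):
        cfg = NetworkConfig(base_channels=4, stages=2, reduction_ratio=2,
                            upsample="bilinear")
        model = build_scdunet(cfg).eval()
        x = Tensor(rng.standard_normal((1, 1, 16, 16)).astype(np.float32))
        assert model(x).shape == (1, 3, 16, 16)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = NetworkConfig(base_channels=4, stages=2, reduction_ratio=2)
        model = build_scdunet(cfg).eval()
        save_checkpoint(model, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz").eval()
        x = Tensor(rng.standard_normal((1, 1, 16, 16)).astype(np.float32))
        assert np.array_equal(model(x).data, back(x).data)
        assert back.config.base_channels == 4


class TestEncoderConvCount:
    def test_default_is_twenty(self):
        assert encoder_conv_count(NetworkConfig()) == 20

    def test_single_stage(self):
        assert encoder_conv_count(NetworkConfig(stages=1)) == 5

    def test_zero_stages_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(stages=0)

    def test_count_matches_built_model(self):
        """The stated convention (4 residual convs + 1 downsampling conv per
        stage) agrees with the layers actually instantiated."""
        cfg = NetworkConfig(base_channels=4, stages=3, reduction_ratio=2)
        model = build_scdunet(cfg)
        n_convs = 0
        for stage in model.enc_stages:
            for block in (stage.block1, stage.block2):
                n_convs += 2
        n_convs += len(model.downs)
        assert n_convs == encoder_conv_count(cfg)
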