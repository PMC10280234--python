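"""Architecture contracts: attention gate, residual blocks, upsamplers,
shape/determinism guarantees and parameter/FLOP accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carn.autodiff import Tensor
from carn.model import (CARB, CarnConfig, CarnModel, CARetention, Upsampler,
                        count_flops, count_parameters, default_reduction,
                        load_checkpoint, save_checkpoint)


def _zero_trunk(block: CARB) -> None:
    for conv in block.convs:
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0


# ---------------------------------------------------------------- attention

def test_sqrt_c_rule_gives_bottleneck_width_8_for_64_channels():
    cfg = CarnConfig(channels=64)
    assert cfg.reduction == 8 == default_reduction(64)
    assert cfg.gate_width == 8
    gate = CARetention(64, 8, np.random.default_rng(0))
    assert gate.down.out_channels == 8
    assert gate.up.out_channels == 64


def test_zeroed_gate_path_outputs_one_half(rng):
    gate = CARetention(8, 4, rng)
    for conv in (gate.down, gate.up):
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
    out = gate(Tensor(rng.random((2, 8, 5, 5)))).data
    np.testing.assert_array_equal(out, np.full((2, 8, 1, 1), 0.5))


def test_pooled_descriptor_of_constant_channels(rng):
    # a constant channel pools to exactly its value
    gate = CARetention(4, 2, rng)
    vals = np.array([0.1, -0.7, 2.0, 0.0])
    f = Tensor(np.broadcast_to(vals[None, :, None, None], (1, 4, 6, 6)).copy())
    pooled = f.mean(axis=(2, 3), keepdims=True)
    np.testing.assert_allclose(pooled.data[0, :, 0, 0], vals, rtol=1e-12)
    assert gate(f).data.shape == (1, 4, 1, 1)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(1, 8), st.integers(0, 2**31 - 1))
def test_gate_entries_strictly_inside_unit_interval(reduction, seed):
    rng = np.random.default_rng(seed)
    gate = CARetention(8, reduction, rng)
    out = gate(Tensor(rng.standard_normal((1, 8, 4, 4)) * 10)).data
    assert np.all(out > 0.0) and np.all(out < 1.0)


def test_gate_rejects_bad_reduction_and_nonfinite_input(rng):
    with pytest.raises(ValueError):
        CARetention(8, 0, rng)
    with pytest.raises(ValueError):
        CARetention(8, 9, rng)
    gate = CARetention(8, 2, rng)
    bad = np.ones((1, 8, 4, 4))
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        gate(Tensor(bad))


# ---------------------------------------------------------------- CARB

def test_zero_trunk_makes_carb_exact_identity(rng):
    block = CARB(8, 3, 3, 2, rng)
    _zero_trunk(block)
    x = rng.standard_normal((2, 8, 6, 7))
    out = block(Tensor(x)).data
    np.testing.assert_array_equal(out, x)  # bit-level identity


def test_carb_matches_stepwise_oracle_composition(rng):
    """conv -> relu -> conv -> pool -> 1x1 down -> relu -> 1x1 up -> sigmoid
    -> channel scale -> residual add, written out with explicit loops."""
    c, red = 8, 3
    block = CARB(c, red, 3, 2, rng)
    x = rng.standard_normal((c, 4, 4))

    def conv_loops(inp, w, b, pad):
        ci, h, wd = inp.shape
        co, _, kh, kw = w.shape
        xp = np.pad(inp, ((0, 0), (pad, pad), (pad, pad)))
        out = np.zeros((co, xp.shape[1] - kh + 1, xp.shape[2] - kw + 1))
        for o in range(co):
            for y in range(out.shape[1]):
                for xx in range(out.shape[2]):
                    out[o, y, xx] = b[o] + np.sum(
                        w[o] * xp[:, y:y + kh, xx:xx + kw]
                    )
        return out

    h = conv_loops(x, block.convs[0].weight.data, block.convs[0].bias.data, 1)
    h = np.maximum(h, 0.0)
    trunk = conv_loops(h, block.convs[1].weight.data, block.convs[1].bias.data, 1)
    pooled = trunk.mean(axis=(1, 2))[:, None, None]
    d = conv_loops(pooled, block.attention.down.weight.data,
                   block.attention.down.bias.data, 0)
    d = np.maximum(d, 0.0)
    u = conv_loops(d, block.attention.up.weight.data,
                   block.attention.up.bias.data, 0)
    gate = 1.0 / (1.0 + np.exp(-u))
    expected = x + gate * trunk

    out = block(Tensor(x[None])).data[0]
    np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-12)


def test_carb_preserves_shape_and_rejects_channel_mismatch(rng):
    block = CARB(8, 3, 3, 2, rng)
    assert block(Tensor(rng.random((1, 8, 16, 16)))).data.shape == (1, 8, 16, 16)
    with pytest.raises(ValueError, match="channels"):
        block(Tensor(rng.random((1, 4, 8, 8))))


# ---------------------------------------------------------------- upsampler

@pytest.mark.parametrize("scale,n_groups", [(2, 1), (4, 2), (8, 3)])
def test_power_of_two_scales_use_one_group_per_doubling(rng, scale, n_groups):
    up = Upsampler(scale, 8, 3, rng)
    assert len(up.convs) == n_groups
    assert all(conv.out_channels == 4 * 8 for conv in up.convs)
    out = up(Tensor(rng.random((1, 8, 5, 6)))).data
    assert out.shape == (1, 8, 5 * scale, 6 * scale)


def test_scale_3_expands_channels_nine_times(rng):
    up = Upsampler(3, 8, 3, rng)
    assert len(up.convs) == 1
    assert up.convs[0].out_channels == 9 * 8
    assert up(Tensor(rng.random((1, 8, 5, 5)))).data.shape == (1, 8, 15, 15)


def test_unsupported_scale_is_a_configuration_error(rng):
    with pytest.raises(ValueError):
        Upsampler(5, 8, 3, rng)
    with pytest.raises(ValueError):
        CarnConfig(scale=5)


# ---------------------------------------------------------------- full model

@pytest.mark.parametrize("scale", [2, 3, 4, 8])
def test_output_is_exactly_scale_times_input(scale):
    model = CarnModel(CarnConfig(scale=scale, n_carb=1, channels=8), seed=0)
    out = model(Tensor(np.random.default_rng(0).random((1, 3, 5, 7))))
    assert out.data.shape == (1, 3, 5 * scale, 7 * scale)


def test_zeroed_body_reduces_to_head_plus_upsampler(rng):
    """With every CARB trunk and the body-tail conv zeroed, the long skip
    means the output equals the head features rendered straight through
    the upsampler."""
    model = CarnModel(CarnConfig(scale=2, n_carb=3, channels=8), seed=4)
    for block in model.body:
        _zero_trunk(block)
    model.body_tail.weight.data[:] = 0.0
    model.body_tail.bias.data[:] = 0.0
    x = rng.random((1, 3, 8, 8))
    out = model(Tensor(x)).data

    means = np.asarray(model.config.rgb_means).reshape(1, 3, 1, 1)
    f0 = model.head(Tensor(x - means))
    ref = model.out_conv(model.upsampler(f0)).data + means
    np.testing.assert_array_equal(out, ref)


def test_forward_is_deterministic_given_seed(rng):
    x = rng.random((1, 3, 8, 8))
    a = CarnModel(CarnConfig(scale=2, n_carb=2, channels=8), seed=11)
    b = CarnModel(CarnConfig(scale=2, n_carb=2, channels=8), seed=11)
    np.testing.assert_array_equal(a(Tensor(x)).data, b(Tensor(x)).data)


def test_benchmark_defaults():
    cfg = CarnConfig()
    assert cfg.n_carb == 8 and cfg.channels == 64 and cfg.reduction == 8
    assert cfg.rgb_means == (0.7204, 0.4298, 0.6397)


def test_model_validates_input(rng):
    model = CarnModel(CarnConfig(scale=2, n_carb=1, channels=8), seed=0)
    with pytest.raises(ValueError):
        model(Tensor(rng.random((1, 4, 8, 8))))  # not RGB
    bad = rng.random((1, 3, 8, 8))
    bad[0, 0, 0, 0] = np.inf
    with pytest.raises(ValueError):
        model(Tensor(bad))


# ------------------------------------------------ parameter/FLOP accounting

def test_parameter_count_is_affine_in_depth():
    counts = [
        count_parameters(CarnModel(CarnConfig(scale=2, n_carb=n, channels=16)))
        for n in (2, 4, 6, 8)
    ]
    increments = np.diff(counts)
    assert np.all(increments > 0)
    assert len(set(increments)) == 1  # constant per-block increment


def test_flops_are_affine_in_depth_and_report_convention():
    f = {
        n: count_flops(CarnModel(CarnConfig(scale=2, n_carb=n)), (128, 128))
        for n in (4, 8, 12)
    }
    assert f[12]["flops"] - f[8]["flops"] == f[8]["flops"] - f[4]["flops"]
    assert "MAC" in f[8]["convention"]
    assert f[8]["input_hw"] == (128, 128)


# ---------------------------------------------------------------- checkpoints

def test_checkpoint_round_trip(tmp_path, rng):
    model = CarnModel(CarnConfig(scale=2, n_carb=2, channels=8), seed=5)
    path = tmp_path / "model.npz"
    save_checkpoint(path, model, update=42)
    loaded, meta = load_checkpoint(path)
    assert meta["update"] == 42
    assert loaded.config == model.config
    x = rng.random((1, 3, 8, 8))
    np.testing.assert_array_equal(loaded(Tensor(x)).data, model(Tensor(x)).data)
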