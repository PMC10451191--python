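"""Network assembly, ablation toggles, determinism and checkpoints."""

import dataclasses

import numpy as np
import pytest

from tailseg.attention import (ChannelAttentionState, SpatialAttentionState,
                               channel_attention, spatial_attention)
from tailseg.errors import ConfigError, DataError
from tailseg.network import (Bottleneck, NetworkConfig, build_model,
                             ca_res_block_forward, load_checkpoint,
                             model_forward, predict_mask, sa_bridge_forward,
                             save_checkpoint)
from tailseg.nn import SpatialAttention, tape


def count_modules(model, name_fragment):
    return sum(1 for n, _ in model.named_parameters() if name_fragment in n)


class TestBuildModel:
    def test_default_layout_has_16_gates_and_4_bridges(self):
        model = build_model(NetworkConfig(base_width=4), seed=0)
        assert count_modules(model, "ca.alpha") == 16
        assert count_modules(model, "bridge.weight") == 4

    def test_toggles_off_leave_no_attention_parameters(self, tiny_net_config):
        cfg = dataclasses.replace(tiny_net_config, use_channel_attention=False,
                                  use_spatial_bridge=False)
        model = build_model(cfg, seed=0)
        names = [n for n, _ in model.named_parameters()]
        assert not any("ca." in n or "bridge." in n for n in names)

    def test_same_config_and_seed_rebuilds_identically(self, tiny_net_config):
        m1 = build_model(tiny_net_config, seed=11)
        m2 = build_model(tiny_net_config, seed=11)
        assert m1.parameter_checksum() == m2.parameter_checksum()
        m3 = build_model(tiny_net_config, seed=12)
        assert m1.parameter_checksum() != m3.parameter_checksum()

    def test_parameter_count_is_a_pure_function_of_config(self, tiny_net_config):
        counts = {build_model(tiny_net_config, seed=s).num_parameters()
                  for s in (0, 1, 2)}
        assert len(counts) == 1

    def test_invalid_config_lists_offenders(self):
        cfg = NetworkConfig(base_width=2, upsample_mode="nearest")
        with pytest.raises(ConfigError) as exc:
            build_model(cfg, seed=0)
        assert "base_width" in str(exc.value)
        assert "upsample_mode" in str(exc.value)

    def test_ablation_lattice_builds_and_runs(self, tiny_net_config, rng):
        x = rng.random((1, 1, 32, 32))
        for ca in (False, True):
            for sa in (False, True):
                cfg = dataclasses.replace(tiny_net_config,
                                          use_channel_attention=ca,
                                          use_spatial_bridge=sa)
                out = model_forward(x, build_model(cfg, seed=0))
                assert out.shape == (1, 5, 32, 32)
                assert np.all(np.isfinite(out))


class TestCaResBlock:
    def test_zero_branch_reduces_to_activation(self, rng):
        block = Bottleneck(8, 4, 8, stride=1, use_ca=False, nam_style=False,
                           rng=rng)
        for name, p in block.named_parameters():
            if "conv" in name:
                p.data[:] = 0.0
        x = rng.normal(0, 1, (8, 6, 6))
        out = ca_res_block_forward(x, block)
        assert np.allclose(out, np.maximum(x, 0), atol=1e-12)

    def test_attention_differs_only_through_the_gate(self, rng):
        gen = np.random.default_rng(7)
        plain = Bottleneck(6, 4, 16, stride=1, use_ca=False, nam_style=False,
                           rng=np.random.default_rng(7))
        gated = Bottleneck(6, 4, 16, stride=1, use_ca=True, nam_style=False,
                           rng=np.random.default_rng(7))
        gated.ca.alpha.data[:] = rng.uniform(0.5, 1.5, 16)
        gated.ca.beta.data[:] = rng.normal(0, 0.5, 16)
        plain.eval()
        gated.eval()
        x = tape.Tensor(rng.normal(0, 1, (2, 6, 6, 6)))
        with tape.no_grad():
            # branch before the gate, shared by both blocks
            h = tape.relu(plain.bn1(plain.conv1(x)))
            h = tape.relu(plain.bn2(plain.conv2(h)))
            branch = plain.bn3(plain.conv3(h))
            short = plain.short_bn(plain.short_conv(x))
            expected_plain = np.maximum(branch.data + short.data, 0)
            state = ChannelAttentionState(
                gated.ca.alpha.data, gated.ca.beta.data,
                gated.ca.running_mean, gated.ca.running_var, gated.ca.eps)
            gated_branch = channel_attention(branch.data, state)
            expected_gated = np.maximum(gated_branch + short.data, 0)
        assert np.allclose(ca_res_block_forward(x.data, plain),
                           expected_plain, atol=1e-10)
        assert np.allclose(ca_res_block_forward(x.data, gated),
                           expected_gated, atol=1e-10)

    def test_stride_two_halves_extents_and_projects_channels(self, rng):
        block = Bottleneck(8, 8, 32, stride=2, use_ca=True, nam_style=False,
                           rng=rng)
        out = ca_res_block_forward(rng.normal(0, 1, (8, 10, 10)), block)
        assert out.shape == (32, 5, 5)


class TestSaBridge:
    def test_disabled_bridge_is_identity(self, rng):
        x = rng.normal(0, 1, (4, 8, 8))
        assert np.array_equal(sa_bridge_forward(x, None), x)

    def test_zero_kernel_halves_the_skip(self, rng):
        bridge = SpatialAttention(rng)
        bridge.weight.data[:] = 0.0
        bridge.bias.data[:] = 0.0
        x = rng.normal(0, 1, (4, 8, 8))
        assert np.allclose(sa_bridge_forward(x, bridge), 0.5 * x, atol=1e-12)

    def test_matches_functional_spatial_attention_bitwise(self, rng):
        bridge = SpatialAttention(rng)
        x = rng.normal(0, 1, (4, 9, 9))
        state = SpatialAttentionState(bridge.weight.data.copy(),
                                      float(bridge.bias.data[0]))
        assert np.array_equal(sa_bridge_forward(x, bridge),
                              spatial_attention(x, state))


class TestModelForward:
    def test_score_map_shape_contract(self, tiny_net_config, rng):
        model = build_model(tiny_net_config, seed=0)
        out = model_forward(rng.random((2, 1, 64, 64)), model)
        assert out.shape == (2, 5, 64, 64)
        assert np.all(np.isfinite(out))

    def test_inference_is_reproducible_to_the_bit(self, tiny_net_config, rng):
        model = build_model(tiny_net_config, seed=0)
        x = rng.random((1, 1, 32, 32))
        assert np.array_equal(model_forward(x, model), model_forward(x, model))

    def test_non_divisible_extent_gives_guidance(self, tiny_net_config, rng):
        model = build_model(tiny_net_config, seed=0)
        with pytest.raises(DataError, match="divisible by 32"):
            model_forward(rng.random((1, 1, 48, 48)), model)

    def test_argmax_ties_break_toward_lower_label(self, tiny_net_config):
        # scores with exact ties resolve to the smaller class index
        scores = np.zeros((1, 5, 2, 2))
        assert np.all(np.argmax(scores, axis=1) == 0)

    def test_saturated_gates_reproduce_attention_free_model(self,
                                                            tiny_net_config,
                                                            rng):
        att_cfg = tiny_net_config
        plain_cfg = dataclasses.replace(att_cfg, use_channel_attention=False,
                                        use_spatial_bridge=False)
        att = build_model(att_cfg, seed=5)
        plain = build_model(plain_cfg, seed=5)
        # share every parameter the two models have in common
        att_state = att.state_dict()
        plain.load_state_dict({k: att_state[k]
                               for k in plain.state_dict()})
        # saturate the gates: sigmoid(... + 50) == 1 to well below 1e-5
        for name, p in att.named_parameters():
            if name.endswith("ca.beta"):
                p.data[:] = 50.0
            if "bridge.weight" in name:
                p.data[:] = 0.0
            if "bridge.bias" in name:
                p.data[:] = 50.0
        x = rng.random((1, 1, 32, 32))
        assert np.allclose(model_forward(x, att), model_forward(x, plain),
                           atol=1e-5)


class TestPrediction:
    def test_predicted_labels_in_range(self, tiny_net_config, rng):
        model = build_model(tiny_net_config, seed=0)
        pred = predict_mask(rng.random((1, 32, 32)), model)
        assert pred.shape == (1, 32, 32)
        assert pred.min() >= 0 and pred.max() <= 4


class TestCheckpoint:
    def test_round_trip_preserves_everything(self, tiny_net_config, rng,
                                             tmp_path):
        model = build_model(tiny_net_config, seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == model.config
        assert loaded.parameter_checksum() == model.parameter_checksum()
        x = rng.random((1, 1, 32, 32))
        assert np.array_equal(model_forward(x, loaded),
                              model_forward(x, model))

    def test_config_compatibility_validated(self, tiny_net_config, tmp_path):
        model = build_model(tiny_net_config, seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        other = dataclasses.replace(tiny_net_config, base_width=8)
        with pytest.raises(ConfigError):
            load_checkpoint(path, expect_config=other)
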