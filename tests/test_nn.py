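"""Residual-network engine: block algebra, oracles, determinism, checkpoints."""

import numpy as np
import pytest

from pvcnet.nn import (
    BasicBlock,
    PretrainedWeightsUnavailable,
    ResNetSpec,
    ResidualBlockSpec,
    build_model,
    load_checkpoint,
    resnet18_spec,
    resnet_tiny_spec,
    save_checkpoint,
    softmax,
)


def brute_force_conv(x, w, stride=1, pad=1):
    """Direct nested-loop 2-D convolution oracle; w is (F, C, k, k)."""
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    out = np.zeros((n, f, ho, wo))
    for ni in range(n):
        for fi in range(f):
            for i in range(ho):
                for j in range(wo):
                    patch = xp[ni, :, i * stride : i * stride + k, j * stride : j * stride + k]
                    out[ni, fi, i, j] = np.sum(patch * w[fi])
    return out


def _block(cin, cout, stride, shortcut, seed=0):
    spec = ResidualBlockSpec(cin, cout, stride, shortcut)
    return BasicBlock(spec, np.random.default_rng(seed), norm_passthrough=True)


class TestResidualBlock:
    def test_zero_residual_identity_shortcut_is_relu(self):
        blk = _block(3, 3, 1, "identity")
        blk.conv1.weight.value[...] = 0.0
        blk.conv2.weight.value[...] = 0.0
        x = np.random.default_rng(1).normal(size=(2, 3, 5, 5))
        assert np.allclose(blk.forward(x), np.maximum(x, 0.0))

    def test_identity_equivalent_projection_is_relu(self):
        blk = _block(4, 4, 1, "projection")
        blk.conv1.weight.value[...] = 0.0
        blk.conv2.weight.value[...] = 0.0
        proj = blk.shortcut.layers[0]
        proj.weight.value[...] = np.eye(4)  # 1x1 kernel: (cout, cin)
        x = np.random.default_rng(2).normal(size=(2, 4, 6, 6))
        assert np.allclose(blk.forward(x), np.maximum(x, 0.0))

    def test_forward_matches_brute_force_convolution_oracle(self):
        blk = _block(2, 2, 1, "identity", seed=3)
        x = np.random.default_rng(4).normal(size=(1, 2, 4, 4))
        w1 = blk.conv1.weight.value.reshape(2, 2, 3, 3)
        w2 = blk.conv2.weight.value.reshape(2, 2, 3, 3)
        h = np.maximum(brute_force_conv(x, w1), 0.0)
        expected = np.maximum(brute_force_conv(h, w2) + x, 0.0)
        assert np.allclose(blk.forward(x), expected, atol=1e-5)

    def test_strided_projection_matches_oracle(self):
        blk = _block(2, 4, 2, "projection", seed=5)
        x = np.random.default_rng(6).normal(size=(1, 2, 6, 6))
        w1 = blk.conv1.weight.value.reshape(4, 2, 3, 3)
        w2 = blk.conv2.weight.value.reshape(4, 4, 3, 3)
        wp = blk.shortcut.layers[0].weight.value.reshape(4, 2, 1, 1)
        h = np.maximum(brute_force_conv(x, w1, stride=2), 0.0)
        f = brute_force_conv(h, w2)
        s = brute_force_conv(x, wp, stride=2, pad=0)
        assert np.allclose(blk.forward(x), np.maximum(f + s, 0.0), atol=1e-5)

    def test_identity_shortcut_requires_matching_dimensions(self):
        with pytest.raises(ValueError, match="identity"):
            ResidualBlockSpec(4, 8, 1, "identity")
        with pytest.raises(ValueError, match="identity"):
            ResidualBlockSpec(4, 4, 2, "identity")

    def test_gradient_flows_through_identity_even_with_zero_residual(self):
        blk = _block(3, 3, 1, "identity")
        blk.conv1.weight.value[...] = 0.0
        blk.conv2.weight.value[...] = 0.0
        x = np.abs(np.random.default_rng(7).normal(size=(1, 3, 4, 4))) + 0.1
        blk.forward(x)
        gx = blk.backward(np.ones((1, 3, 4, 4)))
        assert np.all(gx != 0.0)

    def test_pad_shortcut_adds_no_parameters(self):
        proj = _block(4, 8, 2, "projection")
        padded = _block(4, 8, 2, "pad")
        n_proj = sum(p.value.size for p in proj.params())
        n_pad = sum(p.value.size for p in padded.params())
        assert n_proj - n_pad == 8 * 4  # exactly the 1x1 projection matrix
        x = np.random.default_rng(8).normal(size=(1, 4, 6, 6))
        assert padded.forward(x).shape == (1, 8, 3, 3)


def spec_parameter_count(spec: ResNetSpec) -> int:
    """Independent layer-by-layer arithmetic count (convs, norms, head)."""
    total = spec.stem_channels * 3 * spec.stem_kernel**2 + 2 * spec.stem_channels
    cin = spec.stem_channels
    for si, cout in enumerate(spec.stage_channels):
        for bi in range(spec.blocks_per_stage):
            stride = 2 if (si > 0 and bi == 0) else 1
            total += cout * cin * 9 + 2 * cout      # conv1 + bn1
            total += cout * cout * 9 + 2 * cout     # conv2 + bn2
            if not (cin == cout and stride == 1) and spec.shortcut_mode == "projection":
                total += cout * cin + 2 * cout      # 1x1 projection + bn
            cin = cout
    total += spec.stage_channels[-1] * spec.num_classes + spec.num_classes
    return total


class TestModel:
    def test_softmax_head_outputs_probability_pairs(self):
        model = build_model(resnet_tiny_spec(), seed=0)
        x = np.random.default_rng(0).normal(size=(3, 3, 64, 64))
        p = model.predict_proba(x)
        assert p.shape == (3, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_same_seed_builds_identical_weights(self):
        a = build_model(resnet_tiny_spec(), seed=42)
        b = build_model(resnet_tiny_spec(), seed=42)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    @pytest.mark.parametrize("spec", [resnet18_spec(), resnet_tiny_spec()])
    def test_parameter_count_matches_arithmetic_oracle(self, spec):
        model = build_model(spec, seed=0)
        assert model.n_parameters() == spec_parameter_count(spec)

    def test_channels_double_when_feature_map_halves(self):
        specs = resnet18_spec().block_specs()
        for s in specs:
            if s.stride == 2:
                assert s.output_channels == 2 * s.input_channels
                assert s.shortcut == "projection"
            if s.shortcut == "identity":
                assert s.input_channels == s.output_channels

    def test_pretrained_backbone_without_weights_raises(self):
        with pytest.raises(PretrainedWeightsUnavailable, match="pretrained_backbone=False"):
            build_model(resnet18_spec(), pretrained_backbone=True)

    def test_backbone_loading_from_checkpoint_keeps_head_random(self, tmp_path):
        donor = build_model(resnet_tiny_spec(), seed=1)
        path = tmp_path / "backbone.npz"
        np.savez(path, **{f"{i}:{p.name}": p.value for i, p in enumerate(donor.backbone_params())})
        model = build_model(resnet_tiny_spec(), pretrained_backbone=True, seed=2,
                            backbone_weights=str(path))
        for pa, pb in zip(model.backbone_params(), donor.backbone_params()):
            assert np.array_equal(pa.value, pb.value)
        fresh = build_model(resnet_tiny_spec(), seed=2)
        assert np.array_equal(model.head.weight.value, fresh.head.weight.value)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_model(resnet_tiny_spec(), seed=3)
        x = np.random.default_rng(1).normal(size=(2, 3, 64, 64))
        before = model.predict_proba(x)
        path = str(tmp_path / "model.npz")
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert np.allclose(back.predict_proba(x), before)

    def test_softmax_is_a_valid_distribution_for_extreme_logits(self):
        z = np.array([[1e4, -1e4], [0.0, 0.0], [-50.0, 60.0]])
        p = softmax(z)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.all(np.isfinite(p))
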