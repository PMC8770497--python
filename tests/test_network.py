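"""Architecture accounting, probability-map contracts, and backprop correctness."""

import numpy as np
import pytest

from mafcdn.errors import ShapeError, ValidationError
from mafcdn.network import (
    PRESETS,
    ArchitectureConfig,
    FCDenseNet,
    build_network,
    focal_loss_with_logit_grad,
    preset,
)


def channel_and_param_oracle(cfg: ArchitectureConfig):
    """Closed-form per-stage channel counts and trainable-parameter total.

    Independent of the builder: plain arithmetic over the connectivity rules
    (down blocks concatenate input with output; up blocks forward only the
    new maps; TU keeps its channel count; dense layers are BN+3x3 conv,
    TD is BN+1x1 conv, the first conv is 3x3 on one input channel, the final
    conv is 1x1 to num_classes).
    """
    g = cfg.growth_rate

    def conv_p(cin, cout, k):
        return k * k * cin * cout + cout

    def bn_p(c):
        return 2 * c

    def dense_layer_p(cin):
        return bn_p(cin) + conv_p(cin, g, 3)

    params = conv_p(1, cfg.first_conv_channels, 3)
    trace = [("input", 1), ("first_conv", cfg.first_conv_channels)]
    ch = cfg.first_conv_channels
    skips = []
    for i, n in enumerate(cfg.down_block_layers):
        for j in range(n):
            params += dense_layer_p(ch + j * g)
        ch = ch + n * g
        skips.append(ch)
        trace.append((f"down_block_{i + 1}", ch))
        params += bn_p(ch) + conv_p(ch, ch, 1)
        trace.append((f"transition_down_{i + 1}", ch))
    for j in range(cfg.bottleneck_layers):
        params += dense_layer_p(ch + j * g)
    fwd = cfg.bottleneck_layers * g
    trace.append(("bottleneck_new", fwd))
    for i, n in enumerate(cfg.up_block_layers):
        params += conv_p(fwd, fwd, 3)  # transition up
        trace.append((f"transition_up_{i + 1}", fwd))
        cin = fwd + skips[-(i + 1)]
        trace.append((f"skip_concat_{i + 1}", cin))
        for j in range(n):
            params += dense_layer_p(cin + j * g)
        fwd = n * g
        trace.append((f"up_block_{i + 1}_new", fwd))
    final_stack = cin + cfg.up_block_layers[-1] * g
    trace.append(("final_stack", final_stack))
    params += conv_p(final_stack, cfg.num_classes, 1)
    trace.append(("logits", cfg.num_classes))
    return trace, params


ALL_VARIANTS = ["FC-DenseNet56", "FC-DenseNet67", "FC-DenseNet103", "tiny"]


class TestArchitecture:
    @pytest.mark.parametrize("name", ALL_VARIANTS)
    def test_channel_trace_and_param_count_match_oracle(self, name):
        cfg = preset(name)
        net, trace = build_network(cfg, seed=0)
        ref_trace, ref_params = channel_and_param_oracle(cfg)
        assert trace == ref_trace
        assert net.n_params == ref_params

    def test_down_path_grows_linearly_up_path_does_not(self):
        cfg = preset("FC-DenseNet103")
        _, trace = build_network(cfg, seed=0)
        t = dict(trace)
        ch = cfg.first_conv_channels
        for i, n in enumerate(cfg.down_block_layers):
            ch += n * cfg.growth_rate  # input concatenated with output
            assert t[f"down_block_{i + 1}"] == ch
        for i, n in enumerate(cfg.up_block_layers):
            assert t[f"up_block_{i + 1}_new"] == n * cfg.growth_rate  # new maps only

    def test_tiny_first_down_block_channels(self, tiny_arch):
        _, trace = build_network(tiny_arch, seed=0)
        assert dict(trace)["down_block_1"] == 16 + 2 * 8

    def test_named_preset_structures(self):
        assert preset("FC-DenseNet103").down_block_layers == (4, 5, 7, 10, 12)
        assert preset("FC-DenseNet103").bottleneck_layers == 15
        assert preset("FC-DenseNet103").up_block_layers == (12, 10, 7, 5, 4)
        assert preset("FC-DenseNet56").growth_rate == 12
        assert all(n == 4 for n in preset("FC-DenseNet56").down_block_layers)
        for name in ("FC-DenseNet56", "FC-DenseNet67", "FC-DenseNet103"):
            assert preset(name).dropout_p == 0.2
            assert preset(name).num_classes == 2

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValidationError, match="FC-DenseNet56"):
            preset("FC-DenseNet-999")

    def test_mirror_invariant_enforced(self):
        with pytest.raises(ValidationError):
            ArchitectureConfig(down_block_layers=(2, 2), up_block_layers=(2,))

    def test_indivisible_input_raises_shape_error(self, tiny_arch):
        net, _ = build_network(tiny_arch, seed=0)
        with pytest.raises(ShapeError, match="4"):
            net.forward_logits(np.zeros((1, 1, 63, 63), dtype=np.float32))


class TestForward:
    def test_output_is_probability_map_at_input_resolution(self, tiny_arch, rng):
        net, _ = build_network(tiny_arch, seed=0)
        img = rng.random((16, 24))
        pm = net.predict_proba_map(img)
        assert (pm.height, pm.width) == (16, 24)
        assert np.all(pm.probs >= 0)
        assert np.allclose(pm.probs.sum(axis=2), 1.0, atol=1e-6)

    def test_inference_deterministic_dropout_off(self, tiny_arch, rng):
        net, _ = build_network(tiny_arch, seed=0)
        x = rng.random((1, 1, 16, 16)).astype(np.float32)
        a = net.predict_proba(x)
        b = net.predict_proba(x)
        assert np.array_equal(a, b)

    def test_dropout_seed_reproduces_training_forward(self, tiny_arch, rng):
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        outs = []
        for _ in range(2):
            net, _ = build_network(tiny_arch, seed=0)
            net.seed_dropout(99)
            outs.append(net.forward_logits(x, train=True))
        assert np.array_equal(outs[0], outs[1])


class TestBackprop:
    def test_analytic_gradients_match_finite_differences(self, micro_arch, rng):
        """Directional finite-difference check through every layer type."""
        net = FCDenseNet(micro_arch, seed=3).astype(np.float64)
        x = rng.random((2, 1, 8, 8))
        y = (rng.random((2, 8, 8)) < 0.2).astype(np.int64)
        alpha, gamma = np.array([0.75, 0.25]), 2.0

        def loss_of():
            logits = net.forward_logits(x, train=True)
            return focal_loss_with_logit_grad(logits, y, alpha, gamma)

        _, g = loss_of()
        net.backward(g)
        layers = net.iter_layers()
        grads = [{k: v.copy() for k, v in l.grads.items()} for l in layers]
        eps = 1e-6
        for li, layer in enumerate(layers):
            for k, p in layer.params.items():
                d = np.random.default_rng(li).standard_normal(p.shape)
                p += eps * d
                lp, _ = loss_of()
                p -= 2 * eps * d
                lm, _ = loss_of()
                p += eps * d
                num = (lp - lm) / (2 * eps)
                ana = float((grads[li][k] * d).sum())
                assert abs(num - ana) < 1e-7 + 1e-5 * (abs(num) + abs(ana)), (
                    type(layer).__name__,
                    k,
                )

    def test_fused_logit_gradient_matches_loss_definition(self, rng):
        """The fused softmax+focal gradient agrees with finite differences of
        focal_loss(softmax(logits)) for several (alpha, gamma) settings."""
        from mafcdn.image_core import MaskImage, ProbabilityMap
        from mafcdn.network import FocalConfig, focal_loss, softmax_logits

        z = rng.standard_normal((1, 2, 4, 4))
        y = (rng.random((1, 4, 4)) < 0.3).astype(np.int64)
        for alpha_ma, gamma in [(1.0, 0.0), (0.25, 2.0), (0.5, 1.0)]:
            alpha_t = FocalConfig(alpha_ma, gamma).alpha_t

            def loss_at(zz):
                p = softmax_logits(zz)[0].transpose(1, 2, 0)
                return focal_loss(ProbabilityMap(p), MaskImage(y[0]), FocalConfig(alpha_ma, gamma))

            l0, g = focal_loss_with_logit_grad(z, y, alpha_t, gamma)
            assert l0 == pytest.approx(loss_at(z), rel=1e-12)
            eps = 1e-6
            for _ in range(5):
                d = rng.standard_normal(z.shape)
                num = (loss_at(z + eps * d) - loss_at(z - eps * d)) / (2 * eps)
                assert num == pytest.approx(float((g * d).sum()), rel=1e-4, abs=1e-9)
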