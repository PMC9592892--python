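import numpy as np
import pytest

from lenseg.le_net import (
    DecoderFuse,
    FeatureMap,
    LEConfig,
    LEModule,
    Network,
    NetworkConfig,
    build_network,
    decoder_fuse,
    le_forward,
    network_forward,
)
from lenseg.nn.autograd import Tensor


class TestLEConfig:
    def test_default_rates(self):
        assert LEConfig(8, 4).dilation_rates == (1, 6, 12, 18)

    @pytest.mark.parametrize("rates", [(2, 6, 12, 18), (1, 6, 6, 18), (1, 18, 12, 6)])
    def test_bad_rates_rejected(self, rates):
        with pytest.raises(ValueError):
            LEConfig(8, 4, dilation_rates=rates)


class TestLEModule:
    def test_six_branch_concat_and_one_sixth_reduction(self, rng):
        # full-model widths: 256 in, 256 per branch
        module = LEModule(LEConfig(256, 256), rng=rng)
        module.eval()
        x = Tensor(rng.normal(size=(1, 256, 26, 26)))
        x_t5, x_t4 = module(x, return_concat=True)
        assert x_t4.shape == (1, 1536, 26, 26)
        assert x_t5.shape == (1, 256, 26, 26)
        assert x_t4.shape[1] == 6 * x_t5.shape[1]

    def test_tiny_shape_contract(self, rng):
        out = le_forward(rng.normal(size=(12, 8, 8)), LEConfig(12, 6))
        assert out.shape == (6, 8, 8)

    @pytest.mark.parametrize("hw", [(1, 1), (3, 5), (16, 16)])
    def test_spatial_dims_preserved(self, hw, rng):
        h, w = hw
        out = le_forward(rng.normal(size=(4, h, w)), LEConfig(4, 2))
        assert out.shape == (2, h, w)

    def test_constant_input_propagates_and_pool_equals_1x1(self, rng):
        """With averaging depthwise kernels and identity pointwise maps, a
        constant field stays constant in every branch, and the global-pool
        branch output equals the 1x1-conv branch output (pre-normalisation)."""
        cfg = LEConfig(3, 3)
        module = LEModule(cfg, use_bn=False, rng=rng)
        eye = np.eye(3)[:, :, None, None]
        module.conv1x1.weight.data = eye.copy()
        module.conv1x1.bias.data[:] = 0.0
        module.pool_conv.weight.data = eye.copy()
        module.pool_conv.bias.data[:] = 0.0
        for ds in module.dilated + [module.reduce]:
            c = ds.depthwise.weight.data.shape[0]
            ds.depthwise.weight.data = np.full((c, 1, 3, 3), 1.0 / 9.0)
            ds.depthwise.bias.data[:] = 0.0
            ds.pointwise.weight.data = np.eye(ds.pointwise.weight.data.shape[0], c)[:, :, None, None]
            ds.pointwise.bias.data[:] = 0.0

        c0 = np.array([1.5, -2.0, 0.25])
        x = Tensor(np.broadcast_to(c0[None, :, None, None], (1, 3, 9, 9)).copy())
        x_t5, x_t4 = module(x, return_concat=True)
        # interior pixels of every branch are the constant (borders feel zero padding)
        interior = x_t4.data[0, :, 4, 4].reshape(6, 3)
        assert np.allclose(interior[0], c0)  # 1x1 branch
        assert np.allclose(interior[5], c0)  # pooling branch
        assert np.allclose(interior[5], interior[0])

    def test_channel_mismatch_raises(self, rng):
        module = LEModule(LEConfig(4, 2), rng=rng)
        with pytest.raises(ValueError):
            module(Tensor(rng.normal(size=(1, 5, 8, 8))))


class TestDecoderFuse:
    def test_shape_contract(self, rng):
        out = decoder_fuse(rng.normal(size=(8, 4, 4)), rng.normal(size=(4, 8, 8)), 8)
        assert out.shape == (8, 8, 8)

    def test_full_scale_shape_contract(self, rng):
        out = decoder_fuse(
            rng.normal(size=(16, 26, 26)), rng.normal(size=(8, 52, 52)), 16
        )
        assert out.shape == (16, 52, 52)

    def test_resolution_mismatch_names_both_shapes(self, rng):
        module = DecoderFuse(4, 4, 8, rng=rng)
        with pytest.raises(ValueError, match=r"\(9, 9\).*\(4, 4\)|\(4, 4\).*\(9, 9\)"):
            module(Tensor(rng.normal(size=(1, 4, 4, 4))),
                   Tensor(rng.normal(size=(1, 4, 9, 9))))


class TestBuildNetwork:
    @pytest.mark.parametrize("variant", ["base", "base_le", "base_le_decoder"])
    def test_output_resolution_equals_input(self, variant, rng):
        net = build_network(NetworkConfig(variant=variant), seed=1)
        net.eval()
        main, aux = net(Tensor(rng.normal(size=(1, 1, 64, 64))))
        assert main.shape == (1, 3, 64, 64)
        assert [a.shape for a in aux] == [(1, 3, 8, 8), (1, 3, 16, 16)]

    def test_parameter_count_ordering(self):
        counts = {
            v: build_network(NetworkConfig(variant=v), seed=0).num_parameters()
            for v in ("base", "base_le", "base_le_decoder")
        }
        assert counts["base_le_decoder"] > counts["base_le"] > counts["base"]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(variant="dense_aspp")

    def test_aux_weights_must_match_stages(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_decoder_stages=3, aux_weights=(0.2, 0.3))
        with pytest.raises(ValueError):
            NetworkConfig(aux_weights=(0.3, 0.2))  # must not decrease

    def test_same_seed_same_weights(self):
        a = build_network(NetworkConfig(), seed=5)
        b = build_network(NetworkConfig(), seed=5)
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb and np.array_equal(pa.data, pb.data)


class TestNetworkForward:
    def test_eval_mode_returns_main_only_and_deterministic(self, rng):
        net = build_network(NetworkConfig(variant="base_le"), seed=2)
        net.eval()
        x = rng.normal(size=(1, 1, 32, 32))
        out1 = network_forward(net, x)
        out2 = network_forward(net, x)
        assert not isinstance(out1, tuple)
        assert out1.shape == (1, 3, 32, 32)
        assert np.array_equal(out1.data, out2.data)

    def test_training_mode_returns_aux(self, rng):
        net = build_network(NetworkConfig(), seed=2)
        net.train()
        main, aux = network_forward(net, rng.normal(size=(2, 1, 32, 32)))
        assert len(aux) == 2

    def test_predict_shape_and_classes(self, small_phantom_batch):
        images, _ = small_phantom_batch
        net = build_network(NetworkConfig(), seed=0)
        pred = net.predict(images[:1])
        assert pred.shape == (1, 64, 64)
        assert set(np.unique(pred)) <= {0, 1, 2}

    def test_indivisible_input_errors_unless_padding_enabled(self, rng):
        net = build_network(NetworkConfig(), seed=0)
        net.eval()
        with pytest.raises(ValueError, match="output stride"):
            net(Tensor(rng.normal(size=(1, 1, 50, 50))))
        net_pad = build_network(NetworkConfig(pad_to_stride=True), seed=0)
        net_pad.eval()
        main, _ = net_pad(Tensor(rng.normal(size=(1, 1, 50, 50))))
        assert main.shape == (1, 3, 50, 50)

    def test_resnet_style_encoder_builds_and_runs(self, rng):
        cfg = NetworkConfig(encoder="resnet50-style", variant="base_le",
                            branch_channels=16)
        net = build_network(cfg, seed=0)
        net.eval()
        main, _ = net(Tensor(rng.normal(size=(1, 1, 32, 32))))
        assert main.shape == (1, 3, 32, 32)


def test_feature_map_validation():
    with pytest.raises(ValueError):
        FeatureMap(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        FeatureMap(np.full((1, 2, 2), np.nan))
    fm = FeatureMap(np.zeros((3, 4, 5)))
    assert (fm.channels, fm.height, fm.width) == (3, 4, 5)
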