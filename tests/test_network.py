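import numpy as np
import pytest

from mhnet.autodiff import Tensor
from mhnet.losses import LossConfig, total_loss_graph
from mhnet.network import (
    InceptionBlock,
    MHNet,
    NetworkConfig,
    build_network,
    count_inception_params,
    forward,
)
from mhnet.volumes import Volume


class TestParameterAccounting:
    def test_paper_configuration_counts(self):
        cfg = NetworkConfig()
        assert count_inception_params(cfg, with_bottleneck=False) == 3968
        assert count_inception_params(cfg, with_bottleneck=True) == 1994

    def test_single_kernel_branch(self):
        cfg = NetworkConfig(inception_kernels=(1,))
        assert count_inception_params(cfg, with_bottleneck=False) == 8
        assert count_inception_params(cfg, with_bottleneck=True) == 8

    def test_bottleneck_always_cheaper_with_large_kernels(self):
        for kernels in [(1, 3), (3, 5), (1, 3, 5, 7), (3,)]:
            cfg = NetworkConfig(inception_kernels=kernels)
            assert count_inception_params(cfg, True) < count_inception_params(
                cfg, False
            )

    @pytest.mark.parametrize("with_bottleneck", [True, False])
    def test_formula_matches_instantiated_block(self, with_bottleneck):
        cfg = NetworkConfig(use_bottleneck=with_bottleneck)
        block = InceptionBlock(2, cfg, np.random.default_rng(0))
        assert block.param_count(include_bias=False) == count_inception_params(
            cfg, with_bottleneck=with_bottleneck
        )

    def test_formula_matches_block_nondefault_config(self):
        cfg = NetworkConfig(
            inception_kernels=(1, 3, 5),
            inception_branch_out=6,
            bottleneck_channels=2,
        )
        block = InceptionBlock(4, cfg, np.random.default_rng(0))
        assert block.param_count() == count_inception_params(
            cfg, with_bottleneck=True, in_channels=4
        )


class TestConfigValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            NetworkConfig(inception_kernels=(1, 2))

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError, match="4 levels"):
            NetworkConfig(enc_channels=(8, 8))

    def test_round_trip_dict(self):
        cfg = NetworkConfig(enc_channels=(4, 8, 8, 8), use_inception=False)
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg


class TestForward:
    def test_output_shapes_and_zero_init_identity(self, tiny_net_config, rng):
        net = build_network(tiny_net_config, seed=0)
        f = Volume(rng.random((16, 16, 16), dtype=np.float32))
        m = Volume(rng.random((16, 16, 16), dtype=np.float32))
        fields = forward(net, f, m)
        for phi in (fields.phi_low, fields.phi_mid, fields.phi_high,
                    fields.phi_end, fields.phi_final):
            assert phi.u.shape == (3, 16, 16, 16)
        # untrained net: zero-initialized field convs give the identity map
        assert np.all(fields.phi_final.u == 0)

    def test_indivisible_shape_raises(self, tiny_net_config, rng):
        net = build_network(tiny_net_config)
        v = Volume(rng.random((12, 12, 12)))
        with pytest.raises(ValueError, match="divisible by 16"):
            forward(net, v, v)

    def test_same_seed_same_parameters(self, tiny_net_config):
        a = build_network(tiny_net_config, seed=3)
        b = build_network(tiny_net_config, seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_forward_deterministic(self, tiny_net_config, rng):
        net = build_network(tiny_net_config, seed=0)
        f = rng.random((16, 16, 16), dtype=np.float32)
        m = rng.random((16, 16, 16), dtype=np.float32)
        u1 = net.predict_field(f, m)
        u2 = net.predict_field(f, m)
        np.testing.assert_array_equal(u1, u2)

    def test_without_hierarchical_final_equals_end(self, rng):
        cfg = NetworkConfig(
            enc_channels=(4, 8, 8, 8), dec_channels=(8, 8, 8, 4),
            use_hierarchical=False,
        )
        net = build_network(cfg, seed=0)
        x = Tensor(rng.random((2, 16, 16, 16), dtype=np.float32))
        fields = net.forward_graph(x)
        np.testing.assert_array_equal(fields.phi_final.data, fields.phi_end.data)

    @pytest.mark.parametrize(
        "use_inception,use_hierarchical",
        [(False, True), (True, False), (False, False)],
    )
    def test_ablation_variants_build_and_run(self, rng, use_inception,
                                             use_hierarchical):
        cfg = NetworkConfig(
            enc_channels=(4, 8, 8, 8), dec_channels=(8, 8, 8, 4),
            use_inception=use_inception, use_hierarchical=use_hierarchical,
        )
        net = build_network(cfg, seed=0)
        u = net.predict_field(
            rng.random((16, 16, 16), dtype=np.float32),
            rng.random((16, 16, 16), dtype=np.float32),
        )
        assert u.shape == (3, 16, 16, 16)

    def test_inception_block_output_channels(self, rng):
        cfg = NetworkConfig()
        block = InceptionBlock(2, cfg, np.random.default_rng(0))
        out = block(Tensor(rng.random((2, 8, 8, 8), dtype=np.float32)))
        assert out.shape == (16, 8, 8, 8)


class TestGradientFlow:
    def test_all_parameters_receive_gradients(self, tiny_net_config, rng):
        """After the first update moves the field heads off zero, every
        parameter of the network — earliest encoder conv through each
        hierarchical head — must receive a non-null gradient."""
        from mhnet.training import Adam

        net = build_network(tiny_net_config, seed=0, dtype=np.float64)
        f = rng.random((16, 16, 16))
        m = rng.random((16, 16, 16))
        cfg = LossConfig(ncc_window=5)
        opt = Adam(net.parameters(), lr=1e-3)
        for _ in range(2):
            fields = net.forward_graph(Tensor(np.stack([f, m])))
            loss = total_loss_graph(Tensor(f), Tensor(m), fields.phi_final, cfg)
            opt.zero_grad()
            loss.backward()
            opt.step()
        missing = [
            i for i, p in enumerate(net.parameters())
            if p.grad is None or not np.any(p.grad != 0)
        ]
        assert missing == []
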