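"""Architecture builders, forward-pass contracts, and parameter accounting."""

import numpy as np
import pytest

from mvcnn3d import (
    ArchitectureSpec,
    build_chain,
    build_inception,
    build_inception_resnet,
    build_network,
    build_one_view_ensemble,
    count_parameters,
    figure_config,
    inception_module,
)
from mvcnn3d.layers import (
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MaxPool3D,
    ReLU,
    Residual,
    Sequential,
    SpatialDropout,
)


def _input(n_views=3, batch=2, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(batch, 6, 50, 50, n_views)).astype(np.float32)


class TestChain:
    def test_cnn1_layer_sequence(self):
        net = build_chain(ArchitectureSpec(family="chain", depth_m=1, n_views=3))
        kinds = [type(l).__name__ for l in net.layers]
        assert kinds == [
            "Conv3D",
            "ReLU",
            "SpatialDropout",
            "MaxPool3D",
            "Flatten",
            "Dense",
            "ReLU",
            "Dropout",
            "Dense",
        ]
        conv = net.layers[0]
        assert conv.kernel == (3, 5, 5)
        assert (conv.in_channels, conv.out_channels) == (3, 20)
        fc = net.layers[5]
        assert fc.w.shape == (3 * 25 * 25 * 20, 128)
        assert net.layers[-1].w.shape == (128, 2)

    def test_softmax_family_is_affine_classifier(self):
        net = build_chain(ArchitectureSpec(family="softmax", n_views=1))
        assert [type(l).__name__ for l in net.layers] == ["Flatten", "Dense"]
        assert net.layers[-1].w.shape == (6 * 50 * 50, 2)

    @pytest.mark.parametrize("m", [0, 1, 2, 3])
    def test_forward_is_probability_vector(self, m):
        family = "softmax" if m == 0 else "chain"
        net = build_chain(ArchitectureSpec(family=family, depth_m=m, n_classes=3))
        probs = net.predict_proba(np.zeros((2, 6, 50, 50, 3), dtype=np.float32))
        assert probs.shape == (2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)

    def test_cnn3_filter_plan(self):
        net = build_chain(ArchitectureSpec(family="chain", depth_m=3))
        convs = [l for l in net.layers if isinstance(l, Conv3D)]
        assert [c.kernel for c in convs] == [(3, 5, 5), (3, 5, 5), (2, 3, 3)]
        assert [c.out_channels for c in convs] == [20, 50, 50]
        # the third pool meets a Z=1 map; the clipped window must still work
        probs = net.predict_proba(_input())
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(family="chain", depth_m=4)


class TestInceptionModule:
    def test_variant2_factorizes_kernels(self):
        mod = inception_module(4, (2, 3, 5), variant=2)
        branch5 = mod.branches[2]
        kernels = [l.kernel for l in branch5.layers if isinstance(l, Conv3D)]
        assert kernels == [(1, 1, 5), (1, 5, 1), (5, 1, 1)]

    def test_output_channels_are_sum_of_branches(self, rng):
        mod = inception_module(3, (4, 5, 6), variant=1)
        x = rng.normal(size=(2, 4, 9, 9, 3)).astype(np.float32)
        y = mod.forward(x)
        assert y.shape == (2, 4, 9, 9, 15)

    def test_zero_weights_give_zero_output(self, rng):
        mod = inception_module(2, (2, 2, 2), variant=1)
        for layer in mod.iter_layers():
            for p in layer.params:
                p[...] = 0.0
        x = rng.normal(size=(1, 3, 7, 7, 2)).astype(np.float32)
        assert np.all(mod.forward(x) == 0.0)


class TestInception:
    @pytest.mark.parametrize(
        "n_classes, head_channels", [(2, 32), (3, 64)]
    )
    def test_head_configuration(self, n_classes, head_channels):
        spec = ArchitectureSpec(family="inception1", n_classes=n_classes)
        net = build_inception(spec)
        head_convs = [
            l for l in net.layers if isinstance(l, Conv3D) and l.kernel == (1, 1, 1)
        ]
        assert head_convs[-1].out_channels == head_channels
        pools = [l for l in net.layers if type(l).__name__ == "AvgPool3D"]
        assert pools[-1].sizes == (2, 3, 3)
        assert not any(
            isinstance(l, Dense) and not l.is_softmax for l in net.iter_layers()
        ), "the Inception nets have no fully connected layer"

    @pytest.mark.parametrize("family", ["inception1", "inception2"])
    def test_forward_probabilities(self, family):
        net = build_inception(ArchitectureSpec(family=family))
        probs = net.predict_proba(_input())
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)


class TestInceptionResNet:
    def _block(self, net):
        return next(l for l in net.layers if isinstance(l, Residual))

    def test_zero_branch_reduces_to_shortcut_activation(self, rng):
        net = build_inception_resnet(ArchitectureSpec(family="inception_resnet"))
        block = self._block(net)
        for layer in block.body.iter_layers():
            for p in layer.params:
                p[...] = 0.0
        x = rng.normal(size=(1, 3, 16, 16, 12)).astype(np.float32)
        np.testing.assert_array_equal(block.forward(x), np.maximum(x, 0))

    def test_residual_scaling_algebra(self, rng):
        net = build_inception_resnet(
            ArchitectureSpec(family="inception_resnet", residual_scale=0.1)
        )
        block = self._block(net)
        x = rng.normal(size=(1, 3, 16, 16, 12)).astype(np.float32)
        branch = block.body.forward(x)
        np.testing.assert_allclose(
            block.forward(x), np.maximum(x + 0.1 * branch, 0), rtol=1e-5, atol=1e-6
        )

    def test_scale_zero_equals_plain_shortcut(self, rng):
        spec = ArchitectureSpec(family="inception_resnet", residual_scale=0.0)
        net = build_inception_resnet(spec, seed=5)
        block = self._block(net)
        x = rng.normal(size=(1, 3, 16, 16, 12)).astype(np.float32)
        np.testing.assert_array_equal(block.forward(x), np.maximum(x, 0))

    def test_forward_probabilities(self):
        net = build_inception_resnet(ArchitectureSpec(family="inception_resnet"))
        probs = net.predict_proba(_input())
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)


class TestParameterAccounting:
    def test_dense_closed_form(self):
        net = Sequential([Flatten(), Dense(128, 2, is_softmax=True)])
        assert count_parameters(net).total_params == 128 * 2 + 2

    def test_conv_closed_form(self):
        net = Sequential([Conv3D((3, 5, 5), 3, 20)])
        assert count_parameters(net).total_params == 3 * 5 * 5 * 3 * 20 + 20

    @pytest.mark.parametrize("family", ["softmax", "chain"])
    def test_chain_totals_match_layerwise_sum(self, family):
        spec = ArchitectureSpec(family=family, depth_m=2)
        net = build_chain(spec)
        expected = 0
        for layer in net.iter_layers():
            if isinstance(layer, (Conv3D, Dense)):
                expected += int(np.prod(layer.w.shape)) + layer.b.size
        assert count_parameters(net).total_params == expected

    def test_inception1_reproduces_published_totals(self):
        binary = count_parameters(build_inception(ArchitectureSpec(family="inception1")))
        ternary = count_parameters(
            build_inception(ArchitectureSpec(family="inception1", n_classes=3))
        )
        # published totals: 0.47e5 (binary), 1.49e5 (ternary), 2 significant figures
        assert round(binary.total_params / 1e5, 2) == 0.47
        assert round(ternary.total_params / 1e5, 2) == 1.49
        assert binary.r_f == 3 and ternary.r_f == 3

    def test_figure_config_is_the_source_of_widths(self):
        cfg = figure_config()
        spec = ArchitectureSpec(family="inception1")
        net = build_inception(spec)
        stem = net.layers[0]
        assert stem.out_channels == cfg["binary"]["stem_channels"]


class TestOneViewEnsemble:
    def test_variant1_is_about_three_networks_worth(self):
        spec = ArchitectureSpec(family="inception1", n_views=3)
        multi = count_parameters(build_network(spec))
        ens = count_parameters(build_one_view_ensemble(spec, reduced_channels=False))
        single_equiv = 3 * multi.total_params
        # first-layer filters shrink 3x per sub-network, everything else triples
        assert 0.8 * single_equiv <= ens.total_params <= single_equiv
        assert ens.r_f == 1

    def test_variant2_matches_multi_view_budget(self):
        spec = ArchitectureSpec(family="inception1", n_views=3)
        multi = count_parameters(build_network(spec))
        ens = count_parameters(build_one_view_ensemble(spec, reduced_channels=True))
        assert 0.5 * multi.total_params <= ens.total_params <= 1.5 * multi.total_params
        assert ens.r_f == 1

    def test_single_view_spec_collapses_to_one_network(self):
        spec = ArchitectureSpec(family="inception1", n_views=1)
        ens = build_one_view_ensemble(spec)
        assert len(ens.networks) == 1

    def test_fused_prediction_is_mean_of_views(self, rng):
        spec = ArchitectureSpec(family="chain", depth_m=1, n_views=3)
        ens = build_one_view_ensemble(spec)
        x = rng.normal(size=(3, 6, 50, 50, 3)).astype(np.float32)
        probs = ens.predict_proba(x)
        manual = np.mean(
            [
                net.predict_proba(x[..., v : v + 1])
                for v, net in enumerate(ens.networks)
            ],
            axis=0,
        )
        np.testing.assert_allclose(probs, manual, rtol=1e-6)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)


class TestSpecSerialization:
    def test_yaml_round_trip(self, tmp_path):
        spec = ArchitectureSpec(
            family="inception2", n_classes=3, branch_widths=(4, 8, 12)
        )
        path = tmp_path / "arch.yaml"
        spec.to_yaml(path)
        loaded = ArchitectureSpec.from_yaml(path)
        assert loaded == spec
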