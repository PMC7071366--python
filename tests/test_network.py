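"""CNN primitives, the forward pass and its literal-equation oracle, training."""
import numpy as np
import pytest

from cinet.network import (ConvLayerSpec, Network, NetworkSpec, PoolSpec,
                           TrainConfig, TrainingDivergedError, conv_layer,
                           cuboid_convolve, decide, max_pool, train)
from cinet.reference import reference_forward


class TestCuboidConvolve:
    def test_all_ones_valid(self):
        """Brute-force oracle: 3*3*2 = 18 per output cell."""
        out = cuboid_convolve(np.ones((4, 4, 2)), np.ones((3, 3, 2)), "valid")
        assert out.shape == (2, 2)
        assert np.allclose(out, 18.0)

    def test_identity_kernel_same_mode(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 6, 3))
        f = np.zeros((3, 3, 3))
        f[1, 1, 2] = 1.0  # delta at (u=0, v=0) on slice z=2
        assert np.allclose(cuboid_convolve(x, f, "same"), x[:, :, 2])

    def test_standard_input_valid_shape(self):
        out = cuboid_convolve(np.zeros((32, 32, 5)), np.zeros((3, 3, 5)), "valid")
        assert out.shape == (30, 30)

    def test_matches_literal_triple_sum(self):
        rng = np.random.default_rng(1)
        x, f = rng.normal(size=(5, 6, 3)), rng.normal(size=(3, 3, 3))
        want = np.zeros((3, 4))
        for h in range(3):
            for w in range(4):
                s = 0.0
                for z in range(3):
                    for u in range(3):
                        for v in range(3):
                            s += f[u, v, z] * x[h + u, w + v, z]
                want[h, w] = s
        assert np.allclose(cuboid_convolve(x, f, "valid"), want)

    def test_depth_mismatch_raises(self):
        with pytest.raises(ValueError):
            cuboid_convolve(np.ones((4, 4, 2)), np.ones((3, 3, 3)))


class TestConvLayer:
    def test_zero_input_zero_bias_gives_zero(self):
        out = conv_layer(np.zeros((5, 5, 2)), np.ones((3, 3, 2, 4)), np.zeros(4))
        assert out.shape == (3, 3, 4)
        assert not out.any()

    def test_relu_clamps_negative_preactivations(self):
        out = conv_layer(np.ones((5, 5, 1)), np.ones((3, 3, 1, 2)),
                         biases=np.array([-100.0, -100.0]))
        assert not out.any()

    def test_bias_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            conv_layer(np.ones((5, 5, 1)), np.ones((3, 3, 1, 2)), np.zeros(3))


class TestMaxPool:
    def test_standard_shape(self):
        assert max_pool(np.zeros((28, 28, 32)), 2, 2).shape == (14, 14, 32)

    def test_constant_input(self):
        assert np.allclose(max_pool(np.full((4, 4, 1), 3.5), 2, 2), 3.5)

    def test_single_one_lands_in_one_window(self):
        x = np.zeros((4, 4, 1))
        x[1, 2, 0] = 1.0
        out = max_pool(x, 2, 2)
        assert out.sum() == 1.0 and out[0, 1, 0] == 1.0

    def test_non_integral_dims_raise(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros((5, 5, 1)), 2, 2)


class TestDecide:
    def test_argmax(self):
        assert decide([0.1, 0.7, 0.2, 0.0, 0.0, 0.0]) == 1

    def test_uniform_tie_breaks_low(self):
        assert decide(np.full(6, 1 / 6)) == 0

    def test_one_hot(self):
        assert decide([0, 0, 0, 0, 1, 0]) == 4


class TestForward:
    def test_posteriors_form_a_simplex(self):
        spec = NetworkSpec.cinet(2)
        net = Network.initialize(spec, 0)
        x = np.random.default_rng(0).normal(size=(3, 32, 32, 3))
        probs = net.forward_batch(x)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weights_give_uniform_posteriors(self):
        spec = NetworkSpec.cinet(0)
        net = Network.initialize(spec, 0)
        for k in net.weights:
            net.weights[k] = np.zeros_like(net.weights[k])
        probs = net.forward_batch(np.ones((1, 32, 32, 1)))
        assert np.allclose(probs, 1 / 6)

    def test_input_shape_mismatch_raises(self):
        net = Network.initialize(NetworkSpec.cinet(0), 0)
        with pytest.raises(ValueError):
            net.forward_batch(np.ones((1, 32, 32, 3)))

    def test_matches_reference_on_random_triples(self):
        """Vectorised implementation vs literal-equation oracle, 1e-5."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            spec = NetworkSpec(
                input_shape=(8, 8, int(rng.integers(1, 4))),
                conv_layers=(ConvLayerSpec(int(rng.integers(2, 5)), 3, 3, "same"),
                             ConvLayerSpec(int(rng.integers(2, 5)), 3, 3, "valid")),
                pool=PoolSpec(2, 2),
                fcn_widths=(int(rng.integers(4, 9)), 6),
            )
            net = Network.initialize(spec, trial, dtype=np.float64)
            for k in net.weights:
                net.weights[k] = rng.normal(0, 0.5, net.weights[k].shape)
            x = rng.normal(size=spec.input_shape)
            fast = net.forward_batch(x[None])[0]
            ref = reference_forward(net, x)
            assert np.abs(fast - ref).max() <= 1e-5


class TestSpec:
    def test_dimension_chain_cinet4(self):
        spec = NetworkSpec.cinet(4)
        assert spec.layer_shapes() == [(32, 32, 5), (30, 30, 32),
                                       (28, 28, 32), (14, 14, 32)]
        assert spec.flat_dim == 6272
        assert spec.fcn_widths == (100, 6)

    def test_invalid_pool_dims_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_shape=(7, 7, 1),
                        conv_layers=(ConvLayerSpec(2, 3, 3, "same"),),
                        pool=PoolSpec(2, 2), fcn_widths=(4, 2))

    def test_weight_shape_validation(self):
        spec = NetworkSpec.cinet(0)
        net = Network.initialize(spec, 0)
        bad = dict(net.weights)
        bad["conv0_w"] = bad["conv0_w"][:, :, :, :8]
        with pytest.raises(ValueError):
            Network(spec, bad)


def _tiny_problem(seed=0):
    """A 2-class toy task that trains in well under a second."""
    spec = NetworkSpec(input_shape=(8, 8, 1),
                       conv_layers=(ConvLayerSpec(4, 3, 3, "valid"),),
                       pool=PoolSpec(2, 2), fcn_widths=(8, 2))
    rng = np.random.default_rng(99)
    protos = rng.integers(0, 2, size=(2, 8, 8, 1)).astype(np.float64)
    x = np.concatenate([protos[y][None] + rng.normal(0, 0.03, (8, 8, 1))
                        for y in (0, 1) for _ in range(10)])
    y = np.repeat([0, 1], 10)
    return spec, x, y


class TestTraining:
    def test_reaches_loss_threshold_and_perfect_accuracy(self):
        spec, x, y = _tiny_problem()
        res = train(spec, x, y, TrainConfig(samples_per_class=10, seed=1))
        assert res.converged
        assert res.final_loss < 0.001
        assert res.train_accuracy == 1.0

    def test_seeded_determinism(self):
        spec, x, y = _tiny_problem()
        cfg = TrainConfig(samples_per_class=10, seed=5, max_epochs=15)
        r1 = train(spec, x, y, cfg)
        r2 = train(spec, x, y, cfg)
        for k in r1.network.weights:
            assert np.array_equal(r1.network.weights[k], r2.network.weights[k])
        assert r1.loss_history == r2.loss_history

    def test_divergence_names_the_learning_rate(self):
        spec, x, y = _tiny_problem()
        with pytest.raises(TrainingDivergedError, match="learning_rate"):
            train(spec, x, y, TrainConfig(samples_per_class=10, seed=1,
                                          learning_rate=1e25, max_epochs=5))

    def test_label_range_validated(self):
        spec, x, y = _tiny_problem()
        with pytest.raises(ValueError):
            train(spec, x, y + 5, TrainConfig(samples_per_class=10))


class TestPersistence:
    def test_hdf5_roundtrip(self, tmp_path):
        net = Network.initialize(NetworkSpec.cinet(2), 3)
        path = tmp_path / "net.h5"
        net.save(path)
        loaded = Network.load(path)
        assert loaded.spec == net.spec
        x = np.random.default_rng(0).normal(size=(2, 32, 32, 3))
        assert np.allclose(net.forward_batch(x), loaded.forward_batch(x), atol=1e-6)
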