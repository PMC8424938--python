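import numpy as np
import pytest

from pocketgrid.model import (
    DEFAULT_SCHEDULE,
    BlockSpec,
    FilterSchedule,
    TrainConfig,
    block_census,
    build_block,
    build_puresnet,
    count_parameters,
    dice_loss,
    dice_loss_grad,
    group_kfold,
    predict,
    reduced_schedule,
    train_scaled,
)
from pocketgrid.nn import Conv3D, BatchNorm, Input, Network


def _standalone_block(kind, cin, filters, stride=1, shortcut=True):
    net = Network()
    x = net.add(Input(), [])
    rng = np.random.default_rng(0)
    build_block(net, x, cin, BlockSpec(kind, filters, stride), rng,
                prefix="blk", shortcut=shortcut)
    return net


class TestBlocks:
    def test_convolution_block_has_12_layers(self):
        net = _standalone_block("convolution", 8, (4, 8), stride=2)
        assert len(net.layers) - 1 == 12  # minus the input node

    def test_identity_block_has_10_layers(self):
        net = _standalone_block("identity", 8, (4, 8))
        assert len(net.layers) - 1 == 10

    def test_upsampling_block_has_14_layers(self):
        net = _standalone_block("upsampling", 8, (4, 8), stride=2)
        assert len(net.layers) - 1 == 14

    def test_identity_block_preserves_shape(self, rng):
        net = _standalone_block("identity", 6, (3, 6))
        x = rng.random((9, 9, 9, 6))
        assert net.forward(x).shape == x.shape

    def test_convolution_block_stride_halves_spatial_side(self, rng):
        net = _standalone_block("convolution", 18, (4, 8), stride=2)
        out = net.forward(rng.random((36, 36, 36, 18)))
        assert out.shape == (18, 18, 18, 8)

    def test_upsampling_block_scales_spatial_side(self, rng):
        net = _standalone_block("upsampling", 4, (2, 4), stride=3)
        out = net.forward(rng.random((3, 3, 3, 4)))
        assert out.shape == (9, 9, 9, 4)

    def test_zero_residual_identity_block_is_identity(self, rng):
        """With the main path silenced the additive shortcut passes the
        (non-negative) input straight through."""
        net = _standalone_block("identity", 5, (3, 5))
        for layer in net.layers:
            if isinstance(layer, Conv3D):
                layer.params["kernel"] *= 0.0
                layer.params["bias"] *= 0.0
        x = rng.random((6, 6, 6, 5))  # non-negative, as after an upstream ReLU
        assert np.allclose(net.forward(x), x)

    def test_identity_block_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _standalone_block("identity", 8, (4, 6))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec("pooling", (4, 8))


class TestArchitecture:
    def test_block_census_is_5_13_4_for_any_schedule(self):
        for sched in (DEFAULT_SCHEDULE, reduced_schedule(2), reduced_schedule(3)):
            net = build_puresnet(sched)
            assert block_census(net) == (5, 13, 4)

    def test_total_layer_count_252(self):
        net = build_puresnet(reduced_schedule(2))
        assert count_parameters(net)[2] == 252

    def test_output_shape_and_range(self, rng):
        net = build_puresnet(reduced_schedule(2), seed=0)
        out = net.forward(rng.random((36, 36, 36, 18)))
        assert out.shape == (36, 36, 36, 1)
        assert np.all((out > 0) & (out < 1))

    def test_forward_deterministic_for_fixed_seed(self):
        x = np.zeros((36, 36, 36, 18))
        a = build_puresnet(reduced_schedule(2), seed=9).forward(x)
        b = build_puresnet(reduced_schedule(2), seed=9).forward(x)
        assert np.array_equal(a, b)

    def test_schedule_length_validated(self):
        with pytest.raises(ValueError):
            FilterSchedule(encoder=((2, 2),) * 4, decoder=((2, 2),) * 4)


class TestParameterCounting:
    def test_single_conv_closed_form(self):
        net = Network()
        i0 = net.add(Input(), [])
        net.add(Conv3D(18, 32, kernel=3, rng=np.random.default_rng(0)), [i0])
        trainable, non_trainable, layers = net.count_parameters()
        assert trainable == 3 * 3 * 3 * 18 * 32 + 32 == 15_584
        assert non_trainable == 0 and layers == 2

    def test_batchnorm_closed_form(self):
        net = Network()
        i0 = net.add(Input(), [])
        net.add(BatchNorm(32), [i0])
        trainable, non_trainable, _ = net.count_parameters()
        assert trainable == 64 and non_trainable == 64

    def test_default_build_reproduces_reference_totals(self):
        net = build_puresnet(DEFAULT_SCHEDULE)
        trainable, non_trainable, layers = count_parameters(net)
        assert trainable == 13_840_903
        assert non_trainable == 16_992
        assert layers == 252


class TestDiceLoss:
    def test_perfect_overlap_within_smooth_tolerance(self):
        mask = np.zeros((6, 6, 6))
        mask[2:4, 2:4, 2:4] = 1.0
        loss = dice_loss(mask, mask)
        assert 0 <= loss <= 1.0 / (2 * mask.sum())

    def test_disjoint_closed_form(self):
        pred = np.zeros((10, 10, 10))
        mask = np.zeros((10, 10, 10))
        pred[0, 0, :] = 0.0
        pred[:1, :10, :10] = 1.0  # 100 voxels
        mask[5:6, :10, :10] = 1.0  # disjoint 100 voxels
        assert dice_loss(pred, mask) == pytest.approx(1 - 1 / 201)

    def test_half_coverage_closed_form(self):
        k = 1000
        pred = np.zeros((20, 10, 10))
        mask = np.zeros((20, 10, 10))
        mask[:20, :10, :10] = 1.0  # 2k voxels
        pred[:10, :10, :10] = 1.0  # exactly half of the mask
        assert dice_loss(pred, mask) == pytest.approx(1 - (2 * k + 1) / (3 * k + 1))

    def test_monotone_in_overlap_at_fixed_sizes(self):
        mask = np.zeros((10, 10, 10))
        mask[0, 0, :8] = 1.0
        losses = []
        for overlap in range(1, 9):
            pred = np.zeros((10, 10, 10))
            pred[0, 0, :overlap] = 1.0
            pred[1, 1, : 8 - overlap] = 1.0  # keep |pred| fixed at 8
            losses.append(dice_loss(pred, mask))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 4, 4)), np.zeros((5, 5, 5)))

    def test_gradient_matches_numerics(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(5, 5, 5))
        mask = (rng.random((5, 5, 5)) < 0.2).astype(float)
        g = dice_loss_grad(pred, mask)
        for _ in range(5):
            idx = tuple(int(rng.integers(0, 5)) for _ in range(3))
            eps = 1e-6
            old = pred[idx]
            pred[idx] = old + eps
            up = dice_loss(pred, mask)
            pred[idx] = old - eps
            down = dice_loss(pred, mask)
            pred[idx] = old
            assert g[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4)


def _tiny_dataset(rng):
    x = rng.random((9, 9, 9, 18))
    m = np.zeros((9, 9, 9))
    m[3:5, 3:5, 3:5] = 1.0
    return [(x, m)]


def _tiny_net(seed=0):
    """A 9^3 variant so the training-contract tests stay fast."""
    net = Network()
    rng = np.random.default_rng(seed)
    i0 = net.add(Input(), [])
    i1 = net.add(Conv3D(18, 4, kernel=3, rng=rng), [i0])
    i2 = net.add(BatchNorm(4), [i1])
    from pocketgrid.nn import Activation

    i3 = net.add(Activation("relu"), [i2])
    net.add(Conv3D(4, 1, kernel=1, activation="sigmoid", rng=rng), [i3])
    return net


class TestTraining:
    def test_zero_learning_rate_constant_trace(self, rng):
        data = _tiny_dataset(rng)
        net = _tiny_net()
        cfg = TrainConfig(learning_rate=1e-30, l2=0.0, batch_size=1,
                          seed=0, steps=5)
        trace = train_scaled(net, data, cfg)
        assert np.allclose(trace, trace[0], atol=1e-9)

    def test_same_seed_identical_traces(self, rng):
        data = _tiny_dataset(rng)
        cfg = TrainConfig(learning_rate=1e-3, batch_size=1, seed=4, steps=8)
        t1 = train_scaled(_tiny_net(1), data, cfg)
        t2 = train_scaled(_tiny_net(1), data, cfg)
        assert t1 == t2

    def test_loss_decreases_on_tiny_problem(self, rng):
        data = _tiny_dataset(rng)
        cfg = TrainConfig(learning_rate=3e-3, batch_size=1, seed=0, steps=60)
        trace = train_scaled(_tiny_net(2), data, cfg)
        assert trace[-1] < trace[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_scaled(_tiny_net(), [], TrainConfig())

    def test_bce_loss_option_trains(self, rng):
        data = _tiny_dataset(rng)
        cfg = TrainConfig(learning_rate=3e-3, batch_size=1, seed=0,
                          steps=30, loss="bce")
        trace = train_scaled(_tiny_net(3), data, cfg)
        assert trace[-1] < trace[0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            TrainConfig(loss="hinge")


class TestPredict:
    def test_probabilities_strictly_inside_unit_interval(self, rng):
        net = build_puresnet(reduced_schedule(2), seed=1)
        out = predict(net, rng.random((36, 36, 36, 18)))
        assert out.shape == (36, 36, 36)
        assert np.all((out > 0) & (out < 1))

    def test_reproducible_for_fixed_weights(self):
        net = build_puresnet(reduced_schedule(2), seed=5)
        x = np.zeros((36, 36, 36, 18))
        assert np.array_equal(predict(net, x), predict(net, x))


class TestGroupKFold:
    def test_families_never_split_across_folds(self, rng):
        families = [f"fam{i}" for i in rng.integers(0, 12, size=60)]
        folds = group_kfold(families, k=4)
        assert set(folds) == {0, 1, 2, 3}
        for fam in set(families):
            fam_folds = {f for f, g in zip(folds, families) if g == fam}
            assert len(fam_folds) == 1

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            group_kfold(["a", "b"], k=1)


class TestSerialization:
    def test_weight_file_round_trip(self, tmp_path, rng):
        from pocketgrid.serialize import load_weights, save_weights

        net = build_puresnet(reduced_schedule(2), seed=3)
        x = rng.random((36, 36, 36, 18))
        ref = predict(net, x)
        path = tmp_path / "w.h5"
        save_weights(net, path, schedule=reduced_schedule(2), seed=3)
        restored = load_weights(path)
        assert np.allclose(predict(restored, x), ref)
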