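"""Chebyshev convolution, architecture, training regime and inference."""

import numpy as np
import pytest

import structage as sa
from structage.gcnn import (
    AgeNetwork,
    AgeNetworkConfig,
    ChebConv,
    InferenceConfig,
    LeakageError,
    LrStopSchedule,
    ScanDataset,
    TrainingConfig,
    _l2_penalty,
    cheb_conv,
    evaluate_predictions,
    predict_ensemble_tta,
    random_rotation,
    train,
)

from conftest import random_triangulation_graph

SMALL_CFG = AgeNetworkConfig(
    conv_filters=8,
    last_conv_filters=12,
    dense_units=6,
    n_residual_blocks=2,
    K_first=3,
    K_block=2,
    dropout_softmax_branch=0.0,
    l2_lambda=0.0,
)


def dense_cheb_oracle(L_dense, x, theta, bias):
    """Explicit Chebyshev polynomials of the dense matrix."""
    K = theta.shape[0]
    n = L_dense.shape[0]
    Ts = [np.eye(n)]
    if K > 1:
        Ts.append(L_dense)
    for _ in range(2, K):
        Ts.append(2 * L_dense @ Ts[-1] - Ts[-2])
    y = sum(Ts[k] @ x @ theta[k] for k in range(K))
    return y + bias


class TestChebConv:
    def test_k1_identity_filter_passes_input(self, rng):
        g = random_triangulation_graph(16, rng)
        lap = sa.scaled_laplacian(g)
        x = rng.normal(size=(16, 3))
        theta = np.eye(3)[None]  # K=1, theta_0 = I
        np.testing.assert_allclose(cheb_conv(lap, x, theta), x, atol=1e-12)

    def test_zero_input_yields_bias(self, rng):
        g = random_triangulation_graph(16, rng)
        lap = sa.scaled_laplacian(g)
        bias = np.array([1.5, -2.0])
        y = cheb_conv(lap, np.zeros((16, 3)), np.zeros((4, 3, 2)), bias)
        np.testing.assert_allclose(y, np.tile(bias, (16, 1)), atol=1e-14)

    def test_recursion_matches_dense_oracle(self, rng):
        g = random_triangulation_graph(8, rng)
        lap = sa.scaled_laplacian(g)
        theta = rng.normal(size=(4, 3, 5))
        bias = rng.normal(size=5)
        x = rng.normal(size=(8, 3))
        y = cheb_conv(lap, x, theta, bias)
        yo = dense_cheb_oracle(lap.matrix.toarray(), x, theta, bias)
        np.testing.assert_allclose(y, yo, atol=1e-8)

    def test_k2_locality(self, rng):
        """A K=2 filter reaches one hop: perturbing node v changes outputs
        only at v and its graph neighbors."""
        g = random_triangulation_graph(20, rng)
        lap = sa.scaled_laplacian(g)
        theta = rng.normal(size=(2, 1, 1))
        x = rng.normal(size=(20, 1))
        y0 = cheb_conv(lap, x, theta)
        v = 7
        x2 = x.copy()
        x2[v] += 1.0
        changed = np.where(np.abs(cheb_conv(lap, x2, theta) - y0)[:, 0] > 1e-12)[0]
        neighbors = {v}
        for a, b in g.edges:
            if a == v:
                neighbors.add(b)
            if b == v:
                neighbors.add(a)
        assert set(changed) <= neighbors

    def test_backward_matches_numerical_gradient(self, rng):
        g = random_triangulation_graph(10, rng)
        lap = sa.scaled_laplacian(g)
        layer = ChebConv(lap.matrix, 4, 2, 3, rng)
        x = rng.normal(size=(2, 10, 2))
        w = rng.normal(size=(2, 10, 3))  # arbitrary loss weights

        def loss(xv):
            return float((layer.forward(xv) * w).sum())

        layer.forward(x)
        dx = layer.backward(w)
        eps = 1e-6
        for idx in [(0, 3, 1), (1, 9, 0), (0, 0, 0)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (loss(xp) - loss(xm)) / (2 * eps)
            assert num == pytest.approx(dx[idx], abs=1e-5)


class TestRotation:
    def test_zero_angle_is_identity(self, rng):
        x = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(random_rotation(x, 0.0, rng), x)

    def test_norms_preserved(self, rng):
        x = rng.normal(size=(10, 6))
        y = random_rotation(x, 15.0, rng)
        for c in (0, 3):
            np.testing.assert_allclose(
                np.linalg.norm(y[:, c : c + 3], axis=1),
                np.linalg.norm(x[:, c : c + 3], axis=1),
                atol=1e-10,
            )

    def test_pairwise_distances_preserved(self, rng):
        x = rng.normal(size=(12, 3))
        y = random_rotation(x, 15.0, rng)
        dx = np.linalg.norm(x[:, None] - x[None], axis=-1)
        dy = np.linalg.norm(y[:, None] - y[None], axis=-1)
        np.testing.assert_allclose(dx, dy, atol=1e-9)

    def test_matches_explicit_matrix_product(self, rng):
        from scipy.spatial.transform import Rotation

        x = rng.normal(size=(10, 3))
        rot_rng = np.random.default_rng(5)
        y = random_rotation(x, 15.0, rot_rng)
        oracle_rng = np.random.default_rng(5)
        angles = oracle_rng.uniform(-15, 15, size=3)
        R = Rotation.from_euler("ZYX", angles, degrees=True).as_matrix()
        np.testing.assert_allclose(y, (R @ x.T).T, atol=1e-12)

    def test_non_triple_layout_rejected(self, rng):
        with pytest.raises(ValueError, match="triple"):
            random_rotation(np.zeros((5, 4)), 15.0, rng)


class TestArchitecture:
    def test_parameter_count_closed_form(self, accumbens_hierarchy):
        cfg = SMALL_CFG
        net = AgeNetwork(accumbens_hierarchy, 3, cfg, seed=0)
        C, CL, U = cfg.conv_filters, cfg.last_conv_filters, cfg.dense_units
        expected = (
            cfg.K_first * 3 * C + C  # first conv
            + cfg.n_residual_blocks * (2 * (cfg.K_block * C * C + C) + 2 * (2 * C))
            + 2 * C  # final batch norm
            + cfg.K_block * C * CL + CL  # last conv
            + 2 * (CL * U + U)  # both head dense layers
            + U * 1 + 1  # output combination
        )
        assert net.n_parameters == expected

    def test_zero_weights_forward_gives_output_bias(self, accumbens_hierarchy, rng):
        net = AgeNetwork(accumbens_hierarchy, 3, SMALL_CFG, seed=0)
        for layer, key, _ in net.parameters():
            layer.params[key][:] = 0.0
        net.dense_out.params["b"][:] = 3.25
        x = rng.normal(size=(2, 256, 3))
        np.testing.assert_allclose(net.predict(x), [3.25, 3.25], atol=1e-12)

    def test_one_hot_probability_selects_bin_age(self, accumbens_hierarchy, rng):
        """If the Softmax branch is (numerically) one-hot on bin b and the
        output layer is (weight 1, bias 0), the prediction is branch A's
        value for bin b."""
        net = AgeNetwork(accumbens_hierarchy, 3, SMALL_CFG, seed=0)
        b = 2
        net.dense_probs.params["w"][:] = 0.0
        net.dense_probs.params["b"][:] = -1e4
        net.dense_probs.params["b"][b] = 1e4  # softmax -> one-hot on bin b
        net.dense_out.params["w"][:] = 1.0
        net.dense_out.params["b"][:] = 0.0
        x = rng.normal(size=(1, 256, 3))
        # recompute branch A's bin-b value at the same activations
        pred = net.predict(x)
        bins, probs = net._head_cache
        assert probs[0, b] == pytest.approx(1.0)
        assert pred[0] == pytest.approx(bins[0, b], abs=1e-10)

    def test_shallow_hierarchy_rejected(self, accumbens_graph):
        shallow = sa.binary_partition(accumbens_graph, 1)
        with pytest.raises(ValueError, match="pools"):
            AgeNetwork(shallow, 3, SMALL_CFG, seed=0)

    def test_checkpoint_roundtrip(self, accumbens_hierarchy, tmp_path, rng):
        net = AgeNetwork(accumbens_hierarchy, 3, SMALL_CFG, seed=3)
        x = rng.normal(size=(2, 256, 3))
        ref = net.predict(x)
        path = tmp_path / "net.pkl"
        net.save(path)
        loaded = AgeNetwork.load(path, accumbens_hierarchy)
        np.testing.assert_allclose(loaded.predict(x), ref, atol=1e-12)


class TestTrainingRegime:
    def test_schedule_one_drop_then_stop(self):
        """A 16-long non-improving tail triggers exactly one LR drop; a
        31-long tail triggers the stop."""
        sched = LrStopSchedule(lr_patience=15, stop_patience=30)
        drops, stops = 0, 0
        sched.update(1.0)  # first epoch improves from +inf
        for _ in range(15):
            _, drop, stop = sched.update(1.0)
            drops += drop
            stops += stop
        assert (drops, stops) == (1, 0)
        for _ in range(15):
            _, drop, stop = sched.update(1.0)
            drops += drop
            stops += stop
        assert drops == 1
        assert stops == 1

    def test_l2_regularizer_is_near_vanishing(self, accumbens_hierarchy):
        import dataclasses

        cfg = dataclasses.replace(SMALL_CFG, l2_lambda=1e-12)
        net = AgeNetwork(accumbens_hierarchy, 3, cfg, seed=0)
        assert 0 < _l2_penalty(net) < 1e-6

    def test_subject_overlap_rejected(self, accumbens_hierarchy, rng):
        net = AgeNetwork(accumbens_hierarchy, 3, SMALL_CFG, seed=0)
        x = rng.normal(size=(4, 256, 3))
        a = ScanDataset(x[:2], np.array([60.0, 70.0]), ["s1", "s2"])
        b = ScanDataset(x[2:], np.array([65.0, 75.0]), ["s2", "s3"])
        with pytest.raises(LeakageError):
            train(net, a, b, TrainingConfig(max_epochs=1))

    def test_training_is_deterministic_given_seed(self, accumbens_hierarchy, rng):
        x = rng.normal(size=(24, 256, 3)) * 0.1
        ages = rng.uniform(50, 90, 24)
        tr = ScanDataset(x[:16], ages[:16], [f"a{i}" for i in range(16)])
        va = ScanDataset(x[16:], ages[16:], [f"b{i}" for i in range(8)])
        cfg = TrainingConfig(max_epochs=3, batch_size=8, seed=7)
        histories = []
        for _ in range(2):
            net = AgeNetwork(accumbens_hierarchy, 3, SMALL_CFG, seed=1)
            histories.append(train(net, tr, va, cfg))
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_mae"] == histories[1]["val_mae"]


class _ConstantNet:
    """Stand-in regressor with a fixed output (for aggregation tests)."""

    structure_config = "accumbens"

    def __init__(self, value):
        self.value = value

    def predict(self, x):
        return np.full(x.shape[0], self.value)


class TestInference:
    def test_ensemble_times_tta_estimate_count(self):
        nets = [_ConstantNet(70.0)] * 20
        pred = predict_ensemble_tta(
            nets, np.zeros((8, 3)), InferenceConfig(ensemble_size=20, test_tta=20)
        )
        assert pred.n_estimates == 400

    def test_single_net_no_augmentation_is_plain_forward(self, accumbens_hierarchy, rng):
        net = AgeNetwork(accumbens_hierarchy, 3, SMALL_CFG, seed=0)
        x = rng.normal(size=(256, 3))
        pred = predict_ensemble_tta(
            [net], x, InferenceConfig(ensemble_size=1, test_tta=1, rotation_deg=0.0)
        )
        assert pred.aggregated == pytest.approx(float(net.predict(x[None])[0]))

    def test_constant_ensembles_average(self):
        nets = [_ConstantNet(70.0)] * 10 + [_ConstantNet(74.0)] * 10
        pred = predict_ensemble_tta(
            nets, np.zeros((8, 3)), InferenceConfig(ensemble_size=20, test_tta=1)
        )
        assert pred.aggregated == pytest.approx(72.0)

    def test_mixed_structure_configs_rejected(self):
        a, b = _ConstantNet(70.0), _ConstantNet(70.0)
        b.structure_config = "cortex"
        with pytest.raises(ValueError, match="mixed"):
            predict_ensemble_tta([a, b], np.zeros((8, 3)))


class TestEvaluation:
    def test_perfect_predictions(self):
        m = evaluate_predictions([60.0, 70, 80], [60.0, 70, 80])
        assert m == {"MAE": 0.0, "median_AE": 0.0, "pearson_r": pytest.approx(1.0)}

    def test_constant_offset(self):
        m = evaluate_predictions([62.0, 72, 82], [60.0, 70, 80])
        assert m["MAE"] == pytest.approx(2.0)
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_hand_listed_pairs_match_direct_formulas(self):
        pred = np.array([61.0, 75.0, 68.0, 82.0, 59.0])
        true = np.array([60.0, 70.0, 70.0, 80.0, 65.0])
        m = evaluate_predictions(pred, true)
        err = np.abs(pred - true)
        assert m["MAE"] == pytest.approx(err.mean())
        assert m["median_AE"] == pytest.approx(np.median(err))
        r = np.corrcoef(pred, true)[0, 1]  # independent formula
        assert m["pearson_r"] == pytest.approx(r, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([1.0, 2.0], [1.0])
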