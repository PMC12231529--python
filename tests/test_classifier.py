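"""BiLSTM-GRU network: architecture, loss, training machinery, inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tremorstage import classifier as clf


def _tiny_cfg(**kw):
    base = dict(n_features=3, n_classes=5, bilstm_hidden=6, gru_hidden=6,
                dropout=0.0, l2_lambda=0.0, batch_size=8, max_epochs=5,
                seed=11)
    base.update(kw)
    return clf.NetworkConfig(**base)


class TestBuildNetwork:
    def test_parameter_count_matches_gate_counting_oracle(self):
        # oracle computed from the gate structure: per LSTM direction
        # 4H(N+H+1); GRU (single bias) 3G(2H+G+1); dense C(G+1)
        cfg = clf.NetworkConfig(n_features=19)
        model = clf.build_network(cfg)
        n, h, g, c = 19, 50, 50, 5
        expected = 2 * (4 * h * (n + h + 1)) + 3 * g * (2 * h + g + 1) \
            + c * (g + 1)
        assert expected == 50905
        assert model.parameter_count() == expected

    def test_seeded_init_reproducible(self):
        a = clf.build_network(clf.NetworkConfig(n_features=5, seed=3))
        b = clf.build_network(clf.NetworkConfig(n_features=5, seed=3))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_forward_on_zero_input_valid_distribution(self):
        model = clf.build_network(_tiny_cfg())
        _, probs = clf.predict(model, np.zeros((2, 3, 20), dtype=np.float32))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            clf.build_network(clf.NetworkConfig(n_features=0))
        with pytest.raises(ValueError):
            clf.build_network(clf.NetworkConfig(n_features=3, dropout=1.0))


class TestSoftmax:
    def test_uniform_cases(self):
        np.testing.assert_allclose(clf.softmax(np.zeros(5)), 0.2)
        np.testing.assert_allclose(clf.softmax(np.ones(5)), 0.2)

    def test_two_class_closed_form(self):
        out = clf.softmax(np.array([np.log(2.0), 0.0]))
        np.testing.assert_allclose(out, [2 / 3, 1 / 3])

    @settings(deadline=None, max_examples=1000, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.floats(-100, 100))
    def test_shift_invariance_and_simplex(self, x, shift):
        x = np.array(x)
        p = clf.softmax(x)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(clf.softmax(x + shift), p, atol=1e-9)

    def test_overflow_safe(self):
        p = clf.softmax(np.array([1000.0, 1000.0]))
        np.testing.assert_allclose(p, 0.5)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(5)[[0, 3]]
        assert clf.weighted_cross_entropy(probs, np.array([0, 3])) == 0.0

    def test_uniform_prediction_ln5(self):
        probs = np.full((4, 5), 0.2)
        loss = clf.weighted_cross_entropy(probs, np.array([0, 1, 2, 3]))
        assert loss == pytest.approx(np.log(5.0), abs=1e-9)

    def test_direct_evaluation_example(self):
        probs = np.array([[0.5, 0.5], [0.25, 0.75]])
        loss = clf.weighted_cross_entropy(probs, np.array([0, 0]))
        assert loss == pytest.approx((np.log(2) + np.log(4)) / 2, abs=1e-9)

    def test_matches_nll_oracle_on_random_batches(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            probs = clf.softmax(rng.normal(size=(16, 5)), axis=1)
            y = rng.integers(0, 5, 16)
            w = rng.uniform(0.5, 2.0, 5)
            direct = -np.mean([w[y[i]] * np.log(probs[i, y[i]])
                               for i in range(16)])
            assert clf.weighted_cross_entropy(probs, y, w) == pytest.approx(
                direct, abs=1e-9)

    def test_one_hot_targets_accepted(self):
        probs = np.array([[0.7, 0.3]])
        onehot = np.array([[1.0, 0.0]])
        assert clf.weighted_cross_entropy(probs, onehot) == pytest.approx(
            -np.log(0.7))

    def test_zero_probability_clamped(self):
        probs = np.array([[0.0, 1.0]])
        loss = clf.weighted_cross_entropy(probs, np.array([0]))
        assert np.isfinite(loss)


def _separable_data(n_per_class=16, T=40, n_features=3, seed=0):
    """Five classes distinguished by channel mean level."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label in range(1, 6):
        base = (label - 3) * 1.0
        X.append(base + 0.3 * rng.standard_normal((n_per_class, n_features, T)))
        y += [label] * n_per_class
    return np.concatenate(X).astype(np.float32), np.array(y)


class TestTraining:
    def test_loss_descends_on_separable_data(self):
        X, y = _separable_data()
        cfg = _tiny_cfg(max_epochs=8, dropout=0.2)
        model = clf.build_network(cfg)
        clf.train(model, X, y, cfg)
        iters_per_epoch = len(y) // cfg.batch_size
        assert len(model.history) == cfg.iterations_per_run(len(y))
        first = np.mean(model.history[:iters_per_epoch])
        last = np.mean(model.history[-iters_per_epoch:])
        assert last < first

    def test_zero_learning_rate_freezes_parameters(self):
        X, y = _separable_data(n_per_class=4)
        cfg = _tiny_cfg(lr0=0.0, max_epochs=2)
        model = clf.build_network(cfg)
        before = {k: v.copy() for k, v in model.params.items()}
        clf.train(model, X, y, cfg)
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_overfits_single_batch(self):
        # one mini-batch of identical samples driven for 200 steps must be
        # memorized almost exactly
        rng = np.random.default_rng(7)
        x0 = rng.standard_normal((1, 3, 30)).astype(np.float32)
        X = np.repeat(x0, 8, axis=0)
        y = np.full(8, 4)
        cfg = _tiny_cfg(max_epochs=200, lr_drop_period=1000, lr0=5e-3)
        model = clf.build_network(cfg)
        clf.train(model, X, y, cfg)
        assert model.history[-1] < 0.01
        pred, _ = clf.predict(model, X)
        assert np.all(pred == 4)

    def test_seeded_run_reproducible(self):
        X, y = _separable_data(n_per_class=8)
        runs = []
        for _ in range(2):
            cfg = _tiny_cfg(max_epochs=2, dropout=0.5)
            model = clf.build_network(cfg)
            clf.train(model, X, y, cfg)
            runs.append(model)
        assert runs[0].history == runs[1].history
        for k in runs[0].params:
            np.testing.assert_array_equal(runs[0].params[k],
                                          runs[1].params[k])

    def test_channel_mismatch_rejected(self):
        X, y = _separable_data(n_per_class=4, n_features=2)
        cfg = _tiny_cfg()   # expects 3 features
        model = clf.build_network(cfg)
        with pytest.raises(ValueError):
            clf.train(model, X, y, cfg)

    def test_gradient_clipping_bounds_update_norm(self):
        grads = {"a": np.full((10, 10), 5.0), "b": np.full(10, -5.0)}
        clf._clip_global_norm(grads, 1.0)
        total = np.sqrt(sum(np.sum(g**2) for g in grads.values()))
        assert total == pytest.approx(1.0, rel=1e-6)


class TestPredict:
    def test_labels_in_range_and_deterministic(self):
        model = clf.build_network(_tiny_cfg(dropout=0.5))
        X = np.random.default_rng(0).standard_normal((6, 3, 25)) \
            .astype(np.float32)
        l1, p1 = clf.predict(model, X)
        l2, p2 = clf.predict(model, X)
        assert set(l1) <= {1, 2, 3, 4, 5}
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)   # dropout disabled at inference
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        model = clf.build_network(_tiny_cfg())
        with pytest.raises(ValueError):
            clf.predict(model, np.zeros((2, 4, 25), dtype=np.float32))


def test_checkpoint_round_trip(tmp_path):
    X, y = _separable_data(n_per_class=4)
    cfg = _tiny_cfg(max_epochs=1)
    model = clf.build_network(cfg, channel_names=["a", "b", "c"])
    clf.train(model, X, y, cfg)
    clf.save_model(model, tmp_path / "model")
    back = clf.load_model(tmp_path / "model")
    assert back.config == model.config
    assert back.channel_names == ["a", "b", "c"]
    assert back.history == model.history
    for k in model.params:
        np.testing.assert_array_equal(back.params[k], model.params[k])
    la, _ = clf.predict(model, X)
    lb, _ = clf.predict(back, X)
    np.testing.assert_array_equal(la, lb)
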