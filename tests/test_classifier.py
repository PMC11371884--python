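import numpy as np
import pytest

from condyseat import (
    FeedForwardClassifier,
    NetworkSpec,
    PredictionConfig,
    TrainingConfig,
    class_weights,
    cyclic_lr,
)


class TestCyclicLR:
    CFG_TRI = TrainingConfig(lr_policy="triangular")
    CFG_TRI2 = TrainingConfig(lr_policy="triangular2")

    def test_starts_at_base_rate(self):
        assert cyclic_lr(0, self.CFG_TRI) == pytest.approx(5e-5)
        assert cyclic_lr(0, self.CFG_TRI2) == pytest.approx(5e-5)

    def test_first_peak_reaches_max_rate(self):
        assert cyclic_lr(2000, self.CFG_TRI) == pytest.approx(5e-4)

    def test_triangular2_second_peak_half_amplitude(self):
        assert cyclic_lr(6000, self.CFG_TRI2) == pytest.approx(2.75e-4)

    def test_triangular_wave_shape(self):
        # linear ramp: halfway up the first cycle sits midway between the rates
        assert cyclic_lr(1000, self.CFG_TRI) == pytest.approx((5e-5 + 5e-4) / 2)
        # full period returns to base under plain triangular
        assert cyclic_lr(4000, self.CFG_TRI) == pytest.approx(5e-5)


class TestClassWeights:
    def test_balanced_is_identity(self):
        assert class_weights([0] * 50 + [1] * 50) == (1.0, 1.0)

    def test_study_class_counts(self):
        w_neg, w_pos = class_weights([0] * 85 + [1] * 35)
        assert w_neg == pytest.approx(120 / 170)
        assert w_pos == pytest.approx(120 / 70)

    def test_extreme_imbalance(self):
        w_neg, w_pos = class_weights([0] * 99 + [1])
        assert w_pos / w_neg == pytest.approx(99.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            class_weights([1, 1, 1])


class TestNetworkSpec:
    def test_dense_parameter_count_closed_form(self):
        assert NetworkSpec(input_dim=3, hidden_sizes=(2,)).n_dense_parameters() == 11
        spec = NetworkSpec(input_dim=198, hidden_sizes=(192, 128, 64, 32))
        sizes = (198, 192, 128, 64, 32, 1)
        expected = sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
        assert spec.n_dense_parameters() == expected

    def test_default_config_echo(self):
        cfg = TrainingConfig()
        net = NetworkSpec()
        assert cfg.epochs == 1000
        assert cfg.batch_size == 32
        assert cfg.base_lr == 5e-5 and cfg.max_lr == 5e-4 and cfg.step_size == 2000
        assert net.hidden_sizes == (192, 128, 64, 32)
        assert net.dropout_rate == 0.25 and net.bn_momentum == 0.8

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(hidden_sizes=())
        with pytest.raises(ValueError):
            NetworkSpec(dropout_rate=1.0)
        with pytest.raises(ValueError):
            TrainingConfig(base_lr=1e-3, max_lr=1e-4)
        with pytest.raises(ValueError):
            PredictionConfig(cutoff=0.0)


def make_blobs(n=200, seed=0, dim=10):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(-2.0, 1.0, size=(n // 2, dim))
    X1 = rng.normal(2.0, 1.0, size=(n // 2, dim))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    return X, y


class TestTraining:
    def small_model(self, seed=0, dim=10):
        net = NetworkSpec(input_dim=dim, hidden_sizes=(16, 8))
        # cyclic half-period scaled to the problem: ~50 epochs x 7 batches
        cfg = TrainingConfig(rng_seed=seed, epochs=50, step_size=100)
        return FeedForwardClassifier(net, cfg)

    def test_learns_separable_blobs(self):
        X, y = make_blobs()
        model = self.small_model().fit(X, y)
        _, pred = model.predict(X, PredictionConfig(cutoff=0.5))
        assert (pred == y.astype(bool)).mean() >= 0.99

    def test_same_seed_identical_loss_trace(self):
        X, y = make_blobs()
        a = self.small_model(seed=3).fit(X, y)
        b = self.small_model(seed=3).fit(X, y)
        assert a.loss_trace == b.loss_trace
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_confidences_in_open_unit_interval(self):
        X, y = make_blobs()
        p = self.small_model().fit(X, y).predict_proba(X)
        assert np.all(p > 0) and np.all(p < 1)

    def test_cutoff_semantics_boundary_inclusive(self):
        confidences = np.array([0.19, 0.20, 0.21])
        pcfg = PredictionConfig(cutoff=0.2)
        labels = confidences >= pcfg.cutoff
        assert list(labels) == [False, True, True]

    def test_raising_cutoff_never_flips_correct_to_incorrect(self):
        X, y = make_blobs()
        model = self.small_model().fit(X, y)
        _, pred_low = model.predict(X, PredictionConfig(cutoff=0.2))
        _, pred_high = model.predict(X, PredictionConfig(cutoff=0.6))
        assert not np.any(pred_high & ~pred_low)

    def test_width_mismatch_raises(self):
        X, y = make_blobs()
        model = self.small_model().fit(X, y)
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(np.zeros((3, 7)))
        with pytest.raises(ValueError, match="width"):
            self.small_model().fit(np.zeros((10, 7)), np.r_[np.zeros(5), np.ones(5)])

    def test_single_class_training_rejected(self):
        model = self.small_model()
        with pytest.raises(ValueError, match="both classes"):
            model.fit(np.zeros((10, 10)), np.ones(10))

    def test_save_load_round_trip(self, tmp_path):
        X, y = make_blobs()
        model = self.small_model().fit(X, y)
        model.save(tmp_path / "model.npz")
        back = FeedForwardClassifier.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))


class TestBatchNormContract:
    def test_running_statistics_update_rule(self):
        # hand-fed two-batch sequence through a single hidden layer
        net = NetworkSpec(input_dim=2, hidden_sizes=(2,), dropout_rate=0.0, bn_momentum=0.8)
        model = FeedForwardClassifier(net, TrainingConfig(rng_seed=0))
        # identity dense layer so the BN input is the (ReLU of the) raw batch
        model.W[0] = np.eye(2)
        model.b[0] = np.zeros(2)
        batch1 = np.array([[1.0, 2.0], [3.0, 6.0]])
        batch2 = np.array([[5.0, 0.5], [7.0, 1.5]])
        model._forward(batch1, training=True)
        expected_mean = 0.8 * np.zeros(2) + 0.2 * batch1.mean(axis=0)
        expected_var = 0.8 * np.ones(2) + 0.2 * batch1.var(axis=0)
        np.testing.assert_allclose(model.running_mean[0], expected_mean)
        np.testing.assert_allclose(model.running_var[0], expected_var)
        model._forward(batch2, training=True)
        expected_mean = 0.8 * expected_mean + 0.2 * batch2.mean(axis=0)
        expected_var = 0.8 * expected_var + 0.2 * batch2.var(axis=0)
        np.testing.assert_allclose(model.running_mean[0], expected_mean)
        np.testing.assert_allclose(model.running_var[0], expected_var)

    def test_inference_uses_running_statistics(self):
        net = NetworkSpec(input_dim=2, hidden_sizes=(2,), dropout_rate=0.0)
        model = FeedForwardClassifier(net, TrainingConfig(rng_seed=0))
        X = np.array([[0.5, 1.0]])
        p1 = model.predict_proba(X)
        p2 = model.predict_proba(np.vstack([X, X * 100]))[0:1]
        np.testing.assert_allclose(p1, p2)  # no batch coupling at inference
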