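import math

import numpy as np
import pytest

import p300bci as p
from p300bci.errors import InvalidParameterError, LengthError
from p300bci.network import TrainingConfig, init_model


def forward_oracle(model, x):
    """Nested-loop evaluation of the network equations."""
    y = model.ob
    for i in range(model.m):
        n_i = model.b[i]
        for j in range(model.n):
            n_i += x[j] * model.w[i, j]
        h_i = 2.0 / (1.0 + math.exp(-2.0 * n_i)) - 1.0
        y += h_i * model.hw[i]
    return y


def separable_dataset(n_per_class=100, seed=0):
    """Bell-shaped target curves vs irregular low non-target curves."""
    rng = np.random.default_rng(seed)
    X, T = [], []
    idx = np.arange(31)
    for _ in range(n_per_class):
        centre = rng.uniform(12, 18)
        width = rng.uniform(3, 6)
        X.append(np.exp(-0.5 * ((idx - centre) / width) ** 2))
        T.append(1.0)
        X.append(rng.uniform(-0.4, 0.4, size=31))
        T.append(0.0)
    return np.array(X), np.array(T)


class TestForward:
    def test_zero_weights_output_is_bias(self, rng):
        model = p.NetworkModel(w=np.zeros((15, 31)), b=np.zeros(15),
                               hw=np.zeros(15), ob=0.7)
        assert p.forward(model, rng.normal(size=31)) == pytest.approx(0.7)

    def test_activation_limits(self):
        from p300bci.network import _tanh_sigmoid

        assert _tanh_sigmoid(np.array([0.0]))[0] == 0.0
        assert _tanh_sigmoid(np.array([50.0]))[0] == pytest.approx(1.0)
        assert _tanh_sigmoid(np.array([-50.0]))[0] == pytest.approx(-1.0)

    def test_matches_loop_oracle_on_many_random_pairs(self):
        rng = np.random.default_rng(0)
        for trial in range(1000):
            model = init_model(seed=trial)
            x = rng.normal(size=31)
            assert p.forward(model, x) == pytest.approx(forward_oracle(model, x), abs=1e-12)

    def test_parameter_count(self):
        assert init_model().n_parameters == 496

    def test_size_mismatch(self):
        with pytest.raises(LengthError):
            p.forward(init_model(), np.zeros(30))


class TestClassifyInterval:
    def test_printed_worked_example_flags(self):
        model = init_model(threshold=0.6)
        scores = [0.2910, 0.9473, 0.2493, 0.0233]
        flags = [s > model.threshold for s in scores]
        assert flags == [False, True, False, False]

    def test_strict_inequality_at_threshold(self):
        model = p.NetworkModel(w=np.zeros((15, 31)), b=np.zeros(15),
                               hw=np.zeros(15), ob=0.6, threshold=0.6)
        score, is_target = p.classify_interval(model, np.zeros(31))
        assert score == pytest.approx(0.6)
        assert is_target is False

    def test_unreachable_threshold(self):
        model = p.NetworkModel(w=np.zeros((15, 31)), b=np.zeros(15),
                               hw=np.zeros(15), ob=0.9473, threshold=1.0)
        _, is_target = p.classify_interval(model, np.zeros(31))
        assert is_target is False


class TestTrain:
    def test_separable_features_reach_perfect_training_accuracy(self):
        X, T = separable_dataset()
        model, report = p.train(X, T, TrainingConfig(seed=1))
        y = p.forward(model, X)
        assert np.array_equal((y > model.threshold).astype(float), T)
        assert report.mse_train < 0.05

    def test_goal_met_at_init_runs_zero_epochs(self):
        X, T = separable_dataset(20)
        _, report = p.train(X, T, TrainingConfig(seed=1, mse_goal=1e9))
        assert report.epochs_run == 0
        assert report.stop_reason == "mse_goal"

    def test_deterministic_given_seed(self):
        X, T = separable_dataset(30)
        cfg = TrainingConfig(seed=5, max_epochs=500)
        a, _ = p.train(X, T, cfg)
        b, _ = p.train(X, T, cfg)
        np.testing.assert_array_equal(a.w, b.w)
        np.testing.assert_array_equal(a.hw, b.hw)

    def test_loss_non_increasing_for_small_learning_rate(self):
        X, T = separable_dataset(50)
        cfg = TrainingConfig(seed=2, learning_rate=0.001, max_epochs=2000,
                             patience=10_000)
        _, report = p.train(X, T, cfg)
        losses = [mse for _, mse in report.checkpoints]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_degenerate_split_rejected(self):
        X, T = separable_dataset(2)
        with pytest.raises(InvalidParameterError):
            p.train(X[:2], T[:2], TrainingConfig(seed=1))

    def test_invalid_split_fractions(self):
        with pytest.raises(InvalidParameterError):
            TrainingConfig(split=(0.5, 0.2, 0.2))


class TestThresholdDiagnostic:
    def test_reports_separated_score_ranges(self, trained_setup):
        model = trained_setup["model"]
        session = trained_setup["train_session"]
        tpl = model.template
        X, T = p.training_matrix(session, tpl)
        diag = p.threshold_diagnostic(model, X, T, n_trials=20, seed=0)
        assert diag["target_median"] > diag["nontarget_median"]
        assert diag["configured_threshold"] == pytest.approx(0.6)
        assert diag["n_scored"] == 80


class TestPipelineRecovery:
    def test_trained_pipeline_recovers_held_out_targets(self, trained_setup):
        """Full simulate -> template -> train -> classify chain: single-epoch
        accuracy on a held-out session beats chance (25%) by a wide margin."""
        acc = p.single_epoch_accuracy(
            trained_setup["test_trials"],
            trained_setup["test_session"].truth,
            trained_setup["model"],
        )
        assert acc >= 0.60
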