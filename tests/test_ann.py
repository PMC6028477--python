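"""Network forward pass, Levenberg–Marquardt training, fit metrics."""

import numpy as np
import pytest

from rootmedia import ann
from rootmedia.ann import (
    NetworkWeights,
    TrainingConfig,
    forward,
    mae,
    mbe,
    mse,
    r_squared,
    rmse,
    tansig,
    train,
)


def nested_loop_forward(weights: NetworkWeights, x: np.ndarray) -> float:
    """Independent brute-force evaluator: explicit sums, no linear algebra."""
    total = weights.output_bias
    for i in range(weights.n_hidden):
        s = weights.hidden_biases[i]
        for n in range(weights.n_inputs):
            s += weights.hidden_weights[i, n] * x[n]
        h = 2.0 / (1.0 + np.exp(-2.0 * s)) - 1.0
        total += weights.output_weights[i] * h
    return total


def random_weights(rng, n_inputs=5, n_hidden=8, scale=2.0):
    return NetworkWeights(
        rng.normal(0, scale, (n_hidden, n_inputs)),
        rng.normal(0, scale, n_hidden),
        rng.normal(0, scale, n_hidden),
        float(rng.normal(0, scale)),
    )


class TestTansig:
    def test_matches_logistic_form_and_symmetry(self):
        assert tansig(0.0) == 0.0
        assert tansig(0.5) == pytest.approx(2 / (1 + np.exp(-1)) - 1, rel=1e-15)
        n = np.linspace(-3, 3, 11)
        assert tansig(-n) == pytest.approx(-tansig(n))
        assert tansig(50.0) == pytest.approx(1.0)
        assert np.all(np.abs(tansig(np.array([-1e3, 1e3]))) <= 1.0)


class TestForward:
    def test_zero_network_outputs_zero(self):
        w = NetworkWeights(np.zeros((8, 5)), np.zeros(8), np.zeros(8), 0.0)
        x = np.random.default_rng(0).normal(size=(10, 5))
        assert np.all(forward(w, x) == 0.0)

    def test_single_unit_passthrough_reduces_to_tansig(self):
        hw = np.zeros((8, 5))
        hw[0, 0] = 1.0
        ow = np.zeros(8)
        ow[0] = 1.0
        w = NetworkWeights(hw, np.zeros(8), ow, 0.0)
        x = np.linspace(-2, 2, 9)
        X = np.zeros((9, 5))
        X[:, 0] = x
        assert forward(w, X) == pytest.approx(tansig(x))

    def test_agrees_with_nested_loop_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            w = random_weights(rng)
            x = rng.normal(0, 2, 5)
            assert forward(w, x)[0] == pytest.approx(nested_loop_forward(w, x), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        w = NetworkWeights(np.zeros((8, 5)), np.zeros(8), np.zeros(8), 0.0)
        with pytest.raises(ValueError, match="inputs"):
            forward(w, np.zeros((3, 4)))

    def test_weights_vector_roundtrip_and_json(self, tmp_path):
        rng = np.random.default_rng(5)
        w = random_weights(rng)
        again = NetworkWeights.from_vector(w.to_vector(), n_inputs=5)
        assert again.hidden_weights == pytest.approx(w.hidden_weights)
        assert again.output_bias == pytest.approx(w.output_bias)
        w.save(tmp_path / "w.json")
        loaded = NetworkWeights.load(tmp_path / "w.json")
        x = rng.normal(size=5)
        assert forward(loaded, x) == pytest.approx(forward(w, x))


class TestMetrics:
    def test_perfect_fit(self):
        o = np.array([0.2, 1.4, 3.3])
        assert r_squared(o, o) == 1.0
        assert rmse(o, o) == 0.0
        assert mbe(o, o) == 0.0
        assert mse(o, o) == 0.0

    def test_three_point_hand_values(self):
        O, M = np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0])
        assert rmse(O, M) == pytest.approx(np.sqrt(1 / 3))
        assert mbe(O, M) == pytest.approx(1 / 3)
        assert mae(O, M) == pytest.approx(1 / 3)
        assert r_squared(O, M) == pytest.approx(0.5)
        assert mse(O, M) == pytest.approx(1 / 3)

    def test_constant_predictor_scores_zero_r2(self):
        O = np.array([1.0, 2.0, 3.0])
        M = np.full(3, O.mean())
        assert r_squared(O, M) == pytest.approx(0.0)

    def test_zero_variance_observations_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            r_squared(np.ones(4), np.zeros(4))

    def test_bias_bounded_by_rmse(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            O, M = rng.normal(size=(2, 20))
            assert abs(mbe(O, M)) <= rmse(O, M) + 1e-12
            assert rmse(O, M) ** 2 == pytest.approx(mse(O, M))

    def test_length_checks(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])


class TestTraining:
    def test_realizable_linear_target_reaches_goal(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (216, 5))
        y = X[:, 0]
        result = train(X, y, TrainingConfig(seed=0))
        assert result.stop_reason == "mse_goal"
        assert result.epochs < 800
        assert result.train_mse <= 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, (60, 5))
        y = np.tanh(X[:, 1]) - 0.3 * X[:, 2]
        a = train(X, y, TrainingConfig(seed=11, max_epochs=50))
        b = train(X, y, TrainingConfig(seed=11, max_epochs=50))
        assert a.weights.to_vector() == pytest.approx(b.weights.to_vector())
        c = train(X, y, TrainingConfig(seed=12, max_epochs=50))
        assert not np.allclose(a.weights.to_vector(), c.weights.to_vector())

    def test_accepted_lm_steps_monotonically_decrease_loss(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (100, 5))
        y = 0.5 * X[:, 0] * X[:, 3] + 0.2 * X[:, 4]
        result = train(X, y, TrainingConfig(seed=3))
        diffs = np.diff(result.mse_history)
        assert np.all(diffs <= 1e-15)

    def test_parameter_recovery_from_frozen_network(self):
        """Noise-free data from a random 5-8-1 net is re-learned to R2>=0.99."""
        rng = np.random.default_rng(21)
        truth = NetworkWeights(
            rng.normal(0, 0.8, (8, 5)), rng.normal(0, 0.5, 8),
            rng.normal(0, 0.8, 8), float(rng.normal()),
        )
        X = rng.uniform(-1, 1, (216, 5))
        y = forward(truth, X)
        result = train(X, y, TrainingConfig(seed=4))
        grid = rng.uniform(-1, 1, (500, 5))
        assert r_squared(forward(truth, grid), forward(result.weights, grid)) >= 0.99

    def test_constant_target_returns_constant_predictor(self):
        X = np.random.default_rng(0).uniform(-1, 1, (30, 5))
        with pytest.warns(UserWarning, match="constant"):
            result = train(X, np.full(30, 0.7))
        assert forward(result.weights, X) == pytest.approx(np.full(30, 0.7))
        assert result.stop_reason == "constant_target"

    def test_non_finite_data_rejected(self):
        X = np.zeros((25, 5))
        y = np.zeros(25)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train(X, y)

    def test_gradient_descent_fallback_reduces_loss(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(-1, 1, (120, 5))
        y = 0.8 * X[:, 0]
        cfg = TrainingConfig(algorithm="gradient_descent_momentum", max_epochs=300, seed=9)
        result = train(X, y, cfg)
        assert result.mse_history[-1] < result.mse_history[0] * 0.5

    def test_response_models_are_independent(self, model_cache):
        """Retraining one response never perturbs another at fixed seeds."""
        _, model_a, _ = model_cache("RN", 0)
        before = model_a.weights.to_vector().copy()
        model_cache("RL", 0)  # train a different response in between
        from rootmedia.modeling import prepare_dataset, train_response_model

        bundle = prepare_dataset("RN", seed=0)
        model_again, _ = train_response_model(bundle, TrainingConfig(seed=2))
        assert model_again.weights.to_vector() == pytest.approx(before)


class TestResponseModel:
    def test_predictions_respect_physical_domain(self, model_cache):
        bundle, model, _ = model_cache("R%", 0)
        corners = np.array(
            [
                [bundle.norm.minima[c] for c in ("no3", "nh4", "k", "ca", "cl")],
                [bundle.norm.maxima[c] for c in ("no3", "nh4", "k", "ca", "cl")],
            ]
        )
        rng = np.random.default_rng(0)
        X = rng.uniform(corners[0], corners[1], size=(500, 5))
        y = model.predict(X)
        assert np.all((y >= 0.0) & (y <= 1.0))
        raw = model.predict(X, clip_domain=False)
        assert np.all(np.isfinite(raw))

    def test_serialization_roundtrip(self, model_cache, tmp_path):
        _, model, _ = model_cache("FW", 0)
        model.save(tmp_path / "m.json")
        loaded = ann.ResponseModel.load(tmp_path / "m.json")
        X = np.random.default_rng(1).uniform(10, 40, (20, 5))
        assert loaded.predict(X) == pytest.approx(model.predict(X))
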