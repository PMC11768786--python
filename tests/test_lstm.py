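"""LSTM cell semantics, softmax/cross-entropy closed forms, BPTT gradients
against central finite differences, and training/evaluation behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fatiguekit import lstm
from fatiguekit.lstm import (
    LSTMState,
    TrainConfig,
    backward,
    cell_step,
    cross_entropy,
    evaluate,
    forward,
    init_params,
    load_params,
    one_hot,
    save_params,
    softmax,
    train,
)


def _force_gate(layer, gate, value):
    """Drive a gate to ~0 or ~1 via a large bias."""
    b = {"f": layer.b_f, "i": layer.b_i, "e": layer.b_e}[gate]
    b[:] = 50.0 if value else -50.0


def finite_difference_check(params, X, Y, eps=1e-6, floor=1e-4):
    """Max normalized deviation between BPTT and central differences.

    The error is |fd - g| / max(|fd| + |g|, floor): a pure relative error
    for gradients of visible magnitude, with an absolute floor so that
    ~1e-10 finite-difference noise on near-zero gradients is not magnified.
    """
    grads = backward(params, X, Y)
    worst = 0.0
    for (_, p), (_, g) in zip(params.named_arrays(), grads.named_arrays()):
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = cross_entropy(forward(params, X), Y)
            p[idx] = orig - eps
            lm = cross_entropy(forward(params, X), Y)
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            worst = max(worst, abs(fd - g[idx]) / max(abs(fd) + abs(g[idx]), floor))
    return worst


class TestCellStep:
    def test_forget_gate_one_retains_cell_state(self, rng):
        params = init_params(2, (4,), 3, seed=0)
        layer = params.layers[0]
        _force_gate(layer, "f", True)
        _force_gate(layer, "i", False)
        prev = LSTMState(rng.standard_normal((1, 4)), rng.standard_normal((1, 4)))
        state = cell_step(layer, rng.standard_normal((1, 2)), prev)
        np.testing.assert_allclose(state.c, prev.c, rtol=1e-12)

    def test_forget_and_input_zero_clears_cell_state(self, rng):
        params = init_params(2, (4,), 3, seed=0)
        layer = params.layers[0]
        _force_gate(layer, "f", False)
        _force_gate(layer, "i", False)
        prev = LSTMState(rng.standard_normal((1, 4)), rng.standard_normal((1, 4)))
        state = cell_step(layer, rng.standard_normal((1, 2)), prev)
        np.testing.assert_allclose(state.c, 0.0, atol=1e-20)

    def test_all_zero_params_give_zero_hidden(self):
        params = init_params(3, (5,), 3, seed=0, scale=0.0)
        state = cell_step(params.layers[0], np.ones((1, 3)), LSTMState.zeros(1, 5))
        np.testing.assert_array_equal(state.h, np.zeros((1, 5)))
        np.testing.assert_array_equal(state.c, np.zeros((1, 5)))
        assert np.all(state.f == 0.5) and np.all(state.i == 0.5)

    def test_shape_mismatch_rejected(self):
        params = init_params(3, (5,), 3, seed=0)
        with pytest.raises(ValueError, match="shape"):
            cell_step(params.layers[0], np.ones((1, 4)), LSTMState.zeros(1, 5))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_gate_boundedness(self, seed):
        """Every stored gate activation lies strictly in (0,1); |tanh| <= 1."""
        rng = np.random.default_rng(seed)
        params = init_params(3, (4,), 3, seed=seed)
        state = LSTMState.zeros(2, 4)
        for _ in range(5):
            state = cell_step(params.layers[0], rng.standard_normal((2, 3)), state)
            for gate in (state.f, state.i, state.e):
                assert np.all((gate > 0) & (gate < 1))
            assert np.all(np.abs(state.c_tilde) <= 1.0)
            assert np.all(np.abs(state.h) <= 1.0)


class TestSoftmaxAndLoss:
    def test_uniform_logits(self):
        np.testing.assert_allclose(softmax(np.zeros(3)), np.full(3, 1 / 3))

    def test_shift_invariance(self, rng):
        z = rng.standard_normal(5)
        np.testing.assert_allclose(softmax(z), softmax(z + 17.3), rtol=1e-12)

    def test_normalization_under_extreme_logits(self):
        p = softmax(np.array([1000.0, -1000.0, 0.0]))
        assert np.sum(p) == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_forward_probabilities_normalized(self, rng):
        params = init_params(5, (10, 20), 3, seed=1)
        probs = forward(params, rng.standard_normal((7, 10, 5)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((probs > 0) & (probs < 1))

    def test_cross_entropy_closed_forms(self):
        assert cross_entropy(np.array([1.0, 0.0, 0.0]), np.array([1.0, 0, 0])) == pytest.approx(0.0)
        assert cross_entropy(np.full(3, 1 / 3), np.array([0, 1.0, 0])) == pytest.approx(np.log(3))
        assert cross_entropy(np.array([0.5, 0.25, 0.25]),
                             np.array([1.0, 0, 0])) == pytest.approx(np.log(2))

    def test_zero_probability_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            loss = cross_entropy(np.array([0.0, 1.0, 0.0]), np.array([1.0, 0, 0]))
        assert np.isfinite(loss)


class TestBackward:
    def test_output_layer_gradient_closed_form(self, rng):
        """For a single step, d(loss)/d(w_y) = (softmax - onehot)^T h."""
        params = init_params(2, (3,), 3, seed=2)
        X = rng.standard_normal((1, 1, 2))
        Y = one_hot(np.array([1]), 3)
        probs, = (forward(params, X),)
        grads = backward(params, X, Y)
        _, caches, h_final = lstm._unroll(params, X)
        expected = (probs - Y).T @ h_final
        np.testing.assert_allclose(grads.w_y, expected, rtol=1e-10)

    @pytest.mark.parametrize("shape", [
        dict(F=2, H=(3,), T=4, B=2),
        dict(F=2, H=(3, 2), T=4, B=3),
        dict(F=5, H=(4, 3), T=3, B=2),
    ])
    def test_gradients_match_finite_differences(self, rng, shape):
        params = init_params(shape["F"], shape["H"], 3, seed=7)
        X = rng.standard_normal((shape["B"], shape["T"], shape["F"]))
        Y = one_hot(rng.integers(0, 3, shape["B"]), 3)
        assert finite_difference_check(params, X, Y) < 1e-5

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10**6))
    def test_gradient_check_property(self, seed):
        rng = np.random.default_rng(seed)
        params = init_params(2, (3,), 3, seed=seed)
        X = rng.standard_normal((2, 3, 2))
        Y = one_hot(rng.integers(0, 3, 2), 3)
        assert finite_difference_check(params, X, Y) < 1e-5

    def test_zero_learning_signal_gives_zero_gradients(self):
        """If predicted probabilities equal the labels, all gradients vanish."""
        params = init_params(2, (3,), 3, seed=3)
        # force the network output to match by using uniform labels
        X = np.zeros((3, 2, 2))
        probs = forward(params, X)
        grads = backward(params, X, probs)  # labels := model output
        for _, g in grads.named_arrays():
            np.testing.assert_allclose(g, 0.0, atol=1e-12)


class TestTraining:
    def _toy_separable(self, rng, n=20):
        """Two well-separated sequence classes (mapped to labels 0/2)."""
        X0 = rng.normal(0.2, 0.05, (n, 4, 2))
        X1 = rng.normal(0.8, 0.05, (n, 4, 2))
        X = np.concatenate([X0, X1])
        y = np.array([0] * n + [2] * n)
        return X, y

    def test_separable_classes_reach_perfect_training_accuracy(self, rng):
        X, y = self._toy_separable(rng)
        params = init_params(2, (4,), 3, seed=5)
        result = train(params, X, y, TrainConfig(max_epochs=200, learning_rate=1.0, seed=5))
        assert evaluate(result.params, X, y).accuracy == 1.0

    def test_zero_learning_rate_freezes_loss(self, rng):
        X, y = self._toy_separable(rng, n=5)
        params = init_params(2, (3,), 3, seed=5)
        result = train(params, X, y, TrainConfig(max_epochs=10, learning_rate=0.0))
        assert np.ptp(result.losses) == 0.0

    def test_small_learning_rate_monotone_loss(self, rng):
        """Full-batch GD with a small enough step never increases the loss."""
        X, y = self._toy_separable(rng, n=5)
        params = init_params(2, (3,), 3, seed=5)
        result = train(params, X, y, TrainConfig(max_epochs=50, learning_rate=0.01))
        assert np.all(np.diff(result.losses) <= 1e-12)

    def test_training_is_deterministic(self, rng):
        X, y = self._toy_separable(rng, n=5)
        runs = []
        for _ in range(2):
            params = init_params(2, (3,), 3, seed=9)
            runs.append(train(params, X, y, TrainConfig(max_epochs=20, learning_rate=0.5)))
        np.testing.assert_array_equal(runs[0].losses, runs[1].losses)
        for (_, a), (_, b) in zip(runs[0].params.named_arrays(), runs[1].params.named_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_loss_tolerance_stops_early(self, rng):
        X, y = self._toy_separable(rng)
        params = init_params(2, (4,), 3, seed=5)
        result = train(params, X, y,
                       TrainConfig(max_epochs=200, learning_rate=1.0, loss_tolerance=0.3))
        assert len(result.losses) < 200
        assert result.losses[-1] < 0.3


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        X, y = np.zeros((6, 2, 2)), np.array([0, 1, 2, 0, 1, 2])
        params = init_params(2, (3,), 3, seed=1)
        probs = forward(params, X)
        res = evaluate(params, X, np.argmax(probs, axis=1))
        assert res.accuracy == 1.0
        assert np.trace(res.confusion) == 6

    def test_uninformative_model_on_balanced_set(self):
        """All-zero weights predict one class; balanced 3-class accuracy = 1/3."""
        params = init_params(2, (3,), 3, seed=0, scale=0.0)
        X = np.random.default_rng(0).standard_normal((30, 4, 2))
        y = np.tile([0, 1, 2], 10)
        assert evaluate(params, X, y).accuracy == pytest.approx(1 / 3)

    def test_single_sample_confusion(self):
        params = init_params(2, (3,), 3, seed=1)
        res = evaluate(params, np.zeros((1, 2, 2)), np.array([2]))
        assert res.confusion.sum() == 1
        assert np.count_nonzero(res.confusion) == 1


class TestSerialization:
    def test_weights_round_trip(self, tmp_path, rng):
        params = init_params(5, (10, 20), 3, seed=4)
        path = tmp_path / "weights.yaml"
        save_params(params, path, extra={"domain": "time_frequency"})
        loaded = load_params(path)
        X = rng.standard_normal((2, 3, 5))
        np.testing.assert_allclose(forward(params, X), forward(loaded, X), atol=1e-12)
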