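"""Neural-network core: activations, Adam, architecture shapes, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hierpath import nn
from hierpath.models import (
    CNNArchitectureSpec,
    TrainingConfig,
    build_baseline,
    build_cnn,
    train_model,
)


class TestActivations:
    def test_softmax_uniform_and_closed_form(self):
        assert np.allclose(nn.softmax([0.0, 0.0, 0.0]), [1 / 3] * 3)
        assert np.allclose(nn.softmax([0.0, np.log(2)]), [1 / 3, 2 / 3])

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=10),
        st.floats(-20, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_softmax_normalized_and_shift_invariant(self, logits, shift):
        p = nn.softmax(logits)
        assert np.all(p > 0) and np.isclose(p.sum(), 1.0)
        assert np.allclose(p, nn.softmax(np.asarray(logits) + shift))

    def test_softmax_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            nn.softmax([])
        with pytest.raises(ValueError):
            nn.softmax([np.inf, 0.0])

    @pytest.mark.parametrize(
        "kind,x,expected",
        [("sigmoid", 0.0, 0.5), ("relu", -3.0, 0.0), ("relu", 2.5, 2.5)],
    )
    def test_named_activations(self, kind, x, expected):
        assert nn.apply_activation(x, kind) == pytest.approx(expected)

    def test_unknown_activation_rejected(self):
        with pytest.raises(ValueError):
            nn.apply_activation(0.0, "tanh")


def _oracle_adam(thetas, grads, lr=0.001, b1=0.9, b2=0.999, eps=1e-8):
    """Independent scalar Adam: moment recurrences written out longhand."""
    theta = thetas
    m = v = 0.0
    out = []
    for t, g in enumerate(grads, start=1):
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        m_hat = m / (1 - b1**t)
        v_hat = v / (1 - b2**t)
        theta = theta - lr * m_hat / (np.sqrt(v_hat) + eps)
        out.append(theta)
    return out


class TestAdam:
    def test_zero_gradient_leaves_parameter(self):
        theta, state = 1.5, nn.AdamState.zeros_like(1.5)
        new, _ = nn.adam_step(theta, 0.0, state)
        assert new == pytest.approx(1.5)

    def test_first_step_hand_value(self):
        theta, state = 1.0, nn.AdamState.zeros_like(1.0)
        new, _ = nn.adam_step(theta, 1.0, state, nn.AdamSpec(eps=1e-8))
        assert new == pytest.approx(1.0 - 0.001 * 1.0 / (1.0 + 1e-8), abs=1e-15)

    def test_constant_gradient_monotone(self):
        theta, state = 0.0, nn.AdamState.zeros_like(0.0)
        values = []
        for _ in range(10):
            theta, state = nn.adam_step(theta, 2.7, state)
            values.append(float(theta))
        assert np.all(np.diff(values) < 0)

    def test_matches_scalar_oracle_on_random_sequences(self):
        """100 random scalar (theta0, gradient sequence) pairs agree with an
        independently written Adam to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            theta0 = float(rng.normal())
            grads = rng.normal(size=rng.integers(1, 20))
            expected = _oracle_adam(theta0, grads)
            theta, state = theta0, nn.AdamState.zeros_like(theta0)
            for g, want in zip(grads, expected):
                theta, state = nn.adam_step(theta, float(g), state)
                assert abs(float(theta) - want) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nn.adam_step(np.zeros(3), np.zeros(4), nn.AdamState.zeros_like(np.zeros(3)))


class TestArchitectureShapes:
    def test_full_scale_pool_sides(self):
        """With 1000x1000x3 input the three pooling stages leave spatial
        sides 200, 40 and 5."""
        spec = CNNArchitectureSpec(input_size=1000)
        assert spec.pool_output_sides() == (200, 40, 5)
        net = build_cnn(spec, 3)
        shapes = net.output_shapes()
        assert 200 in [s[0] for s in shapes] and (5, 5, 64) in shapes
        assert shapes[-1] == (3,)

    def test_test_scale_pool_sides(self):
        spec = CNNArchitectureSpec(input_size=200)
        assert spec.pool_output_sides() == (40, 8, 1)

    def test_dense_head_width(self):
        net = build_cnn(CNNArchitectureSpec(input_size=200), 4)
        assert (128,) in net.output_shapes()
        assert net.output_shapes()[-1] == (4,)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(CNNArchitectureSpec(input_size=130), 3)

    @pytest.mark.parametrize("kind,width", [("mlp", 6), ("flat_cnn", 6), ("flat_dcnn", 6)])
    def test_baselines_output_width(self, kind, width):
        net = build_baseline(kind, width, input_size=100)
        assert net.output_shapes()[-1] == (width,)

    def test_flat_cnn_probabilities_normalized(self):
        net = build_baseline("flat_cnn", 6, input_size=100)
        x = np.random.default_rng(0).random((2, 100, 100, 3), dtype=np.float32)
        probs = nn.softmax(net.forward(x), axis=1)
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of a conv-pool-dense stack agree with central
        finite differences (float32 tolerance)."""
        rng = np.random.default_rng(0)
        net = nn.Sequential(
            [nn.Conv2D(4, 3), nn.ReLU(), nn.MaxPool2D(2), nn.Flatten(), nn.Dense(5)],
            (8, 8, 2),
            seed=1,
        )
        x = rng.standard_normal((3, 8, 8, 2)).astype(np.float32)
        y = np.array([0, 2, 4])
        loss, dl = nn.softmax_cross_entropy(net.forward(x), y)
        net.backward(dl)
        for theta, grad in net.params():
            flat, gflat = theta.ravel(), grad.ravel()
            for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                old, eps = flat[i], 1e-3
                flat[i] = old + eps
                lp, _ = nn.softmax_cross_entropy(net.forward(x), y)
                flat[i] = old - eps
                lm, _ = nn.softmax_cross_entropy(net.forward(x), y)
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - gflat[i]) < 5e-3 + 0.02 * abs(numeric)


@pytest.fixture(scope="module")
def toy_data():
    """Two trivially separable classes: dark vs bright 50-pixel tiles."""
    rng = np.random.default_rng(1)
    dark = rng.random((20, 50, 50, 3), dtype=np.float32) * 0.3
    bright = 0.7 + rng.random((20, 50, 50, 3), dtype=np.float32) * 0.3
    x = np.concatenate([dark, bright])
    y = np.array([0] * 20 + [1] * 20)
    return x, y


class TestTraining:
    def _mlp(self, seed=0):
        return nn.Sequential(
            [nn.Flatten(), nn.Dense(16), nn.ReLU(), nn.Dense(2)], (50, 50, 3), seed=seed
        )

    def test_loss_decreases_on_separable_data(self, toy_data):
        x, y = toy_data
        model = train_model(
            self._mlp(), x, y, ("a", "b"), TrainingConfig(epochs=5, seed=0)
        )
        assert model.history["train_loss"][-1] < model.history["train_loss"][0]

    def test_fixed_seed_reproducible(self, toy_data):
        x, y = toy_data
        cfg = TrainingConfig(epochs=3, seed=4)
        m1 = train_model(self._mlp(seed=4), x, y, ("a", "b"), cfg)
        m2 = train_model(self._mlp(seed=4), x, y, ("a", "b"), cfg)
        assert m1.history["train_loss"] == m2.history["train_loss"]
        assert np.array_equal(m1.predict(x), m2.predict(x))

    def test_label_outside_space_rejected(self, toy_data):
        x, y = toy_data
        with pytest.raises(ValueError, match="label"):
            train_model(self._mlp(), x, np.full_like(y, 7), ("a", "b"), TrainingConfig())

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_model(
                self._mlp(),
                np.empty((0, 50, 50, 3)),
                np.empty(0, dtype=int),
                ("a", "b"),
                TrainingConfig(),
            )
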