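"""Confusion-matrix metrics, bootstrap uncertainty, Grad-CAM."""

import numpy as np
import pytest

from hierpath import nn
from hierpath.evaluation import (
    compute_metrics,
    confusion,
    evaluate,
    gradcam,
    gradcam_overlay,
    metric_uncertainty,
)
from hierpath.models import TrainedModel, TrainingConfig, train_model


class TestConfusion:
    def test_perfect_prediction(self):
        counts = confusion([0, 1, 2], [0, 1, 2], 3)
        assert np.all(counts.tp == 1)
        assert np.all(counts.fp == 0) and np.all(counts.fn == 0)

    def test_enumerated_three_samples(self):
        counts = confusion([0, 0, 1], [0, 1, 1], 2)
        assert (counts.tp[0], counts.fn[0], counts.fp[0], counts.tn[0]) == (1, 1, 0, 1)
        assert (counts.tp[1], counts.fp[1], counts.fn[1], counts.tn[1]) == (1, 1, 0, 1)

    def test_count_identities(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        counts = confusion(y_true, y_pred, 4)
        for l in range(4):
            assert counts.tp[l] + counts.fp[l] + counts.fn[l] + counts.tn[l] == 100
        assert counts.tp.sum() == int(np.sum(y_true == y_pred))

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [], 2)
        with pytest.raises(ValueError):
            confusion([0, 1], [0], 2)
        with pytest.raises(ValueError):
            confusion([0, 5], [0, 1], 2)


class TestMetrics:
    def test_perfect_is_all_ones(self):
        report = evaluate([0, 1, 2], [0, 1, 2], ("a", "b", "c"))
        assert report.accuracy == 1.0
        assert report.micro_precision == report.micro_recall == report.micro_f1 == 1.0

    def test_micro_precision_worked_example(self):
        report = evaluate([0, 0, 1], [0, 1, 1], ("a", "b"))
        assert report.micro_precision == pytest.approx(2 / 3)

    def test_matches_per_sample_tally_oracle(self):
        """Micro metrics agree with an independent per-sample tally and with
        scikit-learn on random 4-class labels."""
        from sklearn.metrics import f1_score, precision_score, recall_score

        rng = np.random.default_rng(5)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        report = evaluate(y_true, y_pred, ("a", "b", "c", "d"))
        correct = sum(int(t == p) for t, p in zip(y_true, y_pred))
        assert report.accuracy == pytest.approx(correct / 200)
        assert report.micro_precision == pytest.approx(
            precision_score(y_true, y_pred, average="micro")
        )
        assert report.micro_recall == pytest.approx(
            recall_score(y_true, y_pred, average="micro")
        )
        assert report.micro_f1 == pytest.approx(
            f1_score(y_true, y_pred, average="micro")
        )

    def test_micro_identity_on_single_label_predictions(self):
        """For single-label multi-class prediction, micro precision, recall
        and F1 all equal the accuracy."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(2, 6))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            r = evaluate(y_true, y_pred, tuple("abcdef"[:k]))
            assert r.micro_precision == pytest.approx(r.accuracy)
            assert r.micro_recall == pytest.approx(r.accuracy)
            assert r.micro_f1 == pytest.approx(r.accuracy)

    def test_zero_denominator_reported_as_undefined(self):
        report = compute_metrics(confusion([0, 0], [0, 0], 2), ("a", "b"))
        assert report.per_class["b"]["precision"] is None
        assert report.per_class["b"]["recall"] is None


class TestBootstrap:
    def test_constant_correct_zero_width(self):
        hw = metric_uncertainty([1, 1, 1, 1], [1, 1, 1, 1], "accuracy", seed=0)
        assert hw == 0.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        a = metric_uncertainty(y_true, y_pred, "f1", seed=9)
        b = metric_uncertainty(y_true, y_pred, "f1", seed=9)
        assert a == b and a > 0

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, 100)
        y_pred = np.where(rng.random(100) < 0.8, y_true, 1 - y_true)
        small = metric_uncertainty(y_true, y_pred, "accuracy", seed=1)
        big = metric_uncertainty(
            np.tile(y_true, 10), np.tile(y_pred, 10), "accuracy", seed=1
        )
        assert big < small / 2  # roughly sqrt(10) ~ 3.2x shrink

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            metric_uncertainty([1], [1], "accuracy")
        with pytest.raises(ValueError):
            metric_uncertainty([0, 1], [0, 1], "accuracy", n_boot=10)


@pytest.fixture(scope="module")
def tiny_model():
    """A small conv net trained to separate a dark blob from uniform
    background, so the class evidence is spatially localized."""
    rng = np.random.default_rng(0)
    size = 40
    blanks = 0.85 + 0.05 * rng.random((24, size, size, 3), dtype=np.float32)
    blobs = blanks.copy()
    positions = []
    for i in range(len(blobs)):
        r, c = rng.integers(6, size - 10, size=2)
        blobs[i, r : r + 6, c : c + 6] *= 0.2
        positions.append((int(r), int(c)))
    x = np.concatenate([blanks, blobs])
    y = np.array([0] * len(blanks) + [1] * len(blobs))
    net = nn.Sequential(
        [
            nn.Conv2D(8, 3), nn.ReLU(), nn.MaxPool2D(2),
            nn.Conv2D(8, 3), nn.ReLU(), nn.MaxPool2D(2),
            nn.Flatten(), nn.Dense(16), nn.ReLU(), nn.Dense(2),
        ],
        (size, size, 3),
        seed=2,
    )
    model = train_model(
        net, x, y, ("blank", "blob"),
        TrainingConfig(epochs=12, seed=0, validation_fraction=0.0),
    )
    return model, blobs, positions


class TestGradCAM:
    def test_heatmap_shape_and_range(self, tiny_model):
        model, blobs, _ = tiny_model
        heat = gradcam(model, blobs[0], target_class=1)
        assert heat.shape == blobs[0].shape[:2]
        assert heat.min() >= 0.0 and heat.max() <= 1.0 + 1e-9

    def test_peak_falls_inside_blob(self, tiny_model):
        model, blobs, positions = tiny_model
        hits = 0
        for img, (r, c) in zip(blobs[:10], positions[:10]):
            heat = gradcam(model, img, target_class=1)
            pr, pc = np.unravel_index(np.argmax(heat), heat.shape)
            # generous halo: pooling coarsens localization
            if r - 8 <= pr <= r + 14 and c - 8 <= pc <= c + 14:
                hits += 1
        assert hits >= 7

    def test_class_index_validated(self, tiny_model):
        model, blobs, _ = tiny_model
        with pytest.raises(ValueError):
            gradcam(model, blobs[0], target_class=5)

    def test_overlay_shape_dtype(self, tiny_model):
        model, blobs, _ = tiny_model
        heat = gradcam(model, blobs[0], target_class=1)
        image8 = (blobs[0] * 255).astype(np.uint8)
        overlay = gradcam_overlay(image8, heat)
        assert overlay.shape == image8.shape and overlay.dtype == np.uint8
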