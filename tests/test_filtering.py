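"""Informative-patch filter: autoencoder, k-means, cluster selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hierpath.filtering import (
    AutoencoderSpec,
    embed,
    filter_patches,
    kmeans,
    reconstruct,
    select_informative_cluster,
    train_autoencoder,
)

SMALL_SPEC = AutoencoderSpec(input_size=32, n_filters=8, pool=4, bottleneck=16)


def _patch_set(n=32, size=32, seed=0):
    """Half near-white background patches, half textured tissue-like."""
    rng = np.random.default_rng(seed)
    bg = 250 - np.abs(rng.normal(0, 3, (n // 2, size, size, 3)))
    tissue = rng.integers(60, 220, (n - n // 2, size, size, 3))
    return np.clip(np.concatenate([bg, tissue]), 0, 255).astype(np.uint8)


@pytest.fixture(scope="module")
def trained():
    return train_autoencoder(_patch_set(), SMALL_SPEC, epochs=5, seed=0)


class TestAutoencoder:
    def test_reconstruction_preserves_dimensions(self, trained):
        patches = _patch_set(4)
        out = reconstruct(trained, patches)
        assert out.shape == (4, 32, 32, 3)

    def test_loss_decreases_over_epochs(self, trained):
        assert trained.history[-1] < trained.history[0]

    def test_training_deterministic(self):
        a = train_autoencoder(_patch_set(8), SMALL_SPEC, epochs=2, seed=3)
        b = train_autoencoder(_patch_set(8), SMALL_SPEC, epochs=2, seed=3)
        assert a.history == b.history

    def test_embedding_length_and_determinism(self, trained):
        patches = _patch_set(6)
        va = embed(trained, patches)
        vb = embed(trained, patches)
        assert va.shape == (6, SMALL_SPEC.bottleneck)
        assert np.array_equal(va, vb)

    def test_background_and_tissue_embed_apart(self, trained):
        patches = _patch_set(2)
        vecs = embed(trained, patches)
        assert np.linalg.norm(vecs[0] - vecs[1]) > 0

    def test_too_few_patches_rejected(self):
        with pytest.raises(ValueError):
            train_autoencoder(_patch_set(1)[:1], SMALL_SPEC, epochs=1)

    def test_bottleneck_must_compress(self):
        with pytest.raises(ValueError):
            AutoencoderSpec(input_size=8, n_filters=2, pool=2, bottleneck=64)


def _exhaustive_best_objective(points, k=2):
    """Brute-force minimum of the k-means objective over all assignments of
    points to k non-empty groups."""
    n = len(points)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) < k:
            continue
        labels = np.asarray(labels)
        total = 0.0
        for j in range(k):
            members = points[labels == j]
            total += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, total)
    return best


class TestKMeans:
    def test_separated_clouds(self):
        result = kmeans(np.array([0.0, 0.1, 10.0, 10.1]), k=2, seed=0)
        groups = [set(np.flatnonzero(result.labels == j)) for j in range(2)]
        assert {0, 1} in groups and {2, 3} in groups

    def test_objective_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(6, 2))
        result = kmeans(points, k=2, seed=1)
        assert result.objective == pytest.approx(
            _exhaustive_best_objective(points), rel=1e-9
        )

    def test_identical_points_zero_objective(self):
        result = kmeans(np.ones((5, 3)), k=2, seed=0)
        assert result.objective == pytest.approx(0.0, abs=1e-12)

    def test_converged_state_invariants(self):
        """Assignments are one-hot, centroids equal member means, and the
        stored objective equals its recomputation."""
        rng = np.random.default_rng(3)
        points = rng.normal(size=(40, 4))
        result = kmeans(points, k=2, seed=2)
        a = result.assignment_matrix
        assert np.all(a.sum(axis=1) == 1)
        for j in range(2):
            members = points[result.labels == j]
            assert np.allclose(result.centroids[j], members.mean(axis=0))
        assert result.objective == pytest.approx(result.recompute_objective())
        dist = ((points[:, None] - result.centroids[None]) ** 2).sum(-1)
        assert np.array_equal(result.labels, dist.argmin(axis=1))

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((1, 2)), k=2)


class TestClusterSelection:
    def test_textured_cluster_selected(self):
        from hierpath.filtering import ClusteringResult

        patches = _patch_set(10)  # first half background, second half tissue
        labels = np.array([0] * 5 + [1] * 5)
        result = ClusteringResult(
            centroids=np.zeros((2, 1)),
            labels=labels,
            objective=0.0,
            points=np.zeros((10, 1)),
        )
        assert select_informative_cluster(result, patches) == 1

    def test_tie_breaks_to_lower_index(self):
        patches = np.stack([np.full((8, 8, 3), 100, np.uint8)] * 4)
        result = kmeans(np.array([0.0, 0.0, 9.0, 9.0]), k=2, seed=0)
        assert select_informative_cluster(result, patches) == 0

    def test_requires_two_clusters(self):
        result = kmeans(np.arange(9, dtype=float), k=3, seed=0)
        with pytest.raises(ValueError):
            select_informative_cluster(result, _patch_set(9))


class TestFilterPatches:
    def test_background_removed_tissue_kept(
        self, background_and_tissue_patches
    ):
        backgrounds, tissues = background_and_tissue_patches
        images = np.concatenate([backgrounds, tissues])
        n = len(images)
        frame = pd.DataFrame(
            {
                "slide_id": ["s"] * n,
                "patch_index": range(n),
                "row": 0,
                "col": 0,
                "parent_label": "CD",
                "child_label": "I",
                "split": "train",
                "path": "",
            }
        )
        out, _, result = filter_patches(
            frame, AutoencoderSpec(), seed=0, epochs=5, images=images
        )
        retained = out.retained.to_numpy().astype(bool)
        bg_removed = (~retained[: len(backgrounds)]).mean()
        tissue_kept = retained[len(backgrounds) :].mean()
        assert bg_removed >= 0.95
        assert tissue_kept >= 0.90
        assert set(out.columns) >= {"cluster", "retained"}

    def test_rerun_same_seed_identical(self, background_and_tissue_patches):
        backgrounds, tissues = background_and_tissue_patches
        images = np.concatenate([backgrounds[:6], tissues[:6]])
        frame = pd.DataFrame(
            {
                "slide_id": ["s"] * 12,
                "patch_index": range(12),
                "row": 0,
                "col": 0,
                "parent_label": "EE",
                "child_label": "",
                "split": "train",
                "path": "",
            }
        )
        a, _, _ = filter_patches(frame, AutoencoderSpec(), seed=5, epochs=2, images=images)
        b, _, _ = filter_patches(frame, AutoencoderSpec(), seed=5, epochs=2, images=images)
        assert a.retained.tolist() == b.retained.tolist()
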