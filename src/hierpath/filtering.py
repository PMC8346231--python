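"""Informative-patch filtering: autoencoder embedding + 2-means clustering.

Many tiles cut from a slide contain only background (near-white) or
border debris and would dilute classifier training.  The filter embeds
each patch with a small convolutional autoencoder (trained unsupervised
to reconstruct its input; the bottleneck is the feature vector), clusters
the embeddings with k-means (k = 2), and keeps the cluster whose member
patches show the higher mean pixel standard deviation — background
patches are near-uniform, tissue patches are textured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize
from sklearn.cluster import KMeans

from . import nn
from .patching import load_patch_images


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture of the patch autoencoder.

    One same-padded conv layer of ``n_filters`` kernels of size
    ``kernel_size`` (= 2k+1, preserving dimensions), a spatial
    downsampling, a dense bottleneck, and a mirrored decoder ending in a
    sigmoid so decode(encode(I)) has exactly the input's dimensions.
    Patches are resized to ``input_size`` before encoding.
    """

    input_size: int = 64
    channels: int = 3
    n_filters: int = 16
    kernel_size: int = 3
    pool: int = 4
    bottleneck: int = 64

    def __post_init__(self):
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (2k+1)")
        if self.input_size % self.pool != 0:
            raise ValueError("input size must be divisible by the pooling factor")
        reduced = self.input_size // self.pool
        if self.bottleneck >= reduced * reduced * self.n_filters:
            raise ValueError("bottleneck must be smaller than the flattened input")


@dataclass
class TrainedAutoencoder:
    spec: AutoencoderSpec
    network: nn.Sequential
    bottleneck_layer: int  # index such that layers[:bottleneck_layer] encode
    history: list[float] = field(default_factory=list)


def _build_network(spec: AutoencoderSpec, seed: int) -> tuple[nn.Sequential, int]:
    reduced = spec.input_size // spec.pool
    flat = reduced * reduced * spec.n_filters
    layers = [
        nn.Conv2D(spec.n_filters, spec.kernel_size),
        nn.ReLU(),
        nn.MaxPool2D(spec.pool),
        nn.Flatten(),
        nn.Dense(spec.bottleneck),  # bottleneck output: layer index 4
        nn.Dense(flat),
        nn.ReLU(),
        nn.Reshape((reduced, reduced, spec.n_filters)),
        nn.Upsample2D(spec.pool),
        nn.Conv2D(spec.channels, spec.kernel_size),
        nn.Sigmoid(),
    ]
    net = nn.Sequential(
        layers, (spec.input_size, spec.input_size, spec.channels), seed=seed
    )
    return net, 5


def prepare_patches(patches: np.ndarray, spec: AutoencoderSpec) -> np.ndarray:
    """Scale patches to [0, 1] float32 at the autoencoder's input size."""
    patches = np.asarray(patches)
    if patches.ndim != 4 or patches.shape[3] != spec.channels:
        raise ValueError("expected patches of shape (N, H, W, C)")
    if patches.dtype == np.uint8:
        patches = patches.astype(np.float32) / 255.0
    if patches.shape[1] != spec.input_size or patches.shape[2] != spec.input_size:
        patches = np.stack(
            [
                resize(
                    p,
                    (spec.input_size, spec.input_size),
                    order=1,
                    anti_aliasing=True,
                    preserve_range=True,
                )
                for p in patches
            ]
        )
    return patches.astype(np.float32)


def train_autoencoder(
    patches: np.ndarray,
    spec: AutoencoderSpec = AutoencoderSpec(),
    epochs: int = 5,
    seed: int = 0,
    batch_size: int = 16,
) -> TrainedAutoencoder:
    """Train the autoencoder to reconstruct ``patches`` (MSE, Adam)."""
    x = prepare_patches(patches, spec)
    if len(x) < 2:
        raise ValueError("need at least two patches to train the autoencoder")
    net, bottleneck_layer = _build_network(spec, seed)
    rng = np.random.default_rng(seed + 1)
    optimizer = nn.Adam(nn.AdamSpec())
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            batch = x[order[start : start + batch_size]]
            out = net.forward(batch, train=True, rng=rng)
            loss, dout = nn.mse_loss(out, batch)
            net.backward(dout)
            optimizer.step(net.params())
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedAutoencoder(
        spec=spec, network=net, bottleneck_layer=bottleneck_layer, history=history
    )


def reconstruct(model: TrainedAutoencoder, patches: np.ndarray) -> np.ndarray:
    """decode(encode(x)); output dimensions equal the (prepared) input's."""
    x = prepare_patches(patches, model.spec)
    return model.network.forward(x)


def embed(model: TrainedAutoencoder, patches: np.ndarray) -> np.ndarray:
    """Bottleneck feature vectors, one row per patch."""
    x = prepare_patches(patches, model.spec)
    out = x
    for layer in model.network.layers[: model.bottleneck_layer]:
        out = layer.forward(out, train=False)
    return np.asarray(out, dtype=np.float64)


# ---------------------------------------------------------------------------
# k-means


@dataclass
class ClusteringResult:
    """Converged k-means state.

    At convergence each centroid equals the mean of its assigned points
    and every point is assigned to its nearest centroid; ``objective`` is
    the sum of squared point-to-centroid distances.
    """

    centroids: np.ndarray  # (k, d)
    labels: np.ndarray  # (n,) int
    objective: float
    points: np.ndarray  # (n, d)

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def assignment_matrix(self) -> np.ndarray:
        """One-hot (n, k) assignment matrix; exactly one 1 per row."""
        a = np.zeros((len(self.points), self.k), dtype=int)
        a[np.arange(len(self.points)), self.labels] = 1
        return a

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def recompute_objective(self) -> float:
        d = self.points - self.centroids[self.labels]
        return float(np.sum(d * d))


def _lloyd_polish(points: np.ndarray, labels: np.ndarray, max_rounds: int = 100):
    """Exact Lloyd iterations until assignments are stable, so the returned
    state satisfies the centroid-mean and nearest-centroid conditions
    simultaneously (library stopping tolerances leave a small slack)."""
    k = labels.max() + 1
    for _ in range(max_rounds):
        centroids = np.stack(
            [
                points[labels == j].mean(axis=0)
                if np.any(labels == j)
                else points[0] * np.nan
                for j in range(k)
            ]
        )
        # empty clusters keep their previous centroid
        if np.any(np.isnan(centroids)):
            dist = ((points[:, None, :] - np.nan_to_num(centroids)[None]) ** 2).sum(-1)
        else:
            dist = ((points[:, None, :] - centroids[None]) ** 2).sum(-1)
        new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            return centroids, labels
        labels = new_labels
    return centroids, labels


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusteringResult:
    """Best-of-``n_init`` k-means on feature vectors.

    Initialization and restarts are delegated to k-means++; the winning
    solution is then polished with exact Lloyd steps until assignments
    stabilize.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    if len(points) < k:
        raise ValueError(f"need at least k={k} points, got {len(points)}")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
    ).fit(points)
    candidates = [km.labels_.astype(int)]
    n = len(points)
    if k == 2 and n <= 12:
        # tiny instances: k-means++ restarts can miss the global optimum,
        # so start Lloyd from every bipartition's centroids as well.  The
        # optimal partition is a Lloyd fixed point, so exhaustive restarts
        # make the returned solution provably optimal here.
        for mask in range(1, 2 ** (n - 1)):
            candidates.append(
                np.array([(mask >> i) & 1 for i in range(n)], dtype=int)
            )
    best: ClusteringResult | None = None
    for i, start in enumerate(candidates):
        if i > 0 and len(np.unique(start)) < k:
            continue  # degenerate pair init; the sklearn baseline remains
        centroids, labels = _lloyd_polish(points, start)
        result = ClusteringResult(
            centroids=centroids, labels=labels, objective=0.0, points=points
        )
        result.objective = result.recompute_objective()
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best


def select_informative_cluster(
    result: ClusteringResult, patches: np.ndarray
) -> int:
    """Index of the cluster whose patches have the higher mean pixel
    standard deviation (ties go to the lower index)."""
    if result.k != 2:
        raise ValueError("informative-cluster selection requires k = 2")
    if len(patches) != len(result.points):
        raise ValueError("patches and clustered points are misaligned")
    stds = np.array([float(np.std(p / 255.0 if p.dtype == np.uint8 else p))
                     for p in np.asarray(patches)])
    means = [
        stds[result.labels == j].mean() if np.any(result.labels == j) else -np.inf
        for j in range(2)
    ]
    return int(np.argmax(means))  # argmax takes the lower index on ties


def filter_patches(
    patch_frame: pd.DataFrame,
    spec: AutoencoderSpec = AutoencoderSpec(),
    seed: int = 0,
    epochs: int = 5,
    images: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TrainedAutoencoder, ClusteringResult]:
    """Run the full filter over a patch manifest.

    Returns a copy of the manifest with added ``cluster`` and ``retained``
    columns (every patch's decision is kept, nothing is silently dropped),
    plus the trained autoencoder and clustering state.  Use
    ``frame[frame.retained == 1]`` for the filtered set.
    """
    if images is None:
        images = load_patch_images(patch_frame)
    model = train_autoencoder(images, spec, epochs=epochs, seed=seed)
    features = embed(model, images)
    result = kmeans(features, k=2, seed=seed)
    keep = select_informative_cluster(result, images)
    out = patch_frame.copy()
    out["cluster"] = result.labels
    out["retained"] = (result.labels == keep).astype(int)
    return out, model, result
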