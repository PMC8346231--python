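"""Parent/child CNN classifiers, flat baselines and hierarchical training.

The slide classifier is a three-block CNN: conv(32, 3x3) -> maxpool(5) ->
conv(32, 3x3) -> maxpool(5) -> conv(64, 3x3) -> maxpool(8) -> dense(128)
-> softmax output, trained with Adam (lr 0.001, beta1 0.9, beta2 0.999)
on sparse categorical cross-entropy, ReLU activations and dropout in
every block.  Convolutions are same-padded so pooling alone sets the
spatial reduction: a 1000-pixel input shrinks 1000 -> 200 -> 40 -> 5; the
200-pixel working scale shrinks 200 -> 40 -> 8 -> 1.

The hierarchical model is one parent classifier over {Normal, EE, CD}
(color-balanced inputs) plus one child classifier per parent that has
children — here a 4-way Marsh-severity model trained only on CD patches
(stain-normalized inputs).  Flat CNN / MLP / deep-CNN baselines over the
6 leaf classes are provided for comparison.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .patching import load_patch_images
from .stain import (
    StainNormalizationModel,
    color_balance,
    estimate_balance_spec,
    fit_stain_model,
    normalize_stain,
)
from .taxonomy import ClassTaxonomy, build_default_taxonomy


@dataclass(frozen=True)
class CNNArchitectureSpec:
    """Topology of the slide-patch CNN (see module docstring)."""

    input_size: int = 1000
    channels: int = 3
    conv_filters: tuple[int, int, int] = (32, 32, 64)
    kernel_size: int = 3
    pools: tuple[int, int, int] = (5, 5, 8)
    dense_units: int = 128
    conv_dropout: float = 0.25
    dense_dropout: float = 0.5

    def pool_output_sides(self) -> tuple[int, ...]:
        """Spatial side after each pooling stage."""
        side = self.input_size
        sides = []
        for pool in self.pools:
            if side % pool:
                raise ValueError(
                    f"input size {self.input_size} is not divisible by the "
                    f"pooling cascade {self.pools}"
                )
            side //= pool
            sides.append(side)
        return tuple(sides)


#: Test-scale architecture: the same pooling cascade as the full
#: 1000-pixel spec, entering at 200 pixels (sides 40, 8, 1).
TEST_SCALE_SPEC = CNNArchitectureSpec(input_size=200)

#: Working-scale architecture used for end-to-end training in tests,
#: examples and the CLI: patches are downscaled to 100 pixels with pooling
#: cascade (5, 5, 2) (sides 20, 4, 2), leaving the dense head a 2x2
#: terminal feature map — a 1x1 map loses the spatial averages the
#: severity task needs.  Light dropout suits the small synthetic sets.
WORKING_SPEC = CNNArchitectureSpec(
    input_size=100, pools=(5, 5, 2), conv_dropout=0.1, dense_dropout=0.25
)


def default_pools(input_size: int) -> tuple[int, int, int]:
    """Pooling cascade for an input size: (5, 5, 8) when it divides evenly
    (the 1000- and 200-pixel scales), else (5, 5, 2) (the 100-pixel
    working scale, which keeps a 2x2 terminal feature map)."""
    if input_size % 200 == 0:
        return (5, 5, 8)
    if input_size % 50 == 0:
        return (5, 5, 2)
    raise ValueError(f"no pooling cascade divides input size {input_size}")


def build_cnn(
    spec: CNNArchitectureSpec, n_classes: int, seed: int = 0
) -> nn.Sequential:
    """Untrained patch CNN emitting ``n_classes`` logits."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    spec.pool_output_sides()  # validates divisibility
    layers: list[nn.Layer] = []
    for filters, pool in zip(spec.conv_filters, spec.pools):
        layers += [
            nn.Conv2D(filters, spec.kernel_size),
            nn.ReLU(),
            nn.MaxPool2D(pool),
            nn.Dropout(spec.conv_dropout),
        ]
    layers += [
        nn.Flatten(),
        nn.Dense(spec.dense_units),
        nn.ReLU(),
        nn.Dropout(spec.dense_dropout),
        nn.Dense(n_classes),
    ]
    return nn.Sequential(
        layers, (spec.input_size, spec.input_size, spec.channels), seed=seed
    )


def build_baseline(
    kind: str, n_classes: int = 6, input_size: int = 200, seed: int = 0
) -> nn.Sequential:
    """Flat (non-hierarchical) baselines over the leaf classes.

    ``flat_cnn`` is a two-block CNN; ``mlp`` is a multilayer perceptron on
    flattened RGB input; ``flat_dcnn`` is the slide-CNN topology with a
    leaf-wide output layer.
    """
    if kind == "flat_dcnn":
        return build_cnn(
            CNNArchitectureSpec(
                input_size=input_size, pools=default_pools(input_size)
            ),
            n_classes,
            seed=seed,
        )
    if kind == "flat_cnn":
        layers = [
            nn.Conv2D(32, 3),
            nn.ReLU(),
            nn.MaxPool2D(5),
            nn.Conv2D(32, 3),
            nn.ReLU(),
            nn.MaxPool2D(5),
            nn.Flatten(),
            nn.Dense(64),
            nn.ReLU(),
            nn.Dropout(0.5),
            nn.Dense(n_classes),
        ]
        return nn.Sequential(layers, (input_size, input_size, 3), seed=seed)
    if kind == "mlp":
        layers = [
            nn.Flatten(),
            nn.Dense(128),
            nn.ReLU(),
            nn.Dropout(0.5),
            nn.Dense(64),
            nn.ReLU(),
            nn.Dense(n_classes),
        ]
        return nn.Sequential(layers, (input_size, input_size, 3), seed=seed)
    raise ValueError(f"unknown baseline kind {kind!r}")


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings for one classifier.

    ``augment_orientation`` applies random 90-degree rotations and flips;
    ``augment_gamma`` applies a random per-patch gamma in the given range,
    which makes global intensity uninformative and forces the network onto
    spatial structure (the standard counter to slide-level stain casts).
    ``lr_decay`` cuts the learning rate to 1/3 at 60% and 1/10 at 85% of
    the epochs, and ``tail_averaging`` replaces the final parameters with
    their average over the post-decay (last 15%) epochs; both damp the
    end-of-training noise that otherwise dominates on small datasets.
    """

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    validation_fraction: float = 0.1
    augment_orientation: bool = False
    augment_gamma: tuple[float, float] | None = None
    lr_decay: bool = False
    tail_averaging: bool = False
    seed: int = 0


#: Training settings used for end-to-end runs at the working scale.
#: Orientation augmentation only: amplitude confounds are already removed
#: by the stain preprocessing, and gamma jitter on top costs accuracy.
WORKING_PARENT_CONFIG = TrainingConfig(
    epochs=40, learning_rate=0.003, validation_fraction=0.0,
    augment_orientation=True, lr_decay=True, tail_averaging=True,
)
WORKING_CHILD_CONFIG = TrainingConfig(
    epochs=80, learning_rate=0.003, validation_fraction=0.0,
    augment_orientation=True, lr_decay=True, tail_averaging=True,
)


def _as_float_images(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images)
    if images.dtype == np.uint8:
        return images.astype(np.float32) / 255.0
    return images.astype(np.float32)


def resize_images(images: np.ndarray, size: int) -> np.ndarray:
    """Anti-aliased resize of a patch stack to ``size`` pixels square."""
    from skimage.transform import resize

    images = _as_float_images(images)
    if images.shape[1] == size and images.shape[2] == size:
        return images
    return np.stack(
        [
            resize(im, (size, size), order=1, anti_aliasing=True).astype(np.float32)
            for im in images
        ]
    )


def _augment_batch(
    batch: np.ndarray, config: TrainingConfig, rng: np.random.Generator
) -> np.ndarray:
    out = batch.copy()
    if config.augment_orientation:
        for i in range(len(out)):
            out[i] = np.rot90(out[i], int(rng.integers(0, 4)))
            if rng.random() < 0.5:
                out[i] = out[i][:, ::-1]
    if config.augment_gamma is not None:
        g = rng.uniform(*config.augment_gamma, size=(len(out), 1, 1, 1))
        out = np.clip(out, 1e-3, 1.0) ** g.astype(np.float32)
    return np.ascontiguousarray(out)


def _fingerprint(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


@dataclass
class TrainedModel:
    """A trained classifier plus everything needed to reproduce it."""

    network: nn.Sequential
    class_names: tuple[str, ...]
    config: TrainingConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    data_fingerprint: str = ""
    arch: dict = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = resize_images(images, self.network.input_shape[0])
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.network.forward(x[start : start + batch_size])
            out.append(nn.softmax(logits, axis=1))
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)


def train_model(
    network: nn.Sequential,
    images: np.ndarray,
    labels: np.ndarray,
    class_names: tuple[str, ...],
    config: TrainingConfig = TrainingConfig(),
    arch: dict | None = None,
) -> TrainedModel:
    """Train a classifier network with Adam on cross-entropy.

    Labels must be integer-encoded into ``class_names``; a held-out
    validation fraction is split off (seeded) and its loss recorded per
    epoch alongside the training loss.
    """
    x = _as_float_images(images)
    y = np.asarray(labels, dtype=int)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(x) != len(y):
        raise ValueError("images and labels are misaligned")
    if y.min() < 0 or y.max() >= len(class_names):
        raise ValueError(
            f"label outside the model's label space of {len(class_names)} classes"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = int(len(x) * config.validation_fraction)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split left no training samples")
    optimizer = nn.Adam(
        nn.AdamSpec(
            learning_rate=config.learning_rate,
            beta1=config.beta1,
            beta2=config.beta2,
        )
    )
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    tail_start = int(config.epochs * 0.85)
    tail_sum: list[np.ndarray] | None = None
    tail_n = 0
    for epoch in range(config.epochs):
        if config.lr_decay:
            factor = 1.0
            if epoch >= int(config.epochs * 0.85):
                factor = 0.1
            elif epoch >= int(config.epochs * 0.6):
                factor = 1 / 3
            optimizer.spec = nn.AdamSpec(
                learning_rate=config.learning_rate * factor,
                beta1=config.beta1,
                beta2=config.beta2,
            )
        perm = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            batch = _augment_batch(x[idx], config, rng)
            logits = network.forward(batch, train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            network.backward(dlogits)
            optimizer.step(network.params())
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            logits = network.forward(x[val_idx])
            val_loss, _ = nn.softmax_cross_entropy(logits, y[val_idx])
            history["val_loss"].append(val_loss)
        if config.tail_averaging and epoch >= tail_start:
            snapshot = [theta.copy() for theta, _ in network.params()]
            if tail_sum is None:
                tail_sum = snapshot
            else:
                for acc, s in zip(tail_sum, snapshot):
                    acc += s
            tail_n += 1
    if tail_sum is not None:
        for (theta, _), acc in zip(network.params(), tail_sum):
            theta[...] = acc / tail_n
    return TrainedModel(
        network=network,
        class_names=tuple(class_names),
        config=config,
        history=history,
        data_fingerprint=_fingerprint(x, y),
        arch=arch or {},
    )


# ---------------------------------------------------------------------------
# level-specific preprocessing


def preprocess_parent_inputs(
    images: np.ndarray, slide_ids: np.ndarray | None = None
) -> np.ndarray:
    """Color-balance patches with estimated illuminant gains.

    With ``slide_ids`` the white point is estimated once per slide from
    the mosaic of that slide's patches (slides always contain background,
    single tissue patches may not), and applied to each of its patches.
    """
    images = np.asarray(images)
    if slide_ids is None:
        return np.stack(
            [color_balance(img, estimate_balance_spec(img)) for img in images]
        )
    out = np.empty_like(images)
    slide_ids = np.asarray(slide_ids)
    for slide in np.unique(slide_ids):
        idx = np.flatnonzero(slide_ids == slide)
        mosaic = images[idx].reshape(-1, *images.shape[2:])
        spec = estimate_balance_spec(mosaic)
        for i in idx:
            out[i] = color_balance(images[i], spec)
    return out


def od_representation(images: np.ndarray) -> np.ndarray:
    """Optical-density input encoding, scaled to roughly [0, 1].

    Stains combine linearly in OD space, so in this encoding stain
    amount is a linear feature of the input — one conv + ReLU suffices
    to extract thresholded stain density, which intensity-space inputs
    can only approximate.  Both classifier levels consume this encoding
    (after their respective color balancing / stain normalization).
    """
    x = _as_float_images(images)
    return np.clip(-np.log(np.clip(x, 1e-3, 1.0)) / 2.0, 0.0, 1.0).astype(
        np.float32
    )


def preprocess_child_inputs(
    images: np.ndarray,
    slide_ids: np.ndarray,
    target_model: StainNormalizationModel,
    seed: int = 0,
) -> np.ndarray:
    """Stain-normalize patches to the target profile, per source slide.

    One stain model is fitted per slide on a mosaic of that slide's
    patches, then each patch is re-rendered with the target stain matrix
    and concentration scale.  Slides without enough tissue fall back to
    the target model (no-op normalization of near-empty content).
    """
    images = np.asarray(images)
    out = np.empty_like(images)
    for slide in np.unique(slide_ids):
        idx = np.flatnonzero(slide_ids == slide)
        mosaic = images[idx].reshape(-1, *images.shape[2:])
        try:
            source = fit_stain_model(mosaic, seed=seed)
        except ValueError:
            source = target_model
        for i in idx:
            out[i] = normalize_stain(images[i], source, target_model)
    return out


def fit_target_stain_model(
    patch_frame: pd.DataFrame, parent: str = "CD", seed: int = 0
) -> StainNormalizationModel:
    """Default stain target: fitted on the first training slide (by id)
    of ``parent``."""
    rows = patch_frame[
        (patch_frame.parent_label == parent) & (patch_frame.split == "train")
    ]
    if len(rows) == 0:
        raise ValueError(f"no training patches of parent {parent!r}")
    first = sorted(rows.slide_id.unique())[0]
    images = load_patch_images(rows[rows.slide_id == first])
    return fit_stain_model(images.reshape(-1, *images.shape[2:]), seed=seed)


# ---------------------------------------------------------------------------
# hierarchical model


@dataclass
class HierarchicalModel:
    """Parent classifier plus one child classifier per parent with children."""

    parent: TrainedModel
    children: dict[str, TrainedModel]
    taxonomy: ClassTaxonomy
    stain_targets: dict[str, StainNormalizationModel] = field(default_factory=dict)
    training_set_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for parent_name, model in self.children.items():
            if model.class_names != self.taxonomy.children(parent_name):
                raise ValueError(
                    f"child model label space {model.class_names} does not match "
                    f"taxonomy children of {parent_name!r}"
                )


def train_hierarchical(
    patch_frame: pd.DataFrame,
    taxonomy: ClassTaxonomy | None = None,
    config: TrainingConfig = WORKING_PARENT_CONFIG,
    arch_spec: CNNArchitectureSpec = WORKING_SPEC,
    images: np.ndarray | None = None,
    child_config: TrainingConfig | None = None,
) -> HierarchicalModel:
    """Train the parent model and every needed child model.

    The parent model sees color-balanced versions of all training patches
    labeled {Normal, EE, CD}; each child model sees stain-normalized
    versions of only its parent's patches, labeled with the child classes.
    Patches are resized to the architecture's input size.  Expects a
    (possibly filtered) patch manifest; rows with ``retained == 0`` are
    excluded if a ``retained`` column is present.  ``child_config``
    defaults to the parent ``config`` with more epochs when unset (the
    severity task needs longer training than the parent task).
    """
    taxonomy = taxonomy or build_default_taxonomy()
    if child_config is None:
        child_config = replace(config, epochs=2 * config.epochs)
    frame = patch_frame[patch_frame.split == "train"]
    if "retained" in frame.columns:
        frame = frame[frame.retained == 1]
    frame = frame.reset_index(drop=True)
    missing = set(taxonomy.parent_classes) - set(frame.parent_label)
    if missing:
        raise ValueError(f"training patches missing parent classes: {missing}")
    if images is None:
        images = load_patch_images(frame)

    parent_y = np.array(
        [taxonomy.parent_index(p) for p in frame.parent_label], dtype=int
    )
    parent_x = resize_images(
        od_representation(
            preprocess_parent_inputs(images, frame.slide_id.to_numpy())
        ),
        arch_spec.input_size,
    )
    parent_net = build_cnn(arch_spec, taxonomy.n_parents, seed=config.seed)
    parent_model = train_model(
        parent_net,
        parent_x,
        parent_y,
        taxonomy.parent_classes,
        config,
        arch={"kind": "dcnn", **asdict(arch_spec)},
    )
    sizes = {"parent": len(parent_x)}

    children: dict[str, TrainedModel] = {}
    stain_targets: dict[str, StainNormalizationModel] = {}
    for parent_name in taxonomy.parent_classes:
        kids = taxonomy.children(parent_name)
        if not kids:
            continue
        sub = frame[frame.parent_label == parent_name].reset_index(drop=True)
        if len(sub) == 0 or (sub.child_label == "").any():
            raise ValueError(
                f"parent {parent_name!r} has children but lacks child-labeled "
                "training patches"
            )
        sub_images = images[
            frame.index[frame.parent_label == parent_name].to_numpy()
        ]
        target = fit_target_stain_model(patch_frame, parent_name, seed=config.seed)
        child_x = resize_images(
            od_representation(
                preprocess_child_inputs(
                    sub_images, sub.slide_id.to_numpy(), target, seed=config.seed
                )
            ),
            arch_spec.input_size,
        )
        child_y = np.array(
            [taxonomy.child_index(parent_name, c) for c in sub.child_label],
            dtype=int,
        )
        child_net = build_cnn(arch_spec, len(kids), seed=config.seed + 1)
        children[parent_name] = train_model(
            child_net,
            child_x,
            child_y,
            kids,
            child_config,
            arch={"kind": "dcnn", **asdict(arch_spec)},
        )
        stain_targets[parent_name] = target
        sizes[f"child:{parent_name}"] = len(child_x)

    return HierarchicalModel(
        parent=parent_model,
        children=children,
        taxonomy=taxonomy,
        stain_targets=stain_targets,
        training_set_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# serialization (npz weights + json sidecar)


def _rebuild_network(arch: dict, n_classes: int, input_size: int) -> nn.Sequential:
    kind = arch.get("kind", "dcnn")
    if kind == "dcnn":
        fields = {k: v for k, v in arch.items() if k != "kind"}
        fields["conv_filters"] = tuple(fields.get("conv_filters", (32, 32, 64)))
        fields["pools"] = tuple(fields.get("pools", (5, 5, 8)))
        return build_cnn(CNNArchitectureSpec(**fields), n_classes)
    return build_baseline(kind, n_classes, input_size)


def save_model(model: TrainedModel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(f"{prefix}.npz", **model.network.state_arrays())
    sidecar = {
        "class_names": list(model.class_names),
        "config": asdict(model.config),
        "history": model.history,
        "data_fingerprint": model.data_fingerprint,
        "arch": model.arch,
        "input_shape": list(model.network.input_shape),
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def save_hierarchical(model: HierarchicalModel, out_dir: str | Path) -> None:
    """Persist a hierarchical model as a directory of checkpoints."""
    from .stain import save_stain_model

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_model(model.parent, out_dir / "parent")
    for name, child in model.children.items():
        save_model(child, out_dir / f"child_{name}")
        save_stain_model(model.stain_targets[name], out_dir / f"stain_{name}.json")
    meta = {
        "parent_classes": list(model.taxonomy.parent_classes),
        "child_map": {k: list(v) for k, v in model.taxonomy.child_map.items()},
        "training_set_sizes": model.training_set_sizes,
    }
    (out_dir / "hierarchy.json").write_text(json.dumps(meta, indent=2))


def load_hierarchical(out_dir: str | Path) -> HierarchicalModel:
    from .stain import load_stain_model

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "hierarchy.json").read_text())
    taxonomy = ClassTaxonomy(
        parent_classes=tuple(meta["parent_classes"]),
        child_map={k: tuple(v) for k, v in meta["child_map"].items()},
    )
    children = {}
    stain_targets = {}
    for parent_name in taxonomy.parent_classes:
        if taxonomy.children(parent_name) and (
            out_dir / f"child_{parent_name}.json"
        ).exists():
            children[parent_name] = load_model(out_dir / f"child_{parent_name}")
            stain_targets[parent_name] = load_stain_model(
                out_dir / f"stain_{parent_name}.json"
            )
    return HierarchicalModel(
        parent=load_model(out_dir / "parent"),
        children=children,
        taxonomy=taxonomy,
        stain_targets=stain_targets,
        training_set_sizes=meta.get("training_set_sizes", {}),
    )


def load_model(prefix: str | Path) -> TrainedModel:
    sidecar = json.loads(Path(f"{prefix}.json").read_text())
    input_size = sidecar["input_shape"][0]
    network = _rebuild_network(
        sidecar["arch"], len(sidecar["class_names"]), input_size
    )
    with np.load(f"{prefix}.npz") as arrays:
        network.load_state_arrays(dict(arrays))
    return TrainedModel(
        network=network,
        class_names=tuple(sidecar["class_names"]),
        config=TrainingConfig(**sidecar["config"]),
        history=sidecar["history"],
        data_fingerprint=sidecar["data_fingerprint"],
        arch=sidecar["arch"],
    )
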