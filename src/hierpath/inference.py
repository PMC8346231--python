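"""Patch-level MAP labeling and whole-slide aggregation.

A trained patch model yields, for patch ``j`` of slide ``i``, a
probability vector ``p(y_ij = c | x_ij, D)`` over the C classes.  The
patch's MAP label is its argmax; the slide's label is the argmax of the
component-wise sum of all its patch vectors (equivalently of the
normalized sum).  For a hierarchical model the parent label is decided
first; if that parent has a child model, the same retained patches are
pushed through it and aggregated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    HierarchicalModel,
    od_representation,
    preprocess_child_inputs,
    preprocess_parent_inputs,
)

_TOL = 1e-6


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    if np.any(probs < -_TOL) or abs(probs.sum(axis=-1).max() - 1) > 1e-3:
        raise ValueError("input is not a normalized probability vector")
    return probs


def patch_map(probs: np.ndarray) -> int:
    """MAP class index of one probability vector (ties -> lowest index)."""
    probs = _check_probs(probs)
    if probs.ndim != 1:
        raise ValueError("patch_map expects a single vector")
    return int(np.argmax(probs))


@dataclass
class PatchPrediction:
    slide_id: str
    patch_index: int
    probabilities: np.ndarray
    label: int


@dataclass
class SlidePrediction:
    slide_id: str
    n_patches: int
    probabilities: np.ndarray  # normalized aggregate over patches
    label: int
    child_probabilities: np.ndarray | None = None
    child_label: int | None = None


def aggregate_slide(
    patch_probs: np.ndarray, slide_id: str = ""
) -> SlidePrediction:
    """Sum patch probability vectors, normalize, label by argmax."""
    patch_probs = np.asarray(patch_probs, dtype=np.float64)
    if patch_probs.ndim != 2 or len(patch_probs) == 0:
        raise ValueError("expected a non-empty (N, C) array of patch vectors")
    _check_probs(patch_probs)
    total = patch_probs.sum(axis=0)
    return SlidePrediction(
        slide_id=slide_id,
        n_patches=len(patch_probs),
        probabilities=total / total.sum(),
        label=int(np.argmax(total)),
    )


def classify_slide_hierarchical(
    hmodel: HierarchicalModel,
    patches: np.ndarray,
    slide_id: str = "",
) -> SlidePrediction:
    """Hierarchical whole-slide inference over a slide's retained patches.

    ``patches`` are raw RGB tiles that survived filtering; the level-
    appropriate stain preprocessing (color balancing for the parent
    model, stain normalization for a child model) is applied here.
    """
    patches = np.asarray(patches)
    if len(patches) == 0:
        raise ValueError(f"slide {slide_id!r} has no retained patches")
    parent_x = od_representation(
        preprocess_parent_inputs(patches, np.array([slide_id] * len(patches)))
    )
    parent_probs = hmodel.parent.predict_proba(parent_x)
    slide = aggregate_slide(parent_probs, slide_id)
    parent_name = hmodel.taxonomy.parent_classes[slide.label]
    child_model = hmodel.children.get(parent_name)
    if child_model is not None:
        target = hmodel.stain_targets[parent_name]
        child_x = od_representation(
            preprocess_child_inputs(
                patches, np.array([slide_id] * len(patches)), target
            )
        )
        child_probs = child_model.predict_proba(child_x)
        child_slide = aggregate_slide(child_probs, slide_id)
        slide.child_probabilities = child_slide.probabilities
        slide.child_label = child_slide.label
    return slide


def classify_patches_hierarchical(
    hmodel: HierarchicalModel,
    patches: np.ndarray,
    slide_ids: np.ndarray,
) -> pd.DataFrame:
    """Per-patch hierarchical (leaf-level) prediction.

    Each patch gets a parent MAP label; patches whose parent has a child
    model are additionally pushed through it (stain-normalized per source
    slide) and receive that child's MAP as their leaf label.
    """
    patches = np.asarray(patches)
    taxonomy = hmodel.taxonomy
    parent_probs = hmodel.parent.predict_proba(
        od_representation(preprocess_parent_inputs(patches, slide_ids))
    )
    parent_idx = parent_probs.argmax(axis=1)
    leaf_names = list(taxonomy.leaf_classes)
    leaf_pred = []
    child_maps: dict[str, np.ndarray] = {}
    for parent_name, child_model in hmodel.children.items():
        sel = parent_idx == taxonomy.parent_index(parent_name)
        if not np.any(sel):
            continue
        child_x = od_representation(
            preprocess_child_inputs(
                patches[sel],
                np.asarray(slide_ids)[sel],
                hmodel.stain_targets[parent_name],
            )
        )
        child_maps[parent_name] = child_model.predict_proba(child_x).argmax(axis=1)
    counters = {name: 0 for name in child_maps}
    for i, p_idx in enumerate(parent_idx):
        parent_name = taxonomy.parent_classes[p_idx]
        if parent_name in child_maps:
            c_idx = child_maps[parent_name][counters[parent_name]]
            counters[parent_name] += 1
            leaf = taxonomy.children(parent_name)[c_idx]
        else:
            leaf = parent_name
        leaf_pred.append(leaf)
    return pd.DataFrame(
        {
            "slide_id": slide_ids,
            "parent_pred": [taxonomy.parent_classes[i] for i in parent_idx],
            "leaf_pred": leaf_pred,
            "leaf_index": [leaf_names.index(leaf) for leaf in leaf_pred],
        }
    )


def predict_dataset(
    hmodel: HierarchicalModel,
    patch_frame: pd.DataFrame,
    split: str = "test",
    images: np.ndarray | None = None,
) -> pd.DataFrame:
    """Slide-level hierarchical predictions for one split of a (filtered)
    patch manifest; returns one row per slide with truth and prediction."""
    from .patching import load_patch_images

    frame = patch_frame[patch_frame.split == split]
    if "retained" in frame.columns:
        frame = frame[frame.retained == 1]
    frame = frame.reset_index(drop=True)
    if images is None:
        images = load_patch_images(frame)
    taxonomy = hmodel.taxonomy
    rows = []
    for slide_id in sorted(frame.slide_id.unique()):
        idx = np.flatnonzero((frame.slide_id == slide_id).to_numpy())
        pred = classify_slide_hierarchical(hmodel, images[idx], slide_id)
        sub = frame.iloc[idx[0]]
        parent_pred = taxonomy.parent_classes[pred.label]
        child_pred = (
            taxonomy.children(parent_pred)[pred.child_label]
            if pred.child_label is not None
            else ""
        )
        child_true = sub.child_label or ""
        rows.append(
            {
                "slide_id": slide_id,
                "n_patches": pred.n_patches,
                "parent_true": sub.parent_label,
                "child_true": child_true,
                "parent_pred": parent_pred,
                "child_pred": child_pred,
                "leaf_true": child_true or sub.parent_label,
                "leaf_pred": child_pred or parent_pred,
                **{
                    f"p_{c}": pred.probabilities[i]
                    for i, c in enumerate(taxonomy.parent_classes)
                },
            }
        )
    return pd.DataFrame(rows)


def predictions_frame(
    patch_preds: list[PatchPrediction],
    slide_preds: list[SlidePrediction],
    class_names: tuple[str, ...],
) -> pd.DataFrame:
    """Long-format predictions table (patch rows + slide rows)."""
    prob_cols = [f"p_{c}" for c in class_names]
    rows = []
    for p in patch_preds:
        rows.append(
            [p.slide_id, p.patch_index, "patch", *p.probabilities,
             class_names[p.label]]
        )
    for s in slide_preds:
        rows.append([s.slide_id, "", "slide", *s.probabilities,
                     class_names[s.label]])
    return pd.DataFrame(
        rows,
        columns=["slide_id", "patch_index", "level", *prob_cols, "predicted_label"],
    )
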