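"""Train the two-level classifier on a small synthetic dataset.

Parent CNN: Normal vs EE vs CD on color-balanced patches.
Child CNN: Marsh severity I/IIIa/IIIb/IIIc on stain-normalized CD patches.
Sizes here are kept small so the script runs in about two minutes; the
accuracy-grade configuration used by scripts/acceptance.py trains longer
on more slides.
"""

import tempfile
from pathlib import Path

import numpy as np

from hierpath.filtering import AutoencoderSpec, filter_patches
from hierpath.models import (
    WORKING_CHILD_CONFIG, WORKING_PARENT_CONFIG, replace, train_hierarchical,
)
from hierpath.patching import load_patch_images, patch_dataset
from hierpath.inference import predict_dataset
from hierpath.synthetic import generate_dataset

root = Path(tempfile.mkdtemp())
manifest = generate_dataset(3, root / "slides", slide_size=400,
                            background_fraction=0.25, seed=2)
frame = patch_dataset(manifest, 200, root / "patches")
filtered, _, _ = filter_patches(frame, AutoencoderSpec(), seed=0, epochs=3)
print(f"{len(manifest)} slides -> {len(frame)} patches -> "
      f"{int(filtered.retained.sum())} retained after filtering")

hmodel = train_hierarchical(
    filtered,
    config=replace(WORKING_PARENT_CONFIG, epochs=10),
    child_config=replace(WORKING_CHILD_CONFIG, epochs=15),
)
print("training-set sizes:", hmodel.training_set_sizes)
print(f"parent loss {hmodel.parent.history['train_loss'][0]:.2f} -> "
      f"{hmodel.parent.history['train_loss'][-1]:.2f}")

preds = predict_dataset(hmodel, filtered)
correct = np.mean(preds.parent_pred == preds.parent_true)
print(preds[["slide_id", "parent_true", "parent_pred", "child_true", "child_pred"]]
      .to_string(index=False))
print(f"slide-level parent accuracy on the test split: {correct:.2f}")
print("(Short training: severity predictions improve with the full recipe.)")
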