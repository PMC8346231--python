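"""Tile a slide and separate informative from background patches.

A convolutional autoencoder embeds each tile; 2-means clustering on the
embeddings splits tiles into a textured (tissue) and a near-uniform
(background) group, and the textured cluster is retained.
"""

import numpy as np
import pandas as pd

from hierpath.filtering import AutoencoderSpec, filter_patches
from hierpath.patching import tile_slide
from hierpath.synthetic import SyntheticSlideSpec, generate_slide

slide = generate_slide(
    SyntheticSlideSpec(
        parent_class="CD", child_class="IIIb",
        slide_size=600, background_fraction=0.5, seed=4,
    )
)
patches = tile_slide(slide.image, 200, slide_labels=("CD", "IIIb"), slide_id="demo")
images = np.stack([p.image for p in patches])
frame = pd.DataFrame(
    {
        "slide_id": "demo", "patch_index": range(len(patches)),
        "row": [p.row for p in patches], "col": [p.col for p in patches],
        "parent_label": "CD", "child_label": "IIIb", "split": "train", "path": "",
    }
)
out, model, clustering = filter_patches(frame, AutoencoderSpec(), seed=0, epochs=5,
                                        images=images)
print(f"autoencoder reconstruction MSE: {model.history[0]:.4f} -> {model.history[-1]:.4f}")
print(f"cluster sizes: {clustering.cluster_sizes.tolist()}")
for row, patch in zip(out.itertuples(), patches):
    coverage = slide.tissue_mask[patch.row:patch.row+200, patch.col:patch.col+200].mean()
    print(f"  patch ({patch.row:3d},{patch.col:3d}) tissue={coverage:.2f} "
          f"retained={row.retained}")
print("Fully textured tiles are retained; background-dominated tiles are")
print("discarded before any classifier sees them.")
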