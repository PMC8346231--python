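import warnings

import numpy as np
import pytest

from hierpath.patching import tile_slide
from hierpath.synthetic import SyntheticSlideSpec, generate_slide
from hierpath.taxonomy import build_default_taxonomy

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def taxonomy():
    return build_default_taxonomy()


@pytest.fixture(scope="session")
def small_slides():
    """One 600-pixel slide per leaf class, 50% background, fixed seeds."""
    slides = {}
    for parent, child in [
        ("Normal", None),
        ("EE", None),
        ("CD", "I"),
        ("CD", "IIIa"),
        ("CD", "IIIb"),
        ("CD", "IIIc"),
    ]:
        spec = SyntheticSlideSpec(
            parent_class=parent,
            child_class=child,
            slide_size=600,
            background_fraction=0.5,
            seed=97,
        )
        slides[(parent, child)] = generate_slide(spec)
    return slides


@pytest.fixture(scope="session")
def background_and_tissue_patches(small_slides):
    """Labeled 200-pixel patches split into pure background / tissue by the
    generator's tissue mask (coverage < 5% counts as background)."""
    backgrounds, tissues = [], []
    for slide in small_slides.values():
        for patch in tile_slide(slide.image, 200):
            coverage = slide.tissue_mask[
                patch.row : patch.row + 200, patch.col : patch.col + 200
            ].mean()
            if coverage < 0.05:
                backgrounds.append(patch.image)
            elif coverage > 0.95:
                tissues.append(patch.image)
    return np.stack(backgrounds), np.stack(tissues)
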