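"""Generate a small synthetic slide dataset and inspect its class signals.

Builds one slide per diagnostic leaf class, reports the realized
background fraction and the stain-balance statistic that separates the
parent classes (hematoxylin share of the stain mix: low for Normal,
intermediate for Celiac, high for the inflammation-dense EE class).
"""

from hierpath.synthetic import (
    SyntheticSlideSpec,
    generate_slide,
    hematoxylin_fraction,
)

for parent, child in [
    ("Normal", None), ("EE", None),
    ("CD", "I"), ("CD", "IIIa"), ("CD", "IIIb"), ("CD", "IIIc"),
]:
    spec = SyntheticSlideSpec(
        parent_class=parent, child_class=child,
        slide_size=600, background_fraction=0.4, seed=1,
    )
    slide = generate_slide(spec)
    white = (slide.image.min(axis=2) > 235).mean()
    tissue = slide.image[:, : int(600 * 0.6)]
    label = child or parent
    print(
        f"{label:>5}: background {white:.2f}, "
        f"hematoxylin fraction {hematoxylin_fraction(tissue):.3f}"
    )
print()
print("Hematoxylin fraction rises Normal < CD < EE; within CD it rises")
print("with Marsh severity as nuclear-dot density increases.")
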