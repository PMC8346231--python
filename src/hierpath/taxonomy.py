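"""Two-level label taxonomy for duodenal biopsy classification.

The parent level separates histologically Normal tissue, Environmental
Enteropathy (EE) and Celiac Disease (CD).  CD carries a child level of
modified-Marsh severity grades (I, IIIa, IIIb, IIIc); the other parents
have no children.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ClassTaxonomy:
    """Ordered two-level label space.

    Parameters
    ----------
    parent_classes
        Ordered parent class names; must be unique.
    child_map
        Maps a parent name to its ordered child names (possibly empty).
        Parents absent from the map have no children.
    """

    parent_classes: tuple[str, ...]
    child_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.parent_classes)) != len(self.parent_classes):
            raise ValueError("parent class names must be unique")
        for parent, children in self.child_map.items():
            if parent not in self.parent_classes:
                raise ValueError(f"child_map key {parent!r} is not a parent class")
            if len(set(children)) != len(children):
                raise ValueError(f"child names under {parent!r} must be unique")

    @property
    def n_parents(self) -> int:
        """Number of parent classes (the output width of the parent model)."""
        return len(self.parent_classes)

    def children(self, parent: str) -> tuple[str, ...]:
        if parent not in self.parent_classes:
            raise KeyError(f"unknown parent class {parent!r}")
        return self.child_map.get(parent, ())

    def n_children(self, parent: str) -> int:
        """Child class count for ``parent`` (0 when it has no child level)."""
        return len(self.children(parent))

    def parent_index(self, parent: str) -> int:
        return self.parent_classes.index(parent)

    def child_index(self, parent: str, child: str) -> int:
        return self.children(parent).index(child)

    @property
    def leaf_classes(self) -> tuple[str, ...]:
        """Flattened leaves: childless parents plus every child class."""
        leaves: list[str] = []
        for parent in self.parent_classes:
            kids = self.children(parent)
            leaves.extend(kids if kids else (parent,))
        return tuple(leaves)

    def leaf_of(self, parent: str, child: str | None) -> str:
        """Leaf name for a (parent, child) label pair."""
        kids = self.children(parent)
        if kids:
            if child is None or child not in kids:
                raise ValueError(f"parent {parent!r} requires a child in {kids}")
            return child
        if child is not None:
            raise ValueError(f"parent {parent!r} has no child classes")
        return parent


def build_default_taxonomy() -> ClassTaxonomy:
    """The default biopsy taxonomy: 3 parents, CD split into 4 Marsh grades."""
    return ClassTaxonomy(
        parent_classes=("Normal", "EE", "CD"),
        child_map={"CD": ("I", "IIIa", "IIIb", "IIIc")},
    )
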