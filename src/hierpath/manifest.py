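"""Dataset manifest: slide records, CSV round-trip and consistency checks."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .taxonomy import ClassTaxonomy

MANIFEST_COLUMNS = ["slide_id", "image_path", "parent_label", "child_label", "split"]
SPLITS = ("train", "test")


@dataclass(frozen=True)
class SlideRecord:
    slide_id: str
    image_path: str
    parent_label: str
    child_label: str | None
    split: str


@dataclass
class DatasetManifest:
    """Slide-level dataset listing.

    ``patch_counts`` maps ``(class_name, split) -> n_patches`` and is filled
    downstream by the patching stage; it is not serialized with the records.
    """

    records: list[SlideRecord] = field(default_factory=list)
    patch_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def slides(self, split: str | None = None) -> list[SlideRecord]:
        return [r for r in self.records if split is None or r.split == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.slide_id, r.image_path, r.parent_label, r.child_label or "", r.split)
                for r in self.records
            ],
            columns=MANIFEST_COLUMNS,
        )


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[str, ...]

    @property
    def is_valid(self) -> bool:
        return not self.issues


def _check_record(record: SlideRecord, taxonomy: ClassTaxonomy) -> None:
    if record.parent_label not in taxonomy.parent_classes:
        raise ValueError(
            f"slide {record.slide_id!r}: unknown parent label {record.parent_label!r}"
        )
    children = taxonomy.children(record.parent_label)
    if record.child_label is not None and record.child_label not in children:
        raise ValueError(
            f"slide {record.slide_id!r}: child label {record.child_label!r} "
            f"is not valid under parent {record.parent_label!r}"
        )
    if record.split not in SPLITS:
        raise ValueError(f"slide {record.slide_id!r}: unknown split {record.split!r}")


def build_manifest(
    records: list[SlideRecord], taxonomy: ClassTaxonomy
) -> DatasetManifest:
    """Validate records against the taxonomy and assemble a manifest."""
    seen: set[str] = set()
    for record in records:
        _check_record(record, taxonomy)
        if record.slide_id in seen:
            raise ValueError(f"duplicate slide_id {record.slide_id!r}")
        seen.add(record.slide_id)
    return DatasetManifest(records=list(records))


def validate_manifest(
    manifest: DatasetManifest,
    taxonomy: ClassTaxonomy,
    counts: dict[tuple[str, str], int] | None = None,
) -> ValidationReport:
    """Consistency report for a manifest and optional per-class patch counts.

    Problems are reported, not raised.  For every parent with children and
    every split present in ``counts``, the parent-level count must equal the
    sum of its child-level counts (a CD slide contributes the same patches to
    the parent set and to the child set, so the totals must agree).
    """
    issues: list[str] = []
    seen: set[str] = set()
    for record in manifest.records:
        try:
            _check_record(record, taxonomy)
        except ValueError as exc:
            issues.append(str(exc))
        if record.slide_id in seen:
            issues.append(f"duplicate slide_id {record.slide_id!r}")
        seen.add(record.slide_id)

    counts = counts if counts is not None else manifest.patch_counts
    known = set(taxonomy.parent_classes)
    for parent in taxonomy.parent_classes:
        known.update(taxonomy.children(parent))
    for (name, split), n in counts.items():
        if name not in known:
            issues.append(f"patch count for unknown class {name!r}")
        if split not in SPLITS:
            issues.append(f"patch count for unknown split {split!r}")
        if n < 0:
            issues.append(f"negative patch count for ({name!r}, {split!r})")

    for parent in taxonomy.parent_classes:
        children = taxonomy.children(parent)
        if not children:
            continue
        for split in SPLITS:
            if (parent, split) not in counts:
                continue
            child_counts = [counts.get((c, split)) for c in children]
            if any(c is None for c in child_counts):
                continue
            total = sum(child_counts)  # type: ignore[arg-type]
            if total != counts[(parent, split)]:
                issues.append(
                    f"{parent} {split} count {counts[(parent, split)]} != "
                    f"sum of child counts {total}"
                )
    return ValidationReport(issues=tuple(issues))


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def read_manifest(path: str | Path, taxonomy: ClassTaxonomy) -> DatasetManifest:
    """Read a manifest CSV, raising on structural or taxonomy violations."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    records = [
        SlideRecord(
            slide_id=row.slide_id,
            image_path=row.image_path,
            parent_label=row.parent_label,
            child_label=row.child_label or None,
            split=row.split,
        )
        for row in frame.itertuples()
    ]
    return build_manifest(records, taxonomy)
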