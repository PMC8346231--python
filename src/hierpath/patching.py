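"""Tile slide images into fixed-size labeled patches.

Whole slides are too large to classify directly, so each slide is cut
into square tiles on a regular grid; every tile inherits the slide's
labels.  Tiling is row-major with a 0-based top-left origin; partial
edge windows are dropped rather than padded, so the patch count obeys
``floor((H - patch)/stride + 1) * floor((W - patch)/stride + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .manifest import DatasetManifest
from .taxonomy import ClassTaxonomy, build_default_taxonomy

PATCH_MANIFEST_COLUMNS = [
    "slide_id",
    "patch_index",
    "row",
    "col",
    "parent_label",
    "child_label",
    "split",
    "path",
]


@dataclass
class Patch:
    slide_id: str
    patch_index: int
    row: int
    col: int
    image: np.ndarray
    parent_label: str
    child_label: str | None


def read_slide_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF slide image as an RGB uint8 array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3]


def tile_slide(
    image: np.ndarray,
    patch_size: int,
    stride: int | None = None,
    slide_labels: tuple[str, str | None] = ("", None),
    slide_id: str = "",
) -> list[Patch]:
    """Enumerate all full patch windows of ``image`` in row-major order."""
    if patch_size < 1 or (stride is not None and stride < 1):
        raise ValueError("patch size and stride must be >= 1")
    stride = stride if stride is not None else patch_size
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {h}x{w} is smaller than the patch size {patch_size}"
        )
    parent_label, child_label = slide_labels
    patches = []
    index = 0
    for row in range(0, h - patch_size + 1, stride):
        for col in range(0, w - patch_size + 1, stride):
            patches.append(
                Patch(
                    slide_id=slide_id,
                    patch_index=index,
                    row=row,
                    col=col,
                    image=image[row : row + patch_size, col : col + patch_size],
                    parent_label=parent_label,
                    child_label=child_label,
                )
            )
            index += 1
    return patches


def expected_patch_count(h: int, w: int, patch_size: int, stride: int) -> int:
    """Closed-form tile count for an H x W image (partials dropped)."""
    if h < patch_size or w < patch_size:
        return 0
    return ((h - patch_size) // stride + 1) * ((w - patch_size) // stride + 1)


def patch_dataset(
    manifest: DatasetManifest,
    patch_size: int,
    out_dir: str | Path,
    stride: int | None = None,
    taxonomy: ClassTaxonomy | None = None,
) -> pd.DataFrame:
    """Tile every slide in the manifest, writing patch PNGs and a patch
    manifest; also fills the manifest's per-class patch counts.

    Patch files are named ``{slide_id}__{row}_{col}.png`` so reruns
    produce an identical file set.
    """
    taxonomy = taxonomy or build_default_taxonomy()
    stride = stride if stride is not None else patch_size
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counts: dict[tuple[str, str], int] = {}
    for record in manifest.records:
        image = read_slide_image(record.image_path)
        patches = tile_slide(
            image,
            patch_size,
            stride,
            slide_labels=(record.parent_label, record.child_label),
            slide_id=record.slide_id,
        )
        for patch in patches:
            path = out_dir / f"{record.slide_id}__{patch.row}_{patch.col}.png"
            iio.imwrite(path, patch.image)
            rows.append(
                (
                    record.slide_id,
                    patch.patch_index,
                    patch.row,
                    patch.col,
                    record.parent_label,
                    record.child_label or "",
                    record.split,
                    str(path),
                )
            )
        n = len(patches)
        key = (record.parent_label, record.split)
        counts[key] = counts.get(key, 0) + n
        if record.child_label is not None:
            ckey = (record.child_label, record.split)
            counts[ckey] = counts.get(ckey, 0) + n
    manifest.patch_counts = counts
    frame = pd.DataFrame(rows, columns=PATCH_MANIFEST_COLUMNS)
    frame.to_csv(out_dir / "patches.csv", index=False)
    return frame


def read_patch_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"child_label": str}, keep_default_na=False)
    missing = [c for c in PATCH_MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"patch manifest missing columns: {missing}")
    return frame


def load_patch_images(frame: pd.DataFrame) -> np.ndarray:
    """Stack the patch images of a patch-manifest frame (N, H, W, 3) uint8."""
    return np.stack([read_slide_image(p) for p in frame["path"]])
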