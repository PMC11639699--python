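"""Dataset preprocessing, loading and cross-validation splitting.

Preprocessing follows the nnU-Net-style convention: every image is resized
to a uniform target size (bilinear) and saved as lossless PNG under
``imagesTr/`` with the ``_0000`` channel suffix; the paired mask is resized
nearest-neighbor (preserving binarity), collapsed to one channel, binarized
(any value > 0 maps to 1) and saved under ``labelsTr/`` without the suffix.
Dataset-unique IDs are assigned in sorted order of the source stems, so
re-running the preprocessor on its own output is a byte-identical no-op.

Coordinate convention (used by the whole package, including the metric
point sets): row-major, 0-based, pixel-center; images and masks share it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import ImageSample

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class FoldSplit:
    """Deterministic partition of sample ids into k near-equal folds."""

    assignments: dict  # id -> fold index

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.assignments.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.assignments.items() if f != fold)


def _find_pairs(src_dir: Path) -> tuple[list[tuple[str, Path, Path]], bool]:
    """Locate paired image/mask files; returns (stem, image, mask) triples."""
    for img_sub, msk_sub, nn_style in (
        ("imagesTr", "labelsTr", True),
        ("images", "masks", False),
    ):
        img_dir, msk_dir = src_dir / img_sub, src_dir / msk_sub
        if img_dir.is_dir() and msk_dir.is_dir():
            break
    else:
        raise FileNotFoundError(
            f"{src_dir} has neither images/masks nor imagesTr/labelsTr subdirectories"
        )
    images, masks = {}, {}
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() in IMAGE_EXTENSIONS:
            stem = p.stem
            if nn_style and stem.endswith("_0000"):
                stem = stem[:-5]
            images[stem] = p
    for p in sorted(msk_dir.iterdir()):
        if p.suffix.lower() in IMAGE_EXTENSIONS:
            masks[p.stem] = p
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unpaired image/mask stems: {orphans}")
    return [(s, images[s], masks[s]) for s in sorted(images)], nn_style


def load_mask(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """Load a mask PNG, optionally resize (nearest), binarize to {0,1}."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:  # collapse channels before binarizing
        arr = arr.max(axis=2)
    distinct = np.unique(arr)
    if distinct.size > 2:
        raise ValueError(
            f"mask {path} has {distinct.size} distinct values; expected a binary mask"
        )
    if size is not None and arr.shape != tuple(size):
        img = Image.fromarray(arr).resize((size[1], size[0]), Image.NEAREST)
        arr = np.asarray(img)
    return (arr > 0).astype(np.uint8)


def load_image(path, size: tuple[int, int] | None = None) -> np.ndarray:
    img = Image.open(path).convert("RGB")
    if size is not None and (img.height, img.width) != tuple(size):
        img = img.resize((size[1], size[0]), Image.BILINEAR)
    return np.asarray(img)


def preprocess_dataset(
    src_dir,
    dst_dir,
    target_size: tuple[int, int] = (512, 512),
    prefix: str = "CASE",
) -> list[dict]:
    """Resize, rename and binarize a paired dataset into nnU-Net layout.

    Returns the manifest (one row per case: id, image path, mask path),
    which is also written as ``dst_dir/manifest.csv``.
    """
    src_dir, dst_dir = Path(src_dir), Path(dst_dir)
    pairs, _ = _find_pairs(src_dir)
    width = max(3, len(str(max(len(pairs) - 1, 0))))
    img_out = dst_dir / "imagesTr"
    msk_out = dst_dir / "labelsTr"
    img_out.mkdir(parents=True, exist_ok=True)
    msk_out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (_stem, img_path, msk_path) in enumerate(pairs):
        case_id = f"{prefix}_{i:0{width}d}"
        image = load_image(img_path, target_size)
        mask = load_mask(msk_path, target_size)
        img_file = img_out / f"{case_id}_0000.png"
        msk_file = msk_out / f"{case_id}.png"
        Image.fromarray(image, mode="RGB").save(img_file)
        Image.fromarray(mask, mode="L").save(msk_file)
        manifest.append(
            {"id": case_id, "image": str(img_file.relative_to(dst_dir)),
             "mask": str(msk_file.relative_to(dst_dir))}
        )
    with (dst_dir / "manifest.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "image", "mask"])
        writer.writeheader()
        writer.writerows(manifest)
    return manifest


def load_preprocessed(dst_dir) -> list[ImageSample]:
    """Load a preprocessed dataset directory into memory."""
    dst_dir = Path(dst_dir)
    pairs, _ = _find_pairs(dst_dir)
    return [
        ImageSample(image=load_image(ip), mask=load_mask(mp), id=stem)
        for stem, ip, mp in pairs
    ]


def make_folds(ids: list[str], k: int = 5, seed: int = 0) -> FoldSplit:
    """Deterministic shuffled partition into k folds with sizes differing <= 1."""
    ids = list(ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} ids for {k} folds, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[j]: int(pos % k) for pos, j in enumerate(order)}
    return FoldSplit(assignments=assignments)
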