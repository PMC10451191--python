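"""Reading, writing and splitting image/mask segmentation datasets.

Datasets are pairs of single-channel grayscale raster images and
same-size integer label masks.  Label 0 is background; foreground
classes are 1..C.  Images are stored as 8- or 16-bit grayscale PNG and
scaled to [0, 1] on load; masks are 8-bit PNG holding the raw labels.
Masks are index maps, not colour images — colour is a visualization-only
output (:func:`colorize_mask`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import DataError

#: Visualization palette: background black; wall red, cavity green,
#: myoma blue, cyst yellow.
PALETTE = {
    0: (0, 0, 0),
    1: (255, 0, 0),
    2: (0, 255, 0),
    3: (0, 0, 255),
    4: (255, 255, 0),
}

IMAGE_EXTENSIONS = (".png", ".pgm")


@dataclass
class LabeledImage:
    """A grayscale image with its integer label mask (shared pixel grid).

    Coordinates are row-major, origin top-left, 0-based.
    """

    image: np.ndarray      # float (H, W) in [0, 1]
    mask: np.ndarray       # int (H, W) in {0..C}
    identifier: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise DataError(
                f"{self.identifier}: image shape {self.image.shape} != "
                f"mask shape {self.mask.shape}")


def _scale_to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise DataError(f"unsupported image dtype {arr.dtype} (want uint8/uint16)")


def load_dataset(images_dir, masks_dir, C: int) -> List[LabeledImage]:
    """Load all image/mask pairs, ordered by identifier (file stem).

    Every image must have a same-named mask; per-file problems are
    collected and reported together.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    stems = sorted(p.stem for p in images_dir.iterdir()
                   if p.suffix.lower() in IMAGE_EXTENSIONS) \
        if images_dir.is_dir() else []
    items, problems = [], []
    for stem in stems:
        img_path = next(p for p in (images_dir / f"{stem}{e}"
                                    for e in IMAGE_EXTENSIONS) if p.exists())
        mask_path = next((p for p in (masks_dir / f"{stem}{e}"
                                      for e in IMAGE_EXTENSIONS) if p.exists()),
                         None)
        if mask_path is None:
            problems.append(f"{stem}: missing mask in {masks_dir}")
            continue
        try:
            raw = np.asarray(iio.imread(img_path))
            if raw.ndim != 2:
                raise DataError(f"{stem}: image is not single-channel")
            image = _scale_to_unit(raw)
            mask = np.asarray(iio.imread(mask_path))
            if mask.ndim != 2:
                raise DataError(f"{stem}: mask is not single-channel")
            mask = mask.astype(np.int64)
            if mask.size and mask.max() > C:
                raise DataError(
                    f"{mask_path.name}: mask value {int(mask.max())} outside 0..{C}")
            items.append(LabeledImage(image, mask, stem))
        except DataError as e:
            problems.append(str(e))
    if problems:
        raise DataError("dataset errors:\n  " + "\n  ".join(problems))
    return items


def save_dataset(dataset: Sequence[LabeledImage], out_dir,
                 bit_depth: int = 8) -> None:
    """Write images/, masks/ and a manifest of pairs under ``out_dir``."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    lines = []
    for item in dataset:
        if bit_depth == 8:
            img = np.rint(np.clip(item.image, 0, 1) * 255).astype(np.uint8)
        elif bit_depth == 16:
            img = np.rint(np.clip(item.image, 0, 1) * 65535).astype(np.uint16)
        else:
            raise DataError("bit_depth must be 8 or 16")
        iio.imwrite(out_dir / "images" / f"{item.identifier}.png", img)
        iio.imwrite(out_dir / "masks" / f"{item.identifier}.png",
                    item.mask.astype(np.uint8))
        lines.append(f"{item.identifier},images/{item.identifier}.png,"
                     f"masks/{item.identifier}.png")
    (out_dir / "manifest.txt").write_text("\n".join(lines) + ("\n" if lines else ""))


def remove_background_only(dataset: Sequence[LabeledImage]) -> List[LabeledImage]:
    """Drop images whose mask has no foreground pixel; order preserved.

    Mirrors the study convention of filtering background-only images from
    the *training* split; callers decide which split to filter.
    """
    return [item for item in dataset if np.any(item.mask != 0)]


def split_dataset(dataset: Sequence[LabeledImage], val_fraction: float = 1 / 7,
                  seed: int = 0):
    """Seeded shuffle then floor-based cut into (train, val).

    ``n_val = floor(n * val_fraction)`` (at least 1); both outputs keep the
    original dataset order.  The default fraction 1/7 gives the ~6:1
    train:validation ratio customary for this kind of study data.
    """
    n = len(dataset)
    if n < 2:
        raise DataError("need at least 2 items to split")
    if not 0 < val_fraction < 1:
        raise DataError("val_fraction must be in (0, 1)")
    n_val = max(1, int(np.floor(n * val_fraction)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [dataset[i] for i in range(n) if i not in val_idx]
    val = [dataset[i] for i in range(n) if i in val_idx]
    return train, val


def colorize_mask(mask) -> np.ndarray:
    """Map labels 0..4 to the visualization palette; returns (H, W, 3) uint8."""
    mask = np.asarray(mask)
    if mask.size and (mask.min() < 0 or mask.max() > 4):
        bad = int(mask.min()) if mask.min() < 0 else int(mask.max())
        raise DataError(f"mask value {bad} outside the palette range 0..4")
    lut = np.zeros((5, 3), dtype=np.uint8)
    for label, rgb in PALETTE.items():
        lut[label] = rgb
    return lut[mask]


def labels_from_color(rgb) -> np.ndarray:
    """Inverse of :func:`colorize_mask` (palette colours only)."""
    rgb = np.asarray(rgb)
    out = np.full(rgb.shape[:2], -1, dtype=np.int64)
    for label, colour in PALETTE.items():
        out[np.all(rgb == np.array(colour, dtype=rgb.dtype), axis=-1)] = label
    if np.any(out < 0):
        raise DataError("image contains colours outside the palette")
    return out
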