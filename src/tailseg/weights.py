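"""Class-rebalancing loss weights for long-tailed segmentation datasets.

Foreground classes in medical segmentation data are often wildly unequal
both in how many pixels they occupy and in how many images contain them
at all.  Scaling each class's loss contribution by the inverse of its
*image* count — rather than its pixel count — rebalances learning by how
many distinct annotated instances the network has seen, which is the
quantity that actually carries new learnable features.

With per-class image counts N_i over C foreground classes, the weight of
class i is

    W_i = C / (N_i * sum_j 1/N_j)        ("eq6" mode, sum of weights = C)

or the plain normalized inverse frequency

    W_i = (1/N_i) / sum_j (1/N_j)        ("sum_to_one" mode, sum = 1),

which is the eq6 weight divided by C.  The same formulas applied to pixel
counts give the conventional pixel-frequency baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DataError

MODES = ("eq6", "sum_to_one")


@dataclass(frozen=True)
class ClassStats:
    """Per-foreground-class image and pixel counts over a dataset."""

    class_labels: tuple
    image_counts: tuple
    pixel_counts: tuple

    def __post_init__(self):
        if not (len(self.class_labels) == len(self.image_counts)
                == len(self.pixel_counts)):
            raise DataError("class_labels/image_counts/pixel_counts lengths differ")
        if any(c < 0 for c in self.image_counts + self.pixel_counts):
            raise DataError("counts must be non-negative")

    @property
    def C(self) -> int:
        return len(self.class_labels)


@dataclass(frozen=True)
class WeightVector:
    """Per-class positive loss weights with their normalization mode.

    ``proportions`` are the intermediate inverse-frequency proportions
    (sum of counts divided by each class's count); ``background_weight``
    is the weight applied to label 0, which the rebalancing formula does
    not cover.
    """

    class_labels: tuple
    weights: tuple
    proportions: tuple
    mode: str
    background_weight: float = 1.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise DataError(f"mode must be one of {MODES}, got {self.mode!r}")
        if any(w <= 0 for w in self.weights) or self.background_weight <= 0:
            raise DataError("weights must be strictly positive")

    def full_weights(self) -> np.ndarray:
        """Weights for labels 0..C (background first)."""
        return np.concatenate([[self.background_weight], self.weights])


def compute_class_stats(dataset: Sequence, C: int) -> ClassStats:
    """Count, per foreground class 1..C, images containing it and its pixels.

    ``dataset`` is a sequence of objects with ``mask`` (integer H x W array)
    and ``identifier`` attributes (see :class:`tailseg.data_io.LabeledImage`).
    """
    if C < 1:
        raise DataError("C must be >= 1")
    image_counts = np.zeros(C, dtype=np.int64)
    pixel_counts = np.zeros(C, dtype=np.int64)
    for idx, item in enumerate(dataset):
        mask = np.asarray(item.mask)
        if mask.size and (mask.min() < 0 or mask.max() > C):
            name = getattr(item, "identifier", f"index {idx}")
            bad = int(mask.min()) if mask.min() < 0 else int(mask.max())
            raise DataError(
                f"mask value {bad} outside 0..{C} in {name}")
        hist = np.bincount(mask.ravel(), minlength=C + 1)[1:C + 1]
        pixel_counts += hist
        image_counts += hist > 0
    return ClassStats(tuple(range(1, C + 1)),
                      tuple(image_counts.tolist()),
                      tuple(pixel_counts.tolist()))


def _inverse_frequency_weights(labels, counts, mode, background_weight, kind):
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts <= 0):
        absent = [l for l, c in zip(labels, counts) if c <= 0]
        raise DataError(
            f"class(es) {absent} have zero {kind} count; exclude them from the "
            f"weight computation or supply a floor count")
    C = len(counts)
    inv = 1.0 / counts
    proportions = counts.sum() * inv          # inverse-ratio proportions
    w = inv / inv.sum()                       # sum_to_one
    if mode == "eq6":
        w = C * w                             # sum = C
    elif mode != "sum_to_one":
        raise DataError(f"mode must be one of {MODES}, got {mode!r}")
    return WeightVector(tuple(labels), tuple(w.tolist()),
                        tuple(proportions.tolist()), mode,
                        float(background_weight))


def image_based_weights(stats: ClassStats, mode: str = "eq6",
                        background_weight: float = 1.0) -> WeightVector:
    """Inverse image-count weights (the rebalancing formula's native form)."""
    return _inverse_frequency_weights(stats.class_labels, stats.image_counts,
                                      mode, background_weight, "image")


def pixel_based_weights(stats: ClassStats, mode: str = "eq6",
                        background_weight: float = 1.0) -> WeightVector:
    """Inverse pixel-count weights (the conventional frequency baseline)."""
    return _inverse_frequency_weights(stats.class_labels, stats.pixel_counts,
                                      mode, background_weight, "pixel")


def uniform_weights(C: int, background_weight: float = 1.0) -> WeightVector:
    """Unit weight for every class (the unweighted-loss baseline)."""
    return WeightVector(tuple(range(1, C + 1)), (1.0,) * C, (1.0,) * C,
                        "eq6", background_weight)


# ---------------------------------------------------------------------
# plain-text tables
# ---------------------------------------------------------------------

def write_class_stats(stats: ClassStats, path) -> None:
    lines = ["label,image_count,pixel_count"]
    for l, n, p in zip(stats.class_labels, stats.image_counts, stats.pixel_counts):
        lines.append(f"{l},{n},{p}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_class_stats(path) -> ClassStats:
    rows = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not rows or rows[0].replace(" ", "") != "label,image_count,pixel_count":
        raise DataError(f"{path}: expected header 'label,image_count,pixel_count'")
    labels, imgs, pix = [], [], []
    for ln in rows[1:]:
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 3:
            raise DataError(f"{path}: malformed row {ln!r}")
        labels.append(int(parts[0]))
        imgs.append(int(parts[1]))
        pix.append(int(parts[2]))
    return ClassStats(tuple(labels), tuple(imgs), tuple(pix))


def write_weights(wv: WeightVector, path) -> None:
    lines = [f"# mode={wv.mode} background_weight={wv.background_weight}",
             "label,weight"]
    for l, w in zip(wv.class_labels, wv.weights):
        lines.append(f"{l},{w:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
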