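"""2D pruning-region detection on semantic label images.

A semantic image is an integer raster in which each pixel carries a plant-part
class code::

    0 = background / other
    1 = stem
    2 = petiole
    3 = leaf
    4 = fruit

Pruning regions are found in four steps: (1) split the raster into a binary
stem layer and a binary petiole layer, (2) remove small connected components
from each (segmentation noise), (3) dilate both layers with an all-ones square
kernel and intersect them, which marks the petiole root points where petioles
touch the stem, and (4) dilate that intersection and intersect it with the
original (denoised) petiole layer.  Each 8-connected component of the result
is one pruning region; the member pixel nearest its centroid is the 2D
pruning point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: semantic class codes
LABEL_OTHER = 0
LABEL_STEM = 1
LABEL_PETIOLE = 2
LABEL_LEAF = 3
LABEL_FRUIT = 4
#: code painted into semantic images for detected pruning regions
LABEL_PRUNING = 5

PLANT_LABELS = (LABEL_STEM, LABEL_PETIOLE, LABEL_LEAF, LABEL_FRUIT)

#: default raster size (width, height) and the matching small-component cutoff
DEFAULT_WIDTH = 640
DEFAULT_HEIGHT = 480
DEFAULT_MIN_AREA = 50
DEFAULT_KERNEL_SIZE = 7

# 8-connectivity structuring element for component labeling
_CONN8 = np.ones((3, 3), dtype=bool)


def validate_semantic(labels: np.ndarray, allow_pruning: bool = False) -> np.ndarray:
    """Check a semantic raster and return it as a 2D integer array.

    Values must lie in {0..4} (or {0..5} when ``allow_pruning``); both
    dimensions must be at least 7 so the dilation kernel fits.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"semantic image must be 2D, got shape {labels.shape}")
    if labels.shape[0] < 7 or labels.shape[1] < 7:
        raise ValueError(f"semantic image must be at least 7x7, got {labels.shape}")
    hi = LABEL_PRUNING if allow_pruning else LABEL_FRUIT
    if labels.size and (labels.min() < 0 or labels.max() > hi):
        raise ValueError(f"semantic labels must be in 0..{hi}")
    return labels.astype(np.uint8, copy=False)


@dataclass(frozen=True)
class PruningRegion2D:
    """A connected set of petiole pixels adjacent to the stem.

    ``center`` is the member pixel closest to the region centroid, so the 2D
    pruning point always lies on petiole tissue.
    """

    pixels: frozenset = field(repr=False)
    center: tuple

    def __post_init__(self):
        if not self.pixels:
            raise ValueError("pruning region must contain at least one pixel")
        if self.center not in self.pixels:
            raise ValueError("region center must be a member pixel")

    @property
    def size(self) -> int:
        return len(self.pixels)


def extract_layer(labels: np.ndarray, label: int) -> np.ndarray:
    """Return the 0/1 indicator raster of one semantic class."""
    if label not in (1, 2, 3, 4):
        raise ValueError(f"label must be in 1..4, got {label!r}")
    labels = np.asarray(labels)
    return (labels == label).astype(np.uint8)


def remove_small_components(layer: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_area`` pixels."""
    if min_area < 1:
        raise ValueError(f"min_area must be >= 1, got {min_area}")
    layer = np.asarray(layer)
    lab, n = ndimage.label(layer > 0, structure=_CONN8)
    if n == 0:
        return np.zeros_like(layer, dtype=np.uint8)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab].astype(np.uint8)


def enlarge(layer: np.ndarray, kernel_size: int = DEFAULT_KERNEL_SIZE) -> np.ndarray:
    """Binary dilation with a centered all-ones square kernel.

    A pixel is set iff any input pixel lies within the kernel_size×kernel_size
    window centered on it; windows are clipped at image borders.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
    layer = np.asarray(layer)
    out = ndimage.maximum_filter(
        (layer > 0).astype(np.uint8), size=kernel_size, mode="constant", cval=0
    )
    return out.astype(np.uint8)


def intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise intersection of two binary layers (sum == 2)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"layer shapes differ: {a.shape} vs {b.shape}")
    return ((a > 0) & (b > 0)).astype(np.uint8)


def region_center(pixels) -> tuple:
    """Member pixel minimizing distance to the centroid; ties favor
    smaller row, then smaller column."""
    pts = sorted(pixels)
    if not pts:
        raise ValueError("region has no pixels")
    arr = np.asarray(pts, dtype=float)
    centroid = arr.mean(axis=0)
    d2 = ((arr - centroid) ** 2).sum(axis=1)
    # sorted() above already orders by (row, col): argmin returns first minimum
    best = int(np.argmin(d2))
    return tuple(int(c) for c in pts[best])


def detect_pruning_regions(
    labels: np.ndarray,
    min_area: int | None = None,
    kernel_size: int = DEFAULT_KERNEL_SIZE,
) -> list[PruningRegion2D]:
    """Run the four-step stem/petiole junction detection on one raster.

    When ``min_area`` is None the default of 50 pixels at 640x480 is scaled by
    the raster area.  Returns one region per 8-connected component of the
    final intersection layer (possibly empty).
    """
    labels = validate_semantic(labels, allow_pruning=True)
    if min_area is None:
        h, w = labels.shape
        min_area = max(1, round(DEFAULT_MIN_AREA * (h * w) / (DEFAULT_HEIGHT * DEFAULT_WIDTH)))

    stem = remove_small_components(extract_layer(labels, LABEL_STEM), min_area)
    petiole = remove_small_components(extract_layer(labels, LABEL_PETIOLE), min_area)
    if not stem.any() or not petiole.any():
        return []

    # petiole root points: where the dilated layers overlap
    roots = intersect(enlarge(stem, kernel_size), enlarge(petiole, kernel_size))
    # pruning regions: petiole pixels near the root points
    regions_mask = intersect(enlarge(roots, kernel_size), petiole)

    lab, n = ndimage.label(regions_mask, structure=_CONN8)
    regions = []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(lab == idx)
        pix = frozenset(zip(rows.tolist(), cols.tolist()))
        regions.append(PruningRegion2D(pixels=pix, center=region_center(pix)))
    return regions


def paint_pruning_regions(
    labels: np.ndarray, regions: list[PruningRegion2D]
) -> np.ndarray:
    """Return a copy of the semantic raster with region pixels set to the
    pruning code (5), ready for semantic-cloud construction."""
    out = np.asarray(labels).astype(np.uint8).copy()
    for region in regions:
        for r, c in region.pixels:
            out[r, c] = LABEL_PRUNING
    return out
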