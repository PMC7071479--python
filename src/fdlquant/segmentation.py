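"""Segmentation of neuron-scale objects on merged two-channel images.

The two fluorescence channels are merged to a single 8-bit gray raster,
thresholded (Otsu by default, or a fixed manual value), labeled into
connected components, and filtered by pixel area: only objects with area
strictly greater than ``min_area_px`` (default 400) are kept.  Intensity
measurement is *redirected*: the mask produced here is applied back to the
original channel rasters by the densitometry stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .image_io import TwoChannelImage

logger = logging.getLogger(__name__)

MERGE_RULES = ("mean2", "mean3")


def merge_to_gray(img: TwoChannelImage, rule: str = "mean2") -> np.ndarray:
    """Merge red and green channels to one 8-bit gray raster.

    ``mean2`` (default): gray = round((red + green)/2), rounding half up.
    ``mean3``: gray = round((red + green)/3) -- the unweighted RGB average
    with an all-zero blue channel, as a plain RGB->gray conversion would do.
    ``mean2`` keeps the merged scale comparable to a single channel's and is
    the default everywhere.
    """
    s = img.red.astype(np.uint16) + img.green.astype(np.uint16)
    if rule == "mean2":
        gray = (s + 1) // 2  # round half up on .5
    elif rule == "mean3":
        gray = np.floor(s / 3.0 + 0.5).astype(np.uint16)
    else:
        raise ValueError(f"unknown merge rule {rule!r}; expected one of {MERGE_RULES}")
    return np.minimum(gray, 255).astype(np.uint8)


@dataclass(frozen=True)
class ThresholdResult:
    mask: np.ndarray
    value: int
    method: str


def threshold(
    gray: np.ndarray, method: str = "otsu", fixed_value: int | None = None
) -> ThresholdResult:
    """Binarize a gray raster: mask is True where gray > threshold value.

    ``otsu`` picks the value maximizing between-class variance; ``fixed``
    uses ``fixed_value`` (0-255), standing in for the manual adjustment a
    microscopist would apply.  The chosen value is logged and returned.
    """
    gray = np.asarray(gray)
    if method == "otsu":
        if fixed_value is not None:
            raise ValueError("fixed_value is only meaningful with method='fixed'")
        if gray.min() == gray.max():
            raise ValueError(
                "cannot Otsu-threshold a constant image (no intensity contrast)"
            )
        value = int(threshold_otsu(gray))
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        if not 0 <= fixed_value <= 255:
            raise ValueError("fixed_value must be in [0, 255]")
        value = int(fixed_value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    logger.info("threshold: method=%s value=%d", method, value)
    return ThresholdResult(mask=gray > value, value=value, method=method)


@dataclass(frozen=True)
class RoiObject:
    """One labeled connected component passing the area filter."""

    label_id: int
    coords: np.ndarray = field(repr=False)  # (N, 2) array of (row, col)

    @property
    def area_px(self) -> int:
        return len(self.coords)

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), inclusive."""
        rows, cols = self.coords[:, 0], self.coords[:, 1]
        return int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())


def extract_objects(
    mask: np.ndarray, min_area_px: int = 400, connectivity: int = 8
) -> list[RoiObject]:
    """Label connected components and keep those with area > min_area_px.

    The area cut is a strict inequality: a component of exactly
    ``min_area_px`` pixels is discarded.  ``connectivity`` is 4
    (edge-adjacent) or 8 (edge- or corner-adjacent, the default).  Returned
    label_ids are 1-based and ordered by each component's first pixel in a
    row-major scan.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labeled = cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    if labeled.max() == 0:
        return []
    flat = labeled.ravel()
    labels, first_idx = np.unique(flat, return_index=True)
    order = [(idx, lab) for lab, idx in zip(labels, first_idx) if lab != 0]
    order.sort()  # by first-encountered flat (row-major) index
    objects: list[RoiObject] = []
    next_id = 1
    for _, lab in order:
        coords = np.argwhere(labeled == lab)
        if coords.shape[0] > min_area_px:
            objects.append(RoiObject(label_id=next_id, coords=coords))
            next_id += 1
    return objects


def label_raster(objects: list[RoiObject], shape: tuple[int, int]) -> np.ndarray:
    """Render kept objects back into a label image (0 = background)."""
    out = np.zeros(shape, dtype=np.int32)
    for obj in objects:
        out[obj.coords[:, 0], obj.coords[:, 1]] = obj.label_id
    return out
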