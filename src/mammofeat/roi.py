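"""Boundary annotation -> binary mask -> tight ROI crop.

Coordinate convention: images are indexed (row, col), 0-based, with pixel
centers at integer coordinates.  Annotation boundaries are (x, y) = (col,
row) as is customary for point annotations; they are converted on use.
A pixel belongs to the mask when its center lies inside *or on* the
annotation polygon.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import shapely
from shapely.geometry import Polygon


class MaskError(ValueError):
    pass


@dataclasses.dataclass
class LesionSample:
    """The unit every feature operator consumes: a cropped gray ROI, its
    aligned binary mask, the crop offset in the source image, and the label."""

    roi: np.ndarray  # 2-D uint8 gray patch
    mask: np.ndarray  # 2-D bool, same shape
    offset: tuple[int, int]  # (row, col) of roi[0, 0] in the source image
    label: str

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.roi.shape != self.mask.shape:
            raise MaskError("roi and mask shapes differ")
        if not self.mask.any():
            raise MaskError("mask has no foreground pixels")


def contour_to_mask(boundary: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed simple polygon of (x, y) points into a binary mask.

    Pixel centers exactly on the polygon edge count as foreground, so an
    axis-aligned square with corners (0,0)..(9,9) covers exactly 100 pixels.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[1] != 2 or len(boundary) < 3:
        raise MaskError("boundary must contain at least 3 (x, y) points")
    poly = Polygon(boundary)
    if not poly.is_valid:
        raise MaskError("boundary polygon is degenerate or self-intersecting")
    if poly.area <= 0:
        raise MaskError("boundary polygon has zero area")

    h, w = image_shape
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    if c1 < c0 or r1 < r0:
        raise MaskError("polygon lies outside the image")

    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(cols.ravel(), rows.ravel())
    inside = shapely.covers(poly, pts).reshape(rows.shape)  # boundary counts
    mask = np.zeros(image_shape, dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    if not mask.any():
        raise MaskError("polygon covers no pixel centers")
    return mask


def crop_roi(image: np.ndarray, mask: np.ndarray, label: str = "benign") -> LesionSample:
    """Crop the tight bounding box of the mask foreground.

    Pixels outside the mask but inside the box are retained in the ROI;
    individual feature operators decide whether to honor the mask.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise MaskError("image and mask shapes differ")
    if not mask.any():
        raise MaskError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return LesionSample(
        roi=image[r0:r1, c0:c1].copy(),
        mask=mask[r0:r1, c0:c1].copy(),
        offset=(int(r0), int(c0)),
        label=label,
    )


def reinsert_mask(sample: LesionSample, image_shape: tuple[int, int]) -> np.ndarray:
    """Place the cropped mask back at its offset (inverse of crop_roi)."""
    out = np.zeros(image_shape, dtype=bool)
    r0, c0 = sample.offset
    h, w = sample.mask.shape
    out[r0 : r0 + h, c0 : c0 + w] = sample.mask
    return out
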