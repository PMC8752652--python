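"""Geometry feature battery: 80 features (F46-F125).

13 shape/margin descriptors of the binary lesion mask, 15 Zernike moment
magnitudes (orders n = 0..4, signed repetition m), and 52 generic Fourier
descriptors from a polar 2-D Fourier transform of the mask.  All three
groups operate on the binary mask — the geometric signature of the lesion
outline — never on gray levels.
"""

from __future__ import annotations

from math import factorial

import numpy as np
from scipy import ndimage
from shapely import MultiPoint
from skimage import measure

from .io import GFD_ANGULAR, GFD_RADIAL, ZERNIKE_ORDERS
from .roi import LesionSample

SHAPE_KEYS = [
    "Area", "Major axis length", "Minor axis length", "Eccentricity",
    "Orientation", "Convex area", "Filled area", "Euler number",
    "Equiv diameter", "Solidity", "Extent", "Perimeter", "Perimeter cirratio",
]


def _mask(sample: LesionSample | np.ndarray) -> np.ndarray:
    m = sample.mask if isinstance(sample, LesionSample) else sample
    m = np.asarray(m, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    return m


def convex_pixel_area(mask: np.ndarray) -> float:
    """Number of pixel centers covered by the convex hull of the foreground
    pixel centers (the convex counterpart of the pixel-count area)."""
    rr, cc = np.nonzero(mask)
    hull = MultiPoint(np.column_stack([cc, rr])).convex_hull
    if hull.geom_type != "Polygon":  # collinear masks degenerate to a line
        return float(mask.sum())
    import shapely

    r0, r1 = rr.min(), rr.max()
    c0, c1 = cc.min(), cc.max()
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = shapely.points(cols.ravel(), rows.ravel())
    return float(np.count_nonzero(shapely.covers(hull, pts)))


def mask_perimeter(mask: np.ndarray) -> float:
    """Boundary length: total polyline length of the half-level contours of
    the (zero-padded) mask, summing outer and hole boundaries."""
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        total += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    return total


def compute_shape_features(sample: LesionSample | np.ndarray) -> dict[str, float]:
    """The 13 shape descriptors of the binary mask.

    Axis lengths, eccentricity and orientation come from the equivalent
    ellipse of the second central moments; orientation is reported in
    degrees in (-90, 90], measured from the row axis.  The Euler number uses
    8-connected foreground; 'Perimeter cirratio' is the circularity ratio
    P^2 / (4 pi A).
    """
    mask = _mask(sample)
    area = float(mask.sum())
    props = measure.regionprops(mask.astype(np.uint8))[0]

    orientation = float(np.rad2deg(props.orientation))
    if orientation <= -90.0:
        orientation += 180.0

    convex_area = convex_pixel_area(mask)
    filled = float(ndimage.binary_fill_holes(mask).sum())
    euler = float(measure.euler_number(mask, connectivity=2))
    bbox_area = mask.shape[0] * mask.shape[1]
    perimeter = mask_perimeter(mask)
    return {
        "Area": area,
        "Major axis length": float(props.axis_major_length),
        "Minor axis length": float(props.axis_minor_length),
        "Eccentricity": float(props.eccentricity),
        "Orientation": orientation,
        "Convex area": convex_area,
        "Filled area": filled,
        "Euler number": euler,
        "Equiv diameter": float(np.sqrt(4.0 * area / np.pi)),
        "Solidity": area / convex_area if convex_area > 0 else 1.0,
        "Extent": area / bbox_area,
        "Perimeter": perimeter,
        "Perimeter cirratio": perimeter**2 / (4.0 * np.pi * area),
    }


# --------------------------------------------------------------------------- #
# Zernike moments
# --------------------------------------------------------------------------- #


def _radial_poly(n: int, m: int, r: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(r)
    for s in range((n - m) // 2 + 1):
        coeff = (
            (-1) ** s
            * factorial(n - s)
            / (factorial(s) * factorial((n + m) // 2 - s) * factorial((n - m) // 2 - s))
        )
        out += coeff * r ** (n - 2 * s)
    return out


def _unit_disk_coords(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map mask pixel centers onto the closed unit disk: centroid-centered,
    scaled by the maximum centroid-to-pixel distance."""
    rr, cc = np.nonzero(mask)
    y = rr - rr.mean()
    x = cc - cc.mean()
    rmax = float(np.hypot(x, y).max())
    if rmax == 0:
        rmax = 1.0  # single-pixel mask: one sample at the origin
    r = np.hypot(x, y) / rmax
    theta = np.arctan2(y, x)
    return r, theta


def compute_zernike_moments(sample: LesionSample | np.ndarray) -> dict[str, float]:
    """Magnitudes |Z_nm| of the 15 Zernike moments of the binary mask,
    Z_nm = (n+1)/pi * mean over mask pixels of V_nm*.  Magnitudes are
    rotation-invariant; conjugate pairs (m, -m) have identical magnitude."""
    mask = _mask(sample)
    r, theta = _unit_disk_coords(mask)
    out: dict[str, float] = {}
    for n, m in ZERNIKE_ORDERS:
        radial = _radial_poly(n, m, r)
        v_conj = radial * np.exp(-1j * m * theta)
        z = (n + 1) / np.pi * v_conj.mean()
        name = f"ZM{n}{m}" if m >= 0 else f"ZM{n}-{abs(m)}"
        out[name] = float(np.abs(z))
    return out


# --------------------------------------------------------------------------- #
# Generic Fourier descriptors
# --------------------------------------------------------------------------- #


def compute_gfd(
    sample: LesionSample | np.ndarray,
    radial: int = GFD_RADIAL,
    angular: int = GFD_ANGULAR,
) -> dict[str, float]:
    """Generic Fourier descriptors of the binary mask on a polar frequency
    grid of ``radial`` x ``angular`` frequencies (default 4 x 13 = 52).

    Each mask pixel contributes exp(-j(2 pi r_norm rho + theta phi)) with
    r_norm the centroid distance over the maximum centroid distance.  The
    (0,0) coefficient is normalized by the area (making FD1 scale-invariant
    and identically 1 for any mask); all others by |PF(0,0)|.  Centroid
    centering makes the descriptors translation-invariant; using magnitudes
    makes them rotation-invariant up to rasterization error.
    """
    mask = _mask(sample)
    r, theta = _unit_disk_coords(mask)
    area = float(mask.sum())
    out: dict[str, float] = {}
    rho = np.arange(radial)[:, None, None]
    phi = np.arange(angular)[None, :, None]
    phase = 2.0 * np.pi * r[None, None, :] * rho + theta[None, None, :] * phi
    pf = np.abs(np.exp(-1j * phase).sum(axis=2))  # (radial, angular)
    dc = pf[0, 0]
    for p in range(radial):
        for q in range(angular):
            idx = p * angular + q + 1
            if p == 0 and q == 0:
                out[f"FD{idx}"] = dc / area
            else:
                out[f"FD{idx}"] = pf[p, q] / dc if dc > 0 else 0.0
    return out


def compute_geometry_features(sample: LesionSample | np.ndarray) -> np.ndarray:
    """All 80 geometry features, catalog order F46..F125."""
    vals: list[float] = []
    shape = compute_shape_features(sample)
    vals += [shape[k] for k in SHAPE_KEYS]
    zern = compute_zernike_moments(sample)
    vals += list(zern.values())
    gfd = compute_gfd(sample)
    vals += [gfd[f"FD{i}"] for i in range(1, GFD_RADIAL * GFD_ANGULAR + 1)]
    return np.array(vals, dtype=float)
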