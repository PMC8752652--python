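"""Texture feature battery: 45 features (F1-F45) across seven models.

Models: spatial gray-level co-occurrence matrices (SGLCM, 14 Haralick
statistics averaged over the four unit-displacement directions), gray-level
difference statistics (GLDS), first-order histogram statistics (FOS), the
statistical feature matrix (SFM), Laws' texture energy measures (LTEM),
fractional-Brownian-motion Hurst coefficients at two resolutions, and
Fourier power spectrum (FPS) band sums.

All operators consume the full rectangular ROI patch (not mask-restricted):
the co-occurrence / convolution machinery requires a dense grid.  The
co-occurrence family (SGLCM, GLDS, SFM) works on a quantized copy of the
ROI: gray values are shifted so the minimum is zero and, only when more
than ``levels`` distinct values remain, linearly requantized down to
``levels`` bins.  Small-range inputs therefore keep their exact gray
differences.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d
from skimage.feature import graycomatrix

from .io import LAWS_MASK_NAMES
from .roi import LesionSample

DEFAULT_LEVELS = 32
GLDS_DELTAS = ((0, 1), (1, 0), (1, 1), (1, -1))

SGLCM_KEYS = [
    "ASM", "Contrast", "Correlation", "Sum squares", "Inverse diff moment",
    "Sum average", "Sum variance", "Sum entropy", "Entropy", "Diff variance",
    "Diff entropy", "Info measure1", "Info measure2", "Max Corr Coff",
]


def quantize(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Shift gray values to start at 0; requantize to ``levels`` bins only
    when the value range exceeds ``levels``."""
    image = np.asarray(image)
    lo = int(image.min())
    hi = int(image.max())
    span = hi - lo + 1
    shifted = image.astype(np.int64) - lo
    if span <= levels:
        return shifted
    return (shifted * levels) // span  # floor division onto 0..levels-1


def _roi(sample: LesionSample | np.ndarray) -> np.ndarray:
    if isinstance(sample, LesionSample):
        return np.asarray(sample.roi)
    return np.asarray(sample)


# --------------------------------------------------------------------------- #
# SGLCM (F1-F14)
# --------------------------------------------------------------------------- #


def glcm_matrices(image: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Four normalized symmetric co-occurrence matrices at displacement 1 for
    directions 0, 45, 90 and 135 degrees; shape (levels_used, levels_used, 4)."""
    q = quantize(image, levels).astype(np.uint8)
    used = int(q.max()) + 1
    glcm = graycomatrix(
        q, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=used, symmetric=True, normed=True,
    )
    return glcm[:, :, 0, :]


def _haralick(p: np.ndarray) -> dict[str, float]:
    """The 14 Haralick statistics of one normalized symmetric GLCM."""
    g = p.shape[0]
    i = np.arange(g)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))

    # sum / difference marginals
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    p_dif = np.zeros(g)
    np.add.at(p_dif, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2 * g - 1)
    k_dif = np.arange(g)

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)))

    asm = float(np.sum(p**2))
    contrast = float(np.sum(k_dif**2 * p_dif))
    if var_x > 0 and var_y > 0:
        corr = float((np.sum(ii * jj * p) - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        corr = 0.0
    sum_squares = float(np.sum((ii - mu_x) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    sum_avg = float(np.sum(k_sum * p_sum))
    sum_var = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    sum_ent = ent(p_sum)
    entropy = ent(p)
    dif_mean = float(np.sum(k_dif * p_dif))
    dif_var = float(np.sum((k_dif - dif_mean) ** 2 * p_dif))
    dif_ent = ent(p_dif)

    # information measures of correlation
    hx, hy = ent(px), ent(py)
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[nz] * np.log(outer[nz])))
    nz2 = outer > 0
    hxy2 = float(-np.sum(outer[nz2] * np.log(outer[nz2])))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    live = px > 0
    if live.sum() >= 2:
        ps = p[np.ix_(live, live)]
        pxs = px[live]
        pys = py[live]
        q_mat = (ps / pxs[:, None]) @ (ps / pys[:, None]).T
        eig = np.sort(np.real(np.linalg.eigvals(q_mat)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 0.0

    vals = [asm, contrast, corr, sum_squares, idm, sum_avg, sum_var, sum_ent,
            entropy, dif_var, dif_ent, imc1, imc2, mcc]
    return dict(zip(SGLCM_KEYS, vals))


def compute_sglcm_features(
    sample: LesionSample | np.ndarray, levels: int = DEFAULT_LEVELS
) -> dict[str, float]:
    """Haralick statistics averaged over the four directional matrices."""
    image = _roi(sample)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("SGLCM needs an ROI of at least 2x2 pixels")
    mats = glcm_matrices(image, levels)
    per_dir = [_haralick(mats[:, :, a]) for a in range(mats.shape[2])]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in SGLCM_KEYS}


# --------------------------------------------------------------------------- #
# GLDS (F15-F19)
# --------------------------------------------------------------------------- #


def _difference_histogram(q: np.ndarray, delta: tuple[int, int]) -> np.ndarray:
    """Probability density of |I(x,y) - I(x+dx, y+dy)| for one displacement;
    delta is (drow, dcol)."""
    dr, dc = delta
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    diffs = np.abs(a.astype(np.int64) - b.astype(np.int64)).ravel()
    m = int(q.max()) + 1
    hist = np.bincount(diffs, minlength=m).astype(float)
    return hist / hist.sum()


def compute_glds_features(
    sample: LesionSample | np.ndarray,
    deltas: tuple[tuple[int, int], ...] = GLDS_DELTAS,
    levels: int = DEFAULT_LEVELS,
) -> dict[str, float]:
    """Gray-level difference statistics, averaged over the displacement set."""
    image = _roi(sample)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("GLDS needs an ROI of at least 2x2 pixels")
    q = quantize(image, levels)
    feats = {"Homogeneity": [], "Contrast": [], "Mean": [], "Energy": [], "Entropy": []}
    for delta in deltas:
        p = _difference_histogram(q, delta)
        i = np.arange(len(p))
        nz = p > 0
        feats["Mean"].append(float(np.sum(i * p)))
        feats["Contrast"].append(float(np.sum(i**2 * p)))
        feats["Energy"].append(float(np.sum(p**2)))
        feats["Entropy"].append(float(-np.sum(p[nz] * np.log(p[nz]))))
        feats["Homogeneity"].append(float(np.sum(p / (1.0 + i))))
    return {k: float(np.mean(v)) for k, v in feats.items()}


# --------------------------------------------------------------------------- #
# FOS (F20-F23)
# --------------------------------------------------------------------------- #


def compute_fos_features(sample: LesionSample | np.ndarray) -> dict[str, float]:
    """Population moments of the raw gray-level histogram: mean, variance,
    skewness and (non-excess) kurtosis.  Degenerate (zero variance) patches
    report skewness = kurtosis = 0."""
    x = _roi(sample).astype(float).ravel()
    if x.size == 0:
        raise ValueError("FOS needs at least one pixel")
    mu = float(x.mean())
    var = float(np.mean((x - mu) ** 2))
    if var == 0:
        return {"Mean": mu, "Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    sd = np.sqrt(var)
    skew = float(np.mean((x - mu) ** 3) / sd**3)
    kurt = float(np.mean((x - mu) ** 4) / var**2)
    return {"Mean": mu, "Variance": var, "Skewness": skew, "Kurtosis": kurt}


# --------------------------------------------------------------------------- #
# SFM (F24-F27)
# --------------------------------------------------------------------------- #


def sfm_dissimilarity(
    q: np.ndarray, max_dr: int, max_dc: int
) -> tuple[np.ndarray, np.ndarray]:
    """Dissimilarity DSS(i,j) = E|I(x,y)-I(x+i,y+j)| and contrast
    CON(i,j) = E[(I(x,y)-I(x+i,y+j))^2] over the displacement lattice."""
    dss = np.zeros((max_dr + 1, max_dc + 1))
    con = np.zeros_like(dss)
    h, w = q.shape
    qi = q.astype(np.int64)
    for dr in range(max_dr + 1):
        for dc in range(max_dc + 1):
            if dr == 0 and dc == 0:
                continue
            a = qi[: h - dr, : w - dc]
            b = qi[dr:, dc:]
            d = a - b
            dss[dr, dc] = np.mean(np.abs(d))
            con[dr, dc] = np.mean(d.astype(float) ** 2)
    return dss, con


def _directional_roughness(profile: np.ndarray) -> float:
    """3 - H for one DSS axis profile (fractal-dimension reading of decay)."""
    d = np.arange(1, len(profile))
    vals = profile[1:]
    ok = vals > 0
    if ok.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(d[ok]), np.log(vals[ok]), 1)[0]
    return 3.0 - float(np.clip(slope, 0.0, 1.0))


def compute_sfm_features(
    sample: LesionSample | np.ndarray,
    max_dr: int = 4,
    max_dc: int = 4,
    levels: int = DEFAULT_LEVELS,
) -> dict[str, float]:
    """Statistical-feature-matrix scalars: coarseness, contrast, periodicity,
    roughness, derived from multi-displacement dissimilarity statistics.

    coarseness = n / sum(DSS) over the non-zero displacements (0 when the
    patch is flat); contrast = sqrt of the mean unit-displacement squared
    difference; periodicity = relative depth of the deepest DSS valley;
    roughness = mean of the two axis-wise fractal dimensions 3 - H fitted to
    log DSS versus log distance.
    """
    image = _roi(sample)
    if image.shape[0] <= max_dr + 1 or image.shape[1] <= max_dc + 1:
        raise ValueError("ROI too small for the SFM displacement lattice")
    q = quantize(image, levels)
    dss, con = sfm_dissimilarity(q, max_dr, max_dc)
    valid = np.ones_like(dss, dtype=bool)
    valid[0, 0] = False
    n = int(valid.sum())

    total = float(dss[valid].sum())
    coarseness = n / total if total > 0 else 0.0
    contrast = float(np.sqrt((con[0, 1] + con[1, 0]) / 2.0))
    mean_dss = float(dss[valid].mean())
    periodicity = (mean_dss - float(dss[valid].min())) / mean_dss if mean_dss > 0 else 0.0
    if total > 0:
        roughness = 0.5 * (
            _directional_roughness(dss[:, 0]) + _directional_roughness(dss[0, :])
        )
    else:
        roughness = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Periodicity": periodicity,
        "Roughness": roughness,
    }


# --------------------------------------------------------------------------- #
# LTEM (F28-F41)
# --------------------------------------------------------------------------- #

LAWS_VECTORS = {
    "L": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),  # level
    "E": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),  # edge
    "S": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),  # spot
    "W": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),  # wave
    "R": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),  # ripple
}


def laws_mask_bank() -> dict[str, np.ndarray]:
    """The fourteen 5x5 Laws masks, keyed by their two-letter names.

    A name "XY" denotes outer(X as column, Y as row); pairs XY/YX are kept
    distinct here and averaged into one energy by the feature operator.
    """
    bank: dict[str, np.ndarray] = {}
    for name in LAWS_MASK_NAMES:
        a, b = name[0], name[1]
        bank[name] = np.outer(LAWS_VECTORS[a], LAWS_VECTORS[b])
    return bank


def _mask_energy(image: np.ndarray, mask: np.ndarray) -> float:
    resp = convolve2d(image, mask, mode="valid")
    return float(np.mean(np.abs(resp)))


def compute_ltem_features(sample: LesionSample | np.ndarray) -> dict[str, float]:
    """Laws texture energies: mean absolute 5x5 filter response over fully
    overlapping positions; mixed pairs (XY, YX) averaged into one value."""
    image = _roi(sample).astype(float)
    if image.shape[0] < 5 or image.shape[1] < 5:
        raise ValueError("LTEM needs an ROI of at least 5x5 pixels")
    out: dict[str, float] = {}
    for name in LAWS_MASK_NAMES:
        a, b = name[0], name[1]
        m1 = np.outer(LAWS_VECTORS[a], LAWS_VECTORS[b])
        if a == b:
            out[name] = _mask_energy(image, m1)
        else:
            m2 = np.outer(LAWS_VECTORS[b], LAWS_VECTORS[a])
            out[name] = 0.5 * (_mask_energy(image, m1) + _mask_energy(image, m2))
    return out


# --------------------------------------------------------------------------- #
# Fractal (F42-F43)
# --------------------------------------------------------------------------- #


def _mean_abs_diff_at_distances(image: np.ndarray, dmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean absolute gray difference at each rounded Euclidean pixel distance
    1..dmax, pooling every displacement vector that rounds to the distance."""
    h, w = image.shape
    sums = np.zeros(dmax + 1)
    counts = np.zeros(dmax + 1)
    for dr in range(0, dmax + 1):
        for dc in range(-dmax, dmax + 1):
            if dr == 0 and dc <= 0:
                continue  # half-plane: each unordered pair once
            d = int(round(np.hypot(dr, dc)))
            if not 1 <= d <= dmax:
                continue
            r1 = h - dr
            c0, c1 = max(0, -dc), min(w, w - dc)
            if r1 <= 0 or c1 <= c0:
                continue
            a = image[:r1, c0:c1]
            b = image[dr:, c0 + dc : c1 + dc]
            diff = np.abs(a - b)
            sums[d] += diff.sum()
            counts[d] += diff.size
    dists = np.arange(1, dmax + 1)
    with np.errstate(invalid="ignore"):
        means = sums[1:] / counts[1:]
    ok = counts[1:] > 0
    return dists[ok], means[ok]


def _hurst(image: np.ndarray, dmax: int) -> float:
    d, m = _mean_abs_diff_at_distances(image.astype(float), dmax)
    keep = m > 0
    if keep.sum() < 2:
        return 0.0  # flat patch fallback
    slope = np.polyfit(np.log(d[keep]), np.log(m[keep]), 1)[0]
    return float(np.clip(slope, 0.0, 1.0))


def compute_fractal_features(sample: LesionSample | np.ndarray) -> dict[str, float]:
    """Hurst coefficients of the fractional-Brownian-motion texture model.

    H1: slope of log mean-absolute-difference versus log distance over
    distances 1..8 at full resolution.  H2: the same over distances 1..4
    after 2x downsampling by 2x2 block averaging.  Rougher texture gives a
    lower H.  Constant patches fall back to (0, 0).
    """
    image = _roi(sample).astype(float)
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("fractal estimation needs an ROI of at least 8x8 pixels")
    h1 = _hurst(image, 8)
    h, w = image.shape
    half = image[: h - h % 2, : w - w % 2]
    half = 0.25 * (half[0::2, 0::2] + half[1::2, 0::2] + half[0::2, 1::2] + half[1::2, 1::2])
    h2 = _hurst(half, 4)
    return {"H1": h1, "H2": h2}


# --------------------------------------------------------------------------- #
# FPS (F44-F45)
# --------------------------------------------------------------------------- #


def compute_fps_features(
    sample: LesionSample | np.ndarray,
    radial_band: tuple[float, float] = (0.125, 0.25),
    wedge_half_angle_deg: float = 22.5,
) -> dict[str, float]:
    """Fourier power-spectrum band sums, as fractions of non-DC power.

    ``Sr``: power in the annulus ``radial_band`` (cycles/pixel; the default
    spans a quarter to a half of the Nyquist frequency 0.5).  ``Stheta``:
    power in the symmetric wedge within ``wedge_half_angle_deg`` of the
    horizontal-variation axis.
    """
    image = _roi(sample).astype(float)
    if image.shape[0] < 4 or image.shape[1] < 4:
        raise ValueError("FPS needs an ROI of at least 4x4 pixels")
    spec = np.abs(np.fft.fft2(image)) ** 2
    fy = np.fft.fftfreq(image.shape[0])[:, None]  # row-direction frequency
    fx = np.fft.fftfreq(image.shape[1])[None, :]  # column-direction frequency
    radius = np.hypot(fx, fy)
    nondc = radius > 0
    total = float(spec[nondc].sum())
    if total == 0:
        return {"Sr": 0.0, "Stheta": 0.0}
    lo, hi = radial_band
    annulus = nondc & (radius >= lo) & (radius < hi)
    theta = np.arctan2(np.broadcast_to(fy, spec.shape), np.broadcast_to(fx, spec.shape))
    half = np.deg2rad(wedge_half_angle_deg)
    wedge = nondc & (
        (np.abs(theta) <= half) | (np.abs(np.abs(theta) - np.pi) <= half)
    )
    return {
        "Sr": float(spec[annulus].sum()) / total,
        "Stheta": float(spec[wedge].sum()) / total,
    }


# --------------------------------------------------------------------------- #
# Assembly
# --------------------------------------------------------------------------- #


def compute_texture_features(
    sample: LesionSample, levels: int = DEFAULT_LEVELS
) -> np.ndarray:
    """All 45 texture features, catalog order F1..F45."""
    vals: list[float] = []
    sglcm = compute_sglcm_features(sample, levels)
    vals += [sglcm[k] for k in SGLCM_KEYS]
    glds = compute_glds_features(sample, levels=levels)
    vals += [glds[k] for k in ["Homogeneity", "Contrast", "Mean", "Energy", "Entropy"]]
    fos = compute_fos_features(sample)
    vals += [fos[k] for k in ["Mean", "Variance", "Skewness", "Kurtosis"]]
    sfm = compute_sfm_features(sample, levels=levels)
    vals += [sfm[k] for k in ["Coarseness", "Contrast", "Periodicity", "Roughness"]]
    ltem = compute_ltem_features(sample)
    vals += [ltem[k] for k in LAWS_MASK_NAMES]
    frac = compute_fractal_features(sample)
    vals += [frac["H1"], frac["H2"]]
    fps = compute_fps_features(sample)
    vals += [fps["Sr"], fps["Stheta"]]
    return np.array(vals, dtype=float)
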