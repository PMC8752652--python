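"""Synthetic spiculated-lesion phantoms with ground-truth annotations.

Each phantom is a grayscale patch holding one mass whose outline is a
radial curve r(theta) = R * (1 + a * s(theta)), with s a smoothed periodic
perturbation carrying a configurable number of spiculation lobes, and whose
interior is filled with fractional-Brownian-motion-like texture of a target
Hurst exponent.  Benign presets are smooth and homogeneous (low spiculation
amplitude, high Hurst); malignant presets are spiculated and rough (high
amplitude, low Hurst, higher gray-level contrast) — the geometric and
textural class contrast the downstream analysis assumes.

The module also generates labeled Gaussian feature tables (signal features
among pure noise) for exercising the feature-selection stage directly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import io as mio
from .io import AnnotationRecord, FeatureTable
from .roi import LesionSample, contour_to_mask, crop_roi

_BOUNDARY_POINTS = 180
_MASS_LEVEL_OFFSET = 45  # mass interior mean gray above background
_MARGIN = 5  # required clearance between mass and patch border, px


class LesionSizeError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class LesionParams:
    """Generation parameters for one synthetic mass."""

    label: str
    base_radius: float  # px
    spiculation_amplitude: float  # fraction of radius, [0, 1)
    spiculation_count: int
    boundary_smoothness: int  # low-pass harmonic cutoff on the radial curve
    texture_hurst: float  # target Hurst exponent in (0, 1)
    texture_contrast: float  # gray-level std inside the mass
    background_level: float  # mean gray of surrounding tissue
    patch_size: int  # px per side
    seed: int

    def __post_init__(self) -> None:
        if self.label not in mio.LABELS:
            raise ValueError(f"label must be one of {mio.LABELS}")
        if not 0.0 <= self.spiculation_amplitude < 1.0:
            raise ValueError("spiculation_amplitude must be in [0, 1)")
        if self.spiculation_count < 0:
            raise ValueError("spiculation_count must be >= 0")
        if not 0.0 < self.texture_hurst < 1.0:
            raise ValueError("texture_hurst must be in (0, 1)")
        max_r = self.base_radius * (1.0 + self.spiculation_amplitude)
        if max_r + _MARGIN > self.patch_size / 2.0:
            raise LesionSizeError(
                f"mass radius {max_r:.1f} + {_MARGIN} px margin exceeds "
                f"patch half-size {self.patch_size / 2:.1f}"
            )


#: Default class presets.  The geometric/textural contrast is what matters:
#: benign masses are near-round with gentle, heavily smoothed undulation and
#: smooth (high-Hurst, low-contrast) interiors; malignant masses carry many
#: high-amplitude spicule lobes and rough, heterogeneous interiors.
BENIGN_PRESET = LesionParams(
    label="benign", base_radius=16.0, spiculation_amplitude=0.10,
    spiculation_count=6, boundary_smoothness=8, texture_hurst=0.60,
    texture_contrast=14.0, background_level=90.0, patch_size=72, seed=0,
)
MALIGNANT_PRESET = LesionParams(
    label="malignant", base_radius=16.0, spiculation_amplitude=0.30,
    spiculation_count=11, boundary_smoothness=18, texture_hurst=0.40,
    texture_contrast=24.0, background_level=90.0, patch_size=72, seed=0,
)
DEFAULT_PRESETS = {"benign": BENIGN_PRESET, "malignant": MALIGNANT_PRESET}


def fbm_texture(shape: tuple[int, int], hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Spectral synthesis of fractional-Brownian-like texture, unit variance.

    White Gaussian Fourier coefficients are shaped by an isotropic amplitude
    spectrum f^-(H+1), i.e. a power spectrum proportional to 1/f^(2H+2) —
    the spectral density of a two-dimensional fBm surface, so the pairwise
    increment scaling E|I(p)-I(q)| ~ d^H holds with the target H.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    freq = np.hypot(fx, fy)
    amp = np.zeros_like(freq)
    nz = freq > 0
    amp[nz] = freq[nz] ** (-(hurst + 1.0))
    noise = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    field = np.real(np.fft.ifft2(amp * noise))
    sd = field.std()
    return field / sd if sd > 0 else field


def _radial_profile(params: LesionParams, rng: np.random.Generator) -> np.ndarray:
    """The perturbation s(theta) on a dense angular grid: a dominant wave
    with ``spiculation_count`` lobes plus random harmonic jitter, low-passed
    at the ``boundary_smoothness`` harmonic and scaled to max |s| = 1."""
    n = _BOUNDARY_POINTS
    if params.spiculation_amplitude == 0.0 or params.spiculation_count == 0:
        return np.zeros(n)
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    s = np.cos(params.spiculation_count * theta + phase)
    s = s + 0.5 * rng.normal(size=n)
    spec = np.fft.rfft(s)
    spec[params.boundary_smoothness + 1 :] = 0.0  # low-pass on harmonics
    spec[0] = 0.0  # zero-mean perturbation
    s = np.fft.irfft(spec, n)
    peak = np.max(np.abs(s))
    return s / peak if peak > 0 else s


def generate_lesion(params: LesionParams) -> tuple[np.ndarray, np.ndarray, str]:
    """Generate one lesion patch.

    Returns (image, boundary, label): an 8-bit grayscale patch, the closed
    mass outline as an ordered (x, y) point list, and the class label.
    Identical params (including seed) reproduce bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.patch_size
    center = n / 2.0

    s = _radial_profile(params, rng)
    theta = np.linspace(0.0, 2.0 * np.pi, _BOUNDARY_POINTS, endpoint=False)
    radius = params.base_radius * (1.0 + params.spiculation_amplitude * s)
    xs = center + radius * np.cos(theta)
    ys = center + radius * np.sin(theta)
    boundary = np.column_stack([xs, ys])

    mask = contour_to_mask(boundary, (n, n))

    background = params.background_level + 6.0 * _smooth_noise((n, n), rng)
    interior = (
        params.background_level
        + _MASS_LEVEL_OFFSET
        + params.texture_contrast * fbm_texture((n, n), params.texture_hurst, rng)
    )
    image = np.where(mask, interior, background)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, boundary, params.label


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Low-frequency unit-variance noise for the surrounding tissue."""
    return fbm_texture(shape, 0.8, rng)


@dataclasses.dataclass
class SyntheticDataset:
    """A generated study cohort: one (image, boundary, label) per mass."""

    samples: list[tuple[np.ndarray, np.ndarray, str]]
    class_counts: tuple[int, int]  # (n_benign, n_malignant)
    master_seed: int

    def __len__(self) -> int:
        return len(self.samples)

    def to_lesion_samples(self) -> list[LesionSample]:
        out = []
        for image, boundary, label in self.samples:
            mask = contour_to_mask(boundary, image.shape)
            out.append(crop_roi(image, mask, label=label))
        return out


def sample_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed, independent of generation order."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def _jitter(preset: LesionParams, seed: int) -> LesionParams:
    """Per-sample variation around a class preset, drawn from the sample's
    own stream.  The jitter widths are deliberately large enough that the
    class-conditional distributions of spiculation amplitude, Hurst exponent
    and contrast overlap at the margins — mass cohorts contain borderline
    lesions, and a phantom benchmark should too."""
    rng = np.random.default_rng(seed ^ 0x5EED)
    radius = preset.base_radius * rng.uniform(0.8, 1.2)
    count = max(0, preset.spiculation_count + rng.integers(-2, 3))
    amplitude = preset.spiculation_amplitude * rng.uniform(0.5, 1.5)
    hurst = float(np.clip(preset.texture_hurst + rng.uniform(-0.15, 0.15), 0.05, 0.95))
    contrast = preset.texture_contrast * rng.uniform(0.7, 1.3)
    return dataclasses.replace(
        preset, base_radius=radius, spiculation_count=int(count),
        spiculation_amplitude=amplitude, texture_hurst=hurst,
        texture_contrast=contrast, seed=seed,
    )


def generate_dataset(
    n_benign: int,
    n_malignant: int,
    presets: dict[str, LesionParams] | None = None,
    master_seed: int = 7,
) -> SyntheticDataset:
    """Generate a labeled cohort of n_benign + n_malignant lesions."""
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("class counts must be >= 0")
    presets = presets or DEFAULT_PRESETS
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    samples = []
    for idx, label in enumerate(labels):
        params = _jitter(presets[label], sample_seed(master_seed, idx))
        samples.append(generate_lesion(params))
    return SyntheticDataset(
        samples=samples, class_counts=(n_benign, n_malignant), master_seed=master_seed
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write PNG patches, boundary annotation files and a manifest table.

    Returns the manifest path.  Manifest columns: sample_id, image path,
    annotation path, label.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, (image, boundary, label) in enumerate(dataset.samples):
        sid = f"mass_{idx:04d}"
        img_path = out_dir / f"{sid}.png"
        ann_path = out_dir / f"{sid}.txt"
        Image.fromarray(image, mode="L").save(img_path)
        mio.write_annotation(
            AnnotationRecord(sample_id=sid, boundary=boundary, label=label), ann_path
        )
        rows.append(
            {"sample_id": sid, "image": img_path.name, "annotation": ann_path.name,
             "label": label}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# --------------------------------------------------------------------------- #
# Synthetic feature tables (for the selection/classification stages)
# --------------------------------------------------------------------------- #


def generate_signal_table(
    n_benign: int = 50,
    n_malignant: int = 50,
    n_signal: int = 6,
    effect_size: float = 2.56,
    seed: int = 0,
) -> tuple[FeatureTable, np.ndarray]:
    """A 125-column Gaussian feature table with ``n_signal`` informative
    features among pure noise.

    The class-mean shift of each signal feature is effect_size/sqrt(n_signal)
    so the pooled Mahalanobis separation is ``effect_size`` (the default
    2.56 puts the Bayes accuracy near 0.9).  Signal positions are drawn at
    random.  Returns (table, signal feature indices, 0-based).
    """
    rng = np.random.default_rng(seed)
    n_features = len(mio.feature_catalog())
    n = n_benign + n_malignant
    values = rng.normal(size=(n, n_features))
    y = np.array([0] * n_benign + [1] * n_malignant)
    signal_idx = rng.choice(n_features, size=n_signal, replace=False)
    shift = effect_size / np.sqrt(n_signal)
    values[:, signal_idx] += shift * y[:, None]
    labels = np.where(y == 1, "malignant", "benign").astype(object)
    table = FeatureTable(
        values=values, labels=labels,
        sample_ids=[f"s{i:03d}" for i in range(n)],
    )
    return table, np.sort(signal_idx)
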