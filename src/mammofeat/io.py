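"""Readers/writers for annotations, feature tables, rankings and run configuration.

The central contract of this module is the *feature catalog*: the fixed,
ordered list of 125 named features (F1..F125) that every extraction run
emits and every table/ranking refers to.  Column order is immutable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

LABELS = ("benign", "malignant")

# --------------------------------------------------------------------------- #
# Feature catalog
# --------------------------------------------------------------------------- #


@dataclasses.dataclass(frozen=True)
class CatalogEntry:
    """One feature of the F1..F125 battery."""

    index: int  # 1-based catalog position, the "k" of "Fk"
    name: str  # short name as used in result tables ("ASM", "FD26", ...)
    model: str  # feature model the entry belongs to ("SGLCM", "Shape", ...)

    @property
    def fid(self) -> str:
        return f"F{self.index}"

    @property
    def column_id(self) -> str:
        """Unique table-column identifier (names alone repeat across models)."""
        return f"F{self.index}_{self.name.replace(' ', '_').replace('.', '')}"


_SGLCM_NAMES = [
    "ASM", "Contrast", "Correlation", "Sum squares", "Inverse diff moment",
    "Sum average", "Sum variance", "Sum entropy", "Entropy", "Diff variance",
    "Diff entropy", "Info measure1", "Info measure2", "Max Corr Coff",
]
_GLDS_NAMES = ["Homogeneity", "Contrast", "Mean", "Energy", "Entropy"]
_FOS_NAMES = ["Mean", "Variance", "Skewness", "Kurtosis"]
_SFM_NAMES = ["Coarseness", "Contrast", "Periodicity", "Roughness"]
LAWS_MASK_NAMES = [
    "EE", "SS", "WW", "RR", "EL", "SL", "WL", "RL",
    "SE", "WE", "RE", "WS", "RS", "RW",
]
_FRACTAL_NAMES = ["H1", "H2"]
_FPS_NAMES = ["Sr", "Stheta"]
_SHAPE_NAMES = [
    "Area", "Major axis length", "Minor axis length", "Eccentricity",
    "Orientation", "Convex area", "Filled area", "Euler number",
    "Equiv diameter", "Solidity", "Extent", "Perimeter", "Perimeter cirratio",
]

# Zernike (n, m) order pairs: n = 0..4, |m| <= n, n - |m| even, signed m.
ZERNIKE_ORDERS: tuple[tuple[int, int], ...] = tuple(
    (n, m) for n in range(5) for m in range(-n, n + 1) if (n - abs(m)) % 2 == 0
)
assert len(ZERNIKE_ORDERS) == 15

# Generic Fourier descriptor grid: R radial x T angular frequencies = 52.
GFD_RADIAL = 4
GFD_ANGULAR = 13


def _zernike_name(n: int, m: int) -> str:
    return f"ZM{n}{m}" if m >= 0 else f"ZM{n}-{abs(m)}"


def _build_catalog() -> tuple[CatalogEntry, ...]:
    entries: list[CatalogEntry] = []

    def add(names: Iterable[str], model: str) -> None:
        for name in names:
            entries.append(CatalogEntry(len(entries) + 1, name, model))

    add(_SGLCM_NAMES, "SGLCM")
    add(_GLDS_NAMES, "GLDS")
    add(_FOS_NAMES, "FOS")
    add(_SFM_NAMES, "SFM")
    add(LAWS_MASK_NAMES, "LTEM")
    add(_FRACTAL_NAMES, "Fractal")
    add(_FPS_NAMES, "FPS")
    add(_SHAPE_NAMES, "Shape")
    add((_zernike_name(n, m) for n, m in ZERNIKE_ORDERS), "Zernike")
    add((f"FD{i}" for i in range(1, GFD_RADIAL * GFD_ANGULAR + 1)), "GFD")
    return tuple(entries)


_CATALOG: tuple[CatalogEntry, ...] = _build_catalog()


def feature_catalog() -> tuple[CatalogEntry, ...]:
    """The fixed ordered catalog of the 125 texture + geometry features.

    Positions 1-45 are texture (SGLCM, GLDS, FOS, SFM, LTEM, Fractal, FPS),
    46-125 geometry (shape descriptors, Zernike moment magnitudes, generic
    Fourier descriptors).
    """
    return _CATALOG


def catalog_columns() -> list[str]:
    return [e.column_id for e in _CATALOG]


def catalog_entry(fid: str | int) -> CatalogEntry:
    """Look up a catalog entry by 1-based index or "Fk" identifier."""
    k = int(str(fid).lstrip("Ff"))
    if not 1 <= k <= len(_CATALOG):
        raise KeyError(f"no catalog feature {fid!r}")
    return _CATALOG[k - 1]


# --------------------------------------------------------------------------- #
# Annotations
# --------------------------------------------------------------------------- #


class AnnotationError(ValueError):
    pass


@dataclasses.dataclass
class AnnotationRecord:
    """A lesion boundary: ordered (x, y) pixel coordinates plus a class label.

    The polygon is closed implicitly; on disk the first point is repeated as
    the last line.  At least 3 distinct vertices are required.
    """

    sample_id: str
    boundary: np.ndarray  # (n, 2) float array of (x, y) = (col, row)
    label: str

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise AnnotationError("boundary must be an (n, 2) point array")
        pts = self.boundary
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise AnnotationError("boundary needs at least 3 distinct points")
        self.boundary = pts
        if self.label not in LABELS:
            raise AnnotationError(f"label must be one of {LABELS}")


def write_annotation(record: AnnotationRecord, path: str | Path) -> None:
    """One "x,y" coordinate per line, last point repeating the first;
    a leading "# label: ..." header carries the class."""
    path = Path(path)
    pts = np.vstack([record.boundary, record.boundary[:1]])
    lines = [f"# sample_id: {record.sample_id}", f"# label: {record.label}"]
    lines += [f"{x:.6g},{y:.6g}" for x, y in pts]
    path.write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> AnnotationRecord:
    path = Path(path)
    sample_id = path.stem
    label = None
    points: list[tuple[float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("label:"):
                label = body.split(":", 1)[1].strip()
            elif body.startswith("sample_id:"):
                sample_id = body.split(":", 1)[1].strip()
            continue
        parts = line.split(",")
        try:
            x, y = float(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise AnnotationError(
                f"{path}: cannot parse coordinate line {lineno}: {raw!r}"
            ) from exc
        points.append((x, y))
    if label is None:
        raise AnnotationError(f"{path}: missing '# label:' header")
    return AnnotationRecord(sample_id=sample_id, boundary=np.array(points), label=label)


# --------------------------------------------------------------------------- #
# Feature tables
# --------------------------------------------------------------------------- #


class SchemaError(ValueError):
    pass


@dataclasses.dataclass
class FeatureTable:
    """Per-lesion feature matrix with the fixed 125-column catalog schema.

    ``values`` is (n_samples, 125) in catalog order; ``labels`` holds the
    per-sample class; ``sample_ids`` names the rows.
    """

    values: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(_CATALOG):
            raise SchemaError(
                f"feature table must have {len(_CATALOG)} columns, "
                f"got shape {self.values.shape}"
            )
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.values) or len(self.sample_ids) != len(self.values):
            raise SchemaError("labels/sample_ids length must match row count")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise SchemaError("feature table contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def y(self) -> np.ndarray:
        """Numeric class coding, benign = 0, malignant = 1."""
        return (self.labels == "malignant").astype(int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=catalog_columns())
        df.insert(0, "sample_id", self.sample_ids)
        df["label"] = self.labels
        return df


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    expected = ["sample_id", *catalog_columns(), "label"]
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: header does not match the {len(_CATALOG)}-feature catalog"
        )
    return FeatureTable(
        values=df[catalog_columns()].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=object),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


# --------------------------------------------------------------------------- #
# Rankings
# --------------------------------------------------------------------------- #


def write_ranking(ranking, path: str | Path) -> None:
    """Delimited (rank, feature index, feature name, score, method) table."""
    rows = []
    for rank, idx in enumerate(ranking.order, start=1):
        entry = _CATALOG[idx]
        rows.append(
            {
                "rank": rank,
                "feature_index": entry.fid,
                "feature_name": entry.name,
                "score": ranking.scores[idx],
                "method": ranking.method,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ranking(path: str | Path):
    from .selection import FeatureRanking  # local import: avoid cycle

    df = pd.read_csv(path)
    order = np.array([int(f.lstrip("F")) - 1 for f in df["feature_index"]])
    scores = np.zeros(len(_CATALOG))
    scores[order] = df["score"].to_numpy(dtype=float)
    return FeatureRanking(method=str(df["method"].iloc[0]), order=order, scores=scores)


# --------------------------------------------------------------------------- #
# Run configuration
# --------------------------------------------------------------------------- #


@dataclasses.dataclass
class RunConfig:
    """All tunables of one analysis run.

    Defaults reproduce the standard pipeline: 115 synthetic lesions
    (52 benign / 63 malignant), 32 gray levels for the co-occurrence family,
    Relief-F selection of the top 20, cosine k-NN (k=5, squared inverse
    distance weights) under 10x10 stratified cross-validation, and a forward
    subset search capped at 9 features.
    """

    n_benign: int = 52
    n_malignant: int = 63
    master_seed: int = 7
    glcm_levels: int = 32
    selection_method: str = "relief_f"
    top_k: int = 20
    max_subset_size: int = 9
    knn_variant: str = "best"
    cv_folds: int = 10
    cv_repeats: int = 10
    cv_seed: int = 1234
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        valid_methods = {"relief_f", "pearson", "nca", "term_variance"}
        if self.selection_method not in valid_methods:
            raise ValueError(f"selection_method must be one of {sorted(valid_methods)}")


def read_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
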