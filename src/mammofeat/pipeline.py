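"""End-to-end orchestration: generate -> extract -> select -> evaluate.

Every stage consumes seeds derived from the run configuration; rerunning a
config reproduces byte-identical numeric outputs.  The compact-subset stage
replaces a manual feature-subset choice with a deterministic greedy forward
search over the top-ranked candidates.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import io as mio
from .classify import KNN_PRESETS, CVResult, forward_subset_search, repeated_stratified_cv
from .geometry import compute_geometry_features
from .io import FeatureTable, RunConfig
from .roi import contour_to_mask, crop_roi
from .selection import RANKERS, FeatureRanking, SelectorConfig, select_top_k
from .synthetic import generate_dataset, write_dataset
from .texture import compute_texture_features

logger = logging.getLogger("mammofeat")


class ExtractionError(RuntimeError):
    pass


def extract_features(sample, levels: int = 32) -> np.ndarray:
    """The full 125-feature vector of one lesion, catalog order."""
    tex = compute_texture_features(sample, levels=levels)
    geo = compute_geometry_features(sample)
    return np.concatenate([tex, geo])


def extract_table(samples, sample_ids=None, levels: int = 32) -> FeatureTable:
    """Feature table from in-memory lesion samples."""
    rows, labels, ids = [], [], []
    for i, sample in enumerate(samples):
        rows.append(extract_features(sample, levels=levels))
        labels.append(sample.label)
        ids.append(sample_ids[i] if sample_ids else f"mass_{i:04d}")
    values = np.array(rows) if rows else np.empty((0, len(mio.feature_catalog())))
    return FeatureTable(values=values, labels=np.array(labels, dtype=object), sample_ids=ids)


def run_extraction(manifest_path: str | Path, config: RunConfig) -> FeatureTable:
    """Extract the 125-feature battery for every manifest row.

    Any per-sample failure aborts the run, naming the sample — no silent
    drops.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    samples, ids = [], []
    for _, row in manifest.iterrows():
        sid = str(row["sample_id"])
        try:
            image = np.asarray(Image.open(base / row["image"]).convert("L"))
            record = mio.read_annotation(base / row["annotation"])
            mask = contour_to_mask(record.boundary, image.shape)
            samples.append(crop_roi(image, mask, label=str(row["label"])))
            ids.append(sid)
        except FileNotFoundError as exc:
            raise ExtractionError(f"sample {sid}: missing file {exc.filename}") from exc
        except Exception as exc:
            raise ExtractionError(f"sample {sid}: {exc}") from exc
    logger.info("extracting features for %d lesions", len(samples))
    return extract_table(samples, sample_ids=ids, levels=config.glcm_levels)


def run_selection_comparison(
    table: FeatureTable, config: RunConfig
) -> tuple[dict[str, FeatureRanking], dict[str, CVResult]]:
    """Rank with all four filter methods; evaluate each method's top-k
    subset with the best k-NN variant under repeated stratified CV."""
    sel_cfg = SelectorConfig(seed=config.master_seed)
    knn = KNN_PRESETS[config.knn_variant]
    rankings: dict[str, FeatureRanking] = {}
    results: dict[str, CVResult] = {}
    for method in RANKERS:
        ranking = RANKERS[method](table, sel_cfg)
        rankings[method] = ranking
        subset = select_top_k(ranking, min(config.top_k, len(ranking.order)))
        results[method] = repeated_stratified_cv(
            table, subset, knn, folds=config.cv_folds,
            repeats=config.cv_repeats, master_seed=config.cv_seed,
        )
        logger.info("%s top-%d: %.1f%% accuracy", method, config.top_k,
                    results[method].mean_accuracy)
    return rankings, results


def run_incremental_curve(
    table: FeatureTable, ranking: FeatureRanking, config: RunConfig
) -> pd.DataFrame:
    """Evaluate every prefix of the ranking up to top_k features.

    Row 1 is the top feature alone; row k the top-k subset.
    """
    knn = KNN_PRESETS[config.knn_variant]
    rows = []
    for size in range(1, min(config.top_k, len(ranking.order)) + 1):
        subset = ranking.order[:size]
        res = repeated_stratified_cv(
            table, subset, knn, folds=config.cv_folds,
            repeats=config.cv_repeats, master_seed=config.cv_seed,
        )
        entry = mio.feature_catalog()[subset[-1]]
        rows.append(
            {"n_features": size, "added_feature": entry.fid,
             "added_name": entry.name, **res.summary()}
        )
    return pd.DataFrame(rows)


def permutation_null_accuracy(
    table: FeatureTable,
    subset,
    config: RunConfig,
    n_permutations: int = 3,
) -> float:
    """Mean CV accuracy after randomly permuting the class labels — the
    chance-level reference for the pipeline's real accuracies."""
    knn = KNN_PRESETS[config.knn_variant]
    rng = np.random.default_rng(config.master_seed + 9001)
    accs = []
    for _ in range(n_permutations):
        permuted = FeatureTable(
            values=table.values,
            labels=rng.permutation(np.asarray(table.labels)),
            sample_ids=list(table.sample_ids),
        )
        res = repeated_stratified_cv(
            table=permuted, feature_subset=subset, cfg=knn,
            folds=config.cv_folds, repeats=config.cv_repeats,
            master_seed=config.cv_seed,
        )
        accs.append(res.mean_accuracy)
    return float(np.mean(accs))


@dataclasses.dataclass
class AnalysisReport:
    """Everything one full run produces."""

    table: FeatureTable
    rankings: dict[str, FeatureRanking]
    method_results: dict[str, CVResult]
    full_result: CVResult
    top_k_result: CVResult
    curve: pd.DataFrame
    subset: list[int]
    subset_result: CVResult

    def subset_names(self) -> list[str]:
        catalog = mio.feature_catalog()
        return [f"{catalog[i].fid} {catalog[i].name}" for i in self.subset]


def run_full_analysis(config: RunConfig, out_dir: str | Path | None = None) -> AnalysisReport:
    """The complete analysis on the synthetic cohort.

    Generates the cohort, extracts all 125 features, compares the four
    selection methods at top-k, traces the incremental accuracy curve of
    the configured method, and runs the forward subset search over its
    top-k candidates.  Writes all artifacts under ``out_dir`` when given.
    """
    dataset = generate_dataset(
        config.n_benign, config.n_malignant, master_seed=config.master_seed
    )
    logger.info("generated %d synthetic lesions", len(dataset))
    table = extract_table(dataset.to_lesion_samples(), levels=config.glcm_levels)

    rankings, method_results = run_selection_comparison(table, config)
    knn = KNN_PRESETS[config.knn_variant]
    cv_kwargs = dict(folds=config.cv_folds, repeats=config.cv_repeats,
                     master_seed=config.cv_seed)

    full_result = repeated_stratified_cv(table, None, knn, **cv_kwargs)
    ranking = rankings[config.selection_method]
    top = select_top_k(ranking, min(config.top_k, len(ranking.order)))
    top_k_result = method_results[config.selection_method]
    curve = run_incremental_curve(table, ranking, config)
    subset, subset_result = forward_subset_search(
        table, top, knn, max_size=config.max_subset_size, **cv_kwargs
    )

    report = AnalysisReport(
        table=table, rankings=rankings, method_results=method_results,
        full_result=full_result, top_k_result=top_k_result, curve=curve,
        subset=list(map(int, subset)), subset_result=subset_result,
    )
    if out_dir is not None:
        _write_report(report, config, Path(out_dir), dataset)
    return report


def _write_report(report: AnalysisReport, config: RunConfig, out_dir: Path, dataset) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, out_dir / "dataset")
    mio.write_feature_table(report.table, out_dir / "features.csv")
    for method, ranking in report.rankings.items():
        mio.write_ranking(ranking, out_dir / f"ranking_{method}.csv")
    comparison = pd.DataFrame(
        [{"method": m, **r.summary()} for m, r in report.method_results.items()]
    )
    comparison.to_csv(out_dir / "selection_comparison.csv", index=False)
    report.curve.to_csv(out_dir / "incremental_curve.csv", index=False)
    summary = pd.DataFrame(
        [
            {"feature_set": "all_125", "n_features": report.table.values.shape[1],
             **report.full_result.summary()},
            {"feature_set": f"top_{config.top_k}_{config.selection_method}",
             "n_features": min(config.top_k, report.table.values.shape[1]),
             **report.top_k_result.summary()},
            {"feature_set": "compact_subset", "n_features": len(report.subset),
             **report.subset_result.summary()},
        ]
    )
    summary.to_csv(out_dir / "summary.csv", index=False)
    (out_dir / "compact_subset.txt").write_text(
        "\n".join(report.subset_names()) + "\n"
    )
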