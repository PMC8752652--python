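import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammofeat.classify import (
    EPS_WEIGHT,
    KNN_PRESETS,
    KNNConfig,
    confusion_metrics,
    forward_subset_search,
    knn_predict,
    repeated_stratified_cv,
)
from mammofeat.io import FeatureTable


def brute_force_knn(train_x, train_y, query, cfg):
    """Independent per-query oracle: explicit distance formulas, explicit
    sorting with index tie-break, explicit voting."""
    preds = []
    for q in np.atleast_2d(query):
        pairs = []
        for i, t in enumerate(train_x):
            if cfg.metric == "euclidean":
                d = np.sqrt(np.sum((q - t) ** 2))
            elif cfg.metric == "cubic":
                d = np.sum(np.abs(q - t) ** 3) ** (1 / 3)
            else:
                na, nb = np.linalg.norm(q), np.linalg.norm(t)
                d = 1.0 if na == 0 or nb == 0 else 1.0 - float(q @ t) / (na * nb)
            pairs.append((d, i))
        pairs.sort()
        k = min(cfg.k, len(pairs))
        nn = [i for _, i in pairs[:k]]
        classes = sorted(set(train_y))
        if cfg.weighting == "uniform":
            votes = {c: sum(train_y[i] == c for i in nn) for c in classes}
            best = max(votes.values())
            tied = [c for c in classes if votes[c] == best]
            preds.append(tied[0] if len(tied) == 1 else train_y[nn[0]])
        else:
            score = {
                c: sum(
                    1.0 / (pairs[j][0] ** 2 + EPS_WEIGHT)
                    for j in range(k)
                    if train_y[pairs[j][1]] == c
                )
                for c in classes
            }
            preds.append(max(classes, key=lambda c: score[c]))
    return np.array(preds)


def make_cv_table(n_per_class, n_informative=4, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    vals = rng.normal(size=(n, 125))
    y = np.array([0] * n_per_class + [1] * n_per_class)
    vals[:, :n_informative] += gap * y[:, None]
    labels = np.where(y == 1, "malignant", "benign").astype(object)
    return FeatureTable(vals, labels, [f"s{i}" for i in range(n)])


class TestKnnPredict:
    def test_coincident_point_wins_at_k1(self):
        x = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array(["benign", "malignant"])
        cfg = KNNConfig(k=1, metric="euclidean", weighting="uniform")
        assert knn_predict(x, y, [[5.0, 5.0]], cfg)[0] == "malignant"

    def test_squared_inverse_hand_weights(self):
        """Neighbors at distances 1 (A) and 2 (B): weights 1 vs 0.25 -> A."""
        x = np.array([[1.0, 0.0], [2.0, 0.0]])
        y = np.array(["A", "B"])
        cfg = KNNConfig(k=2, metric="euclidean", weighting="squared_inverse_distance")
        assert knn_predict(x, y, [[0.0, 0.0]], cfg)[0] == "A"

    def test_cosine_scale_invariance(self):
        x = np.array([[1.0, 2.0], [-3.0, 1.0]])
        y = np.array(["A", "B"])
        cfg = KNNConfig(k=1, metric="cosine", weighting="uniform")
        assert knn_predict(x, y, [[10.0, 20.0]], cfg)[0] == "A"

    def test_k_exceeding_train_clamps_with_warning(self):
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array(["A", "A", "B"])
        cfg = KNNConfig(k=10, metric="euclidean", weighting="uniform")
        with pytest.warns(UserWarning):
            pred = knn_predict(x, y, [[0.5]], cfg)
        assert pred[0] == "A"

    def test_k_equals_n_uniform_predicts_majority(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 4))
        y = np.array(["A"] * 18 + ["B"] * 12)
        cfg = KNNConfig(k=30, metric="euclidean", weighting="uniform")
        pred = knn_predict(x, y, rng.normal(size=(20, 4)), cfg)
        assert np.all(pred == "A")

    @pytest.mark.parametrize(
        "metric, weighting",
        list(itertools.product(
            ("euclidean", "cosine", "cubic"),
            ("uniform", "squared_inverse_distance"),
        )),
    )
    def test_matches_brute_force_oracle(self, metric, weighting):
        rng = np.random.default_rng(7)
        train = rng.normal(size=(30, 5))
        y = np.array(["benign"] * 15 + ["malignant"] * 15)
        query = rng.normal(size=(200, 5))
        cfg = KNNConfig(k=5, metric=metric, weighting=weighting)
        np.testing.assert_array_equal(
            knn_predict(train, y, query, cfg), brute_force_knn(train, y, query, cfg)
        )


class TestConfusionMetrics:
    def test_worked_example(self):
        y_true = np.array(["malignant"] * 10 + ["benign"] * 10)
        y_pred = np.array(
            ["malignant"] * 9 + ["benign"] * 1 + ["benign"] * 8 + ["malignant"] * 2
        )
        acc, sens, spec = confusion_metrics(y_true, y_pred)
        assert (acc, sens, spec) == (85.0, 90.0, 80.0)

    def test_perfect_and_inverted(self):
        y = np.array(["malignant", "benign", "malignant", "benign"])
        assert confusion_metrics(y, y) == (100.0, 100.0, 100.0)
        inv = np.where(y == "benign", "malignant", "benign")
        assert confusion_metrics(y, inv) == (0.0, 0.0, 0.0)

    def test_no_positives_rejected(self):
        y = np.array(["benign", "benign"])
        with pytest.raises(ValueError):
            confusion_metrics(y, y)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_accuracy_identity(self, seed):
        """accuracy = (sens*P + spec*N) / (P+N) holds exactly."""
        rng = np.random.default_rng(seed)
        y_true = np.array(["benign", "malignant"])[rng.integers(0, 2, 30)]
        if len(set(y_true)) < 2:
            y_true[0], y_true[1] = "benign", "malignant"
        y_pred = np.array(["benign", "malignant"])[rng.integers(0, 2, 30)]
        acc, sens, spec = confusion_metrics(y_true, y_pred)
        p = np.sum(y_true == "malignant")
        n = np.sum(y_true == "benign")
        assert acc == pytest.approx((sens * p + spec * n) / (p + n))


class TestRepeatedStratifiedCV:
    def test_separated_classes_high_accuracy(self):
        for seed in (1, 2, 3):
            table = make_cv_table(60, seed=seed)
            res = repeated_stratified_cv(
                table, list(range(4)), KNN_PRESETS["best"], repeats=3, master_seed=seed
            )
            assert res.mean_accuracy >= 95.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(5):
            table = make_cv_table(60, gap=0.0, seed=rng.integers(2**31))
            res = repeated_stratified_cv(
                table, None, KNN_PRESETS["best"], repeats=2, master_seed=0
            )
            accs.append(res.mean_accuracy)
        assert 40.0 <= np.mean(accs) <= 60.0

    def test_deterministic(self):
        table = make_cv_table(20, seed=4)
        r1 = repeated_stratified_cv(table, None, KNN_PRESETS["best"], repeats=2)
        r2 = repeated_stratified_cv(table, None, KNN_PRESETS["best"], repeats=2)
        np.testing.assert_array_equal(r1.accuracy, r2.accuracy)
        np.testing.assert_array_equal(r1.sensitivity, r2.sensitivity)

    def test_too_few_per_class_rejected(self):
        table = make_cv_table(5)
        with pytest.raises(ValueError, match="folds"):
            repeated_stratified_cv(table, None, KNN_PRESETS["best"], folds=10)


class TestForwardSearch:
    def _table_with_label_feature(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        y = np.array([0, 1] * (n // 2))
        vals = rng.normal(size=(n, 125))
        vals[:, 5] = y + 0.01 * rng.normal(size=n)
        labels = np.where(y == 1, "malignant", "benign").astype(object)
        return FeatureTable(vals, labels, [f"s{i}" for i in range(n)])

    def test_label_feature_selected_first(self):
        table = self._table_with_label_feature()
        subset, _ = forward_subset_search(
            table, [2, 5, 9, 14], KNN_PRESETS["best"], max_size=3,
            folds=5, repeats=2,
        )
        assert subset[0] == 5

    def test_duplicate_informative_feature_enters_once(self):
        table = self._table_with_label_feature()
        table.values[:, 9] = table.values[:, 5]
        subset, _ = forward_subset_search(
            table, [5, 9, 2], KNN_PRESETS["best"], max_size=3, folds=5, repeats=2
        )
        assert (5 in subset) != (9 in subset)

    def test_result_at_least_full_candidate_accuracy(self):
        table = make_cv_table(30, n_informative=3, gap=1.0, seed=9)
        candidates = list(range(12))
        subset, res = forward_subset_search(
            table, candidates, KNN_PRESETS["best"], max_size=5, folds=5, repeats=2,
            master_seed=77,
        )
        full = repeated_stratified_cv(
            table, candidates, KNN_PRESETS["best"], folds=5, repeats=2, master_seed=77
        )
        assert res.mean_accuracy >= full.mean_accuracy
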