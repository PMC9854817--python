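"""Evaluation protocol: splitting, contingency tables, ROC/AUC, experiments."""

import numpy as np
import pytest

from ramandx import (
    ConfusionMatrix,
    confusion,
    generate_dataset,
    metrics_from_cm,
    preprocess_set,
    roc_auc,
    run_binary_experiments,
    run_full_experiment,
    stratified_split,
)
from ramandx.errors import ConfigError, DataError
from ramandx.evaluate import CLASS_PAIRS, ModelGrids
from ramandx.cnn import CNNSpec

from conftest import small_generator_config


def _labels(counts: dict[str, int]) -> np.ndarray:
    out = []
    for cls, n in counts.items():
        out += [cls] * n
    return np.array(out, dtype=object)


class TestStratifiedSplit:
    def test_study_design_counts(self):
        labels = _labels({"HC": 241, "BC": 463, "DCIS": 100})
        split = stratified_split(labels, train_frac=0.7, seed=0)
        assert split.per_class_counts == {
            "HC": (168, 73), "BC": (324, 139), "DCIS": (70, 30)
        }
        assert split.n_train == 562 and split.n_test == 242

    def test_half_split_of_ten(self):
        split = stratified_split(_labels({"HC": 10}), train_frac=0.5, seed=1)
        assert split.per_class_counts == {"HC": (5, 5)}

    def test_partition_is_exact_and_seeded(self):
        labels = _labels({"HC": 20, "BC": 30, "DCIS": 11})
        a = stratified_split(labels, 0.7, seed=9)
        b = stratified_split(labels, 0.7, seed=9)
        assert np.array_equal(a.train_indices, b.train_indices)
        assert np.array_equal(a.test_indices, b.test_indices)
        union = np.sort(np.concatenate([a.train_indices, a.test_indices]))
        assert np.array_equal(union, np.arange(labels.size))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ConfigError):
            stratified_split(_labels({"HC": 10}), train_frac=1.0, seed=0)
        with pytest.raises(DataError):
            stratified_split(_labels({"HC": 10, "DCIS": 1}), 0.7, seed=0)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = _labels({"HC": 3, "BC": 5, "DCIS": 2})
        cm = confusion(y, y, ("HC", "BC", "DCIS"))
        assert np.array_equal(cm.counts, np.diag([3, 5, 2]))

    def test_constant_predictor_fills_one_column(self):
        y = _labels({"HC": 4, "BC": 6})
        pred = np.array(["BC"] * 10, dtype=object)
        cm = confusion(y, pred, ("HC", "BC"))
        assert np.array_equal(cm.counts, [[0, 4], [0, 6]])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        order = ("HC", "BC", "DCIS")
        y_true = np.array(order, dtype=object)[rng.integers(0, 3, 200)]
        y_pred = np.array(order, dtype=object)[rng.integers(0, 3, 200)]
        cm = confusion(y_true, y_pred, order)
        oracle = np.zeros((3, 3), dtype=int)
        for t, p in zip(y_true, y_pred):
            oracle[order.index(t), order.index(p)] += 1
        assert np.array_equal(cm.counts, oracle)

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            confusion(["HC"], ["BC"], ("HC", "DCIS"))


class TestMetrics:
    def test_identity_matrix_gives_perfect_metrics(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 5]]), ("HC", "BC"))
        rep = metrics_from_cm(cm, positive_class="BC")
        assert rep.accuracy == 1.0 and rep.misdiagnoses == 0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_accuracy_equals_direct_agreement_rate(self):
        rng = np.random.default_rng(3)
        order = ("HC", "BC", "DCIS")
        y_true = np.array(order, dtype=object)[rng.integers(0, 3, 500)]
        y_pred = np.array(order, dtype=object)[rng.integers(0, 3, 500)]
        rep = metrics_from_cm(confusion(y_true, y_pred, order))
        assert rep.accuracy == pytest.approx(np.mean(y_true == y_pred), abs=1e-12)

    def test_zero_true_row_flags_undefined_rate(self):
        cm = ConfusionMatrix(np.array([[4, 1], [0, 0]]), ("HC", "BC"))
        rep = metrics_from_cm(cm, positive_class="BC")
        assert np.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined


class TestRocAuc:
    def test_perfect_separation_gives_unit_auc(self):
        y = np.array(["HC"] * 5 + ["BC"] * 5, dtype=object)
        scores = np.zeros((10, 2))
        scores[:, 1] = np.concatenate([np.linspace(0, 0.4, 5), np.linspace(0.6, 1, 5)])
        scores[:, 0] = 1 - scores[:, 1]
        rep = roc_auc(scores, y, ("HC", "BC"), positive_class="BC")
        assert rep.auc == 1.0

    def test_label_independent_scores_give_half_auc(self):
        """Monte-Carlo: with scores independent of labels, AUC -> 0.5."""
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.array(["HC", "BC"], dtype=object)[rng.integers(0, 2, 2000)]
            s = rng.uniform(size=(2000, 1))
            scores = np.hstack([1 - s, s])
            aucs.append(roc_auc(scores, y, ("HC", "BC"), positive_class="BC").auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_binary_auc_equals_mann_whitney_statistic(self):
        """Brute-force pair-counting oracle on a 12-sample ranking."""
        rng = np.random.default_rng(8)
        y = np.array(["HC"] * 5 + ["BC"] * 7, dtype=object)
        s = rng.uniform(size=12)
        scores = np.column_stack([1 - s, s])
        rep = roc_auc(scores, y, ("HC", "BC"), positive_class="BC")
        pos, neg = s[5:], s[:5]
        wins = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        assert rep.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_three_class_auc_is_macro_ovr_average(self):
        rng = np.random.default_rng(9)
        order = ("HC", "BC", "DCIS")
        y = np.array(order, dtype=object)[rng.integers(0, 3, 90)]
        raw = rng.uniform(size=(90, 3))
        scores = raw / raw.sum(axis=1, keepdims=True)
        rep = roc_auc(scores, y, order)
        from sklearn.metrics import roc_auc_score

        per_class = [
            roc_auc_score((y == c).astype(int), scores[:, i]) for i, c in enumerate(order)
        ]
        assert rep.auc == pytest.approx(np.mean(per_class), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(DataError):
            roc_auc(np.ones((3, 2)) / 2, np.array(["HC"] * 3, dtype=object), ("HC", "BC"))


def _small_grids(epochs=6):
    return ModelGrids(
        k_grid=(1, 3),
        n_trees_grid=(20,),
        depth_grid=(None,),
        c_grid=(1.0, 10.0),
        gamma_grid=(0.1, 1.0),
        cnn=CNNSpec(input_len=256, epochs=epochs),
        cnn_cv=False,
    )


@pytest.fixture(scope="module")
def report():
    cfg = small_generator_config(seed=5)
    return run_full_experiment(generator=cfg, grids=_small_grids(), seed=5)


class TestExperiments:

    def test_report_structure_complete(self, report):
        assert set(report["three_class"]) == {"KNN", "RF", "SVM", "CNN"}
        assert set(report["binary"]) == {"HC_vs_BC", "HC_vs_DCIS", "BC_vs_DCIS"}
        for pair in report["binary"].values():
            assert set(pair) == {"KNN", "RF", "SVM", "CNN"}
        assert len(report["history"]["train_loss"]) == 6

    def test_accuracies_are_fractions(self, report):
        for res in report["three_class"].values():
            assert 0.0 <= res["accuracy"] <= 1.0
            assert 0.0 <= res["auc"] <= 1.0

    def test_three_class_row_sums_match_test_counts(self, report):
        per_class = report["split"]["per_class"]
        for res in report["three_class"].values():
            rows = np.array(res["confusion"]).sum(axis=1)
            expected = [per_class[c][1] for c in res["class_order"]]
            assert list(rows) == expected

    def test_binary_tasks_keep_pair_ordering_and_counts(self, report):
        assert list(report["binary"]) == [f"{a}_vs_{b}" for a, b in CLASS_PAIRS]
        for key, pair in report["binary"].items():
            first, second = key.split("_vs_")
            for res in pair.values():
                rows = np.array(res["confusion"]).sum(axis=1)
                assert rows[0] == report["split"]["per_class"][first][1]
                assert rows[1] == report["split"]["per_class"][second][1]
                assert res["positive_class"] == second

    def test_perfect_binary_matrix_means_perfect_metrics(self, report):
        for pair in report["binary"].values():
            for res in pair.values():
                cm = np.array(res["confusion"])
                if np.all(cm == np.diag(np.diag(cm))):
                    assert res["sensitivity"] == 1.0
                    assert res["specificity"] == 1.0
                    assert res["accuracy"] == 1.0

    def test_binary_experiments_reuse_main_partition(self):
        cfg = small_generator_config(seed=6)
        data = preprocess_set(generate_dataset(cfg))
        split = stratified_split(data.labels, 0.7, seed=6)
        results = run_binary_experiments(
            data, split, families=("KNN",), grids=_small_grids(), seed=6
        )
        hc_dcis = results["HC_vs_DCIS"]["KNN"]
        counts = split.per_class_counts
        rows = np.array(hc_dcis["confusion"]).sum(axis=1)
        assert rows[0] == counts["HC"][1] and rows[1] == counts["DCIS"][1]
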