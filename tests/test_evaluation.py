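"""Scenario parsing, confusion matrices, metric equations and the
scenario runner's structural contracts."""

import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score

from ictalnet.evaluation import (
    SCENARIO_CATALOGUE,
    ablation,
    build_scenario,
    confusion,
    featurize,
    metrics,
    run_scenario,
)


class TestBuildScenario:
    def test_merged_binary_groups(self):
        spec = build_scenario("FN-S")
        assert spec.n_labels == 2
        assert spec.groups[0] == frozenset("FN")
        assert spec.groups[1] == frozenset("S")
        assert spec.labels == ("FN", "S")

    def test_five_class_is_singletons(self):
        spec = build_scenario("F-N-O-Z-S")
        assert spec.n_labels == 5
        assert all(len(g) == 1 for g in spec.groups)

    def test_en_dash_and_case_accepted(self):
        assert build_scenario("fn–oz–s").labels == ("FN", "OZ", "S")

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_scenario("FS-S")

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            build_scenario("Q-S")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_scenario("FNOZS")

    def test_catalogue_all_parse(self):
        assert len(SCENARIO_CATALOGUE) == 15
        for name in SCENARIO_CATALOGUE:
            build_scenario(name)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion([0, 1, 2, 1], [0, 1, 2, 1], 3)
        np.testing.assert_array_equal(cm, np.diag([1, 2, 1]))

    def test_hand_counted_example(self):
        cm = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 2]])

    def test_total_is_sample_count(self, rng):
        y1, y2 = rng.integers(0, 4, (2, 100))
        assert confusion(y1, y2, 4).sum() == 100

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1], 2)


class TestMetrics:
    def test_perfect_binary_classifier(self):
        rep = metrics(np.array([[50, 0], [0, 50]]))
        assert rep.accuracy == rep.f1 == rep.precision == rep.recall == 100.0

    def test_binary_hand_computed(self):
        # TP=50, TN=40, FP=5, FN=5 with class 1 positive
        rep = metrics(np.array([[40, 5], [5, 50]]))
        assert rep.accuracy == pytest.approx(90.0)
        assert rep.precision == pytest.approx(100 * 50 / 55)
        assert rep.recall == pytest.approx(100 * 50 / 55)
        assert rep.f1 == pytest.approx(100 * 50 / 55)

    def test_accuracy_is_trace_over_total(self, rng):
        cm = rng.integers(0, 30, (4, 4))
        cm += np.eye(4, dtype=int)  # ensure support everywhere
        rep = metrics(cm)
        assert rep.accuracy == pytest.approx(100 * np.trace(cm) / cm.sum())

    def test_f1_between_min_and_max_of_precision_recall(self, rng):
        for _ in range(20):
            cm = rng.integers(0, 30, (2, 2)) + 1
            rep = metrics(cm)
            assert min(rep.precision, rep.recall) - 1e-9 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-9

    def test_macro_averages_match_sklearn(self, rng):
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        rep = metrics(confusion(y_true, y_pred, 3))
        assert rep.precision == pytest.approx(
            100 * precision_score(y_true, y_pred, average="macro", zero_division=0)
        )
        assert rep.recall == pytest.approx(
            100 * recall_score(y_true, y_pred, average="macro")
        )

    def test_metrics_from_matrix_equal_metrics_from_labels(self, rng):
        """Brute-force oracle: per-class sensitivity recomputed directly
        from the label lists."""
        y_true = rng.integers(0, 3, 300)
        y_pred = rng.integers(0, 3, 300)
        rep = metrics(confusion(y_true, y_pred, 3), class_names=["A", "B", "C"])
        for k, name in enumerate(["A", "B", "C"]):
            mask = y_true == k
            expected = 100 * np.mean(y_pred[mask] == k)
            assert rep.sensitivity[name] == pytest.approx(expected)

    def test_zero_support_class_excluded_with_warning(self):
        cm = np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]])
        with pytest.warns(RuntimeWarning, match="zero support"):
            rep = metrics(cm, class_names=["a", "b", "c"])
        assert np.isnan(rep.sensitivity["c"])
        assert np.isfinite(rep.precision)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.zeros((2, 2), dtype=int))


class TestScenarioRunner:
    def test_binary_scenario_on_separable_classes(self, tiny_dataset, tiny_config):
        res = run_scenario(tiny_dataset, "Z-S", tiny_config)
        assert res.confusion.shape == (2, 2)
        assert res.confusion.sum() == res.n_test
        assert 0 <= res.report.accuracy <= 100

    def test_five_class_confusion_shape(self, tiny_dataset, tiny_config):
        res = run_scenario(tiny_dataset, "F-N-O-Z-S", tiny_config)
        assert res.confusion.shape == (5, 5)
        assert set(res.report.sensitivity) == {"Z", "O", "N", "F", "S"}

    def test_same_seed_reproduces_result(self, tiny_dataset, tiny_config):
        a = run_scenario(tiny_dataset, "Z-S", tiny_config)
        b = run_scenario(tiny_dataset, "Z-S", tiny_config)
        assert a.report == b.report
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_missing_class_rejected(self, tiny_dataset, tiny_config):
        partial = {k: v for k, v in tiny_dataset.items() if k != "S"}
        with pytest.raises(ValueError, match="lacks records"):
            run_scenario(partial, "Z-S", tiny_config)

    def test_window_count_and_label_conservation(self, tiny_dataset, tiny_config):
        from ictalnet.windowing import count_windows

        feat = featurize(tiny_dataset, "Z-S", tiny_config)
        per_class = count_windows(3 * 4097, tiny_config.window)
        assert feat.windows.shape[0] == 2 * per_class
        assert np.bincount(feat.labels).tolist() == [per_class, per_class]
        # every window in exactly one split
        both = np.concatenate([feat.train_idx, feat.test_idx])
        assert np.array_equal(np.sort(both), np.arange(feat.windows.shape[0]))

    def test_record_level_split_separates_source_records(self, tiny_dataset, tiny_config):
        cfg = tiny_config.with_(split="record")
        feat = featurize(tiny_dataset, "Z-S", cfg)
        assert feat.train_idx.size > 0 and feat.test_idx.size > 0
        res = run_scenario(tiny_dataset, "Z-S", cfg, featurized=feat)
        assert res.confusion.sum() == feat.test_idx.size


class TestAblation:
    def test_three_arms_share_the_split(self, tiny_dataset, tiny_config):
        results = ablation(tiny_dataset, tiny_config, scenario="Z-S")
        assert set(results) == {"latent", "stats", "fused"}
        checksums = {r.split_checksum for r in results.values()}
        assert len(checksums) == 1

    def test_arm_feature_widths_differ(self, tiny_dataset, tiny_config):
        # structural check via confusion totals: all arms evaluate the
        # same number of held-out windows
        results = ablation(tiny_dataset, tiny_config, scenario="Z-S")
        totals = {r.confusion.sum() for r in results.values()}
        assert len(totals) == 1
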