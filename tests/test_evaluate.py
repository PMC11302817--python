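import numpy as np
import pytest

from cylqa.evaluate import (CLASS_NAMES, binary_compare, build_report,
                            confusion_matrix, gpr_distributions,
                            metrics_from_confusion, roc_auc)
from cylqa.gamma import CLINICAL_CRITERIA, GammaCriteria, GammaResult
from cylqa.simulate import ErrorClass

from oracles import binary_metrics_by_hand, mann_whitney_auc


class TestConfusionMatrix:
    def test_counts(self):
        cm = confusion_matrix([0, 1, 2, 2], [0, 2, 2, 1], n_classes=3)
        assert cm.tolist() == [[1, 0, 0], [0, 0, 1], [0, 1, 1]]
        assert cm.sum() == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])


class TestMetricsFromConfusion:
    def test_perfect_diagonal(self):
        cm = np.eye(5, dtype=int) * 15
        m = metrics_from_confusion(cm)
        assert m == {"accuracy": 1.0, "precision": 1.0,
                     "recall": 1.0, "f1": 1.0}

    def test_binary_hand_computed(self):
        # TP=3 FP=1 FN=1 TN=5, rows (neg, pos) x cols (neg, pos)
        cm = np.array([[5, 1], [1, 3]])
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_degenerate_classifier_convention(self):
        cm = np.array([[10, 0], [10, 0]])  # never predicts positive
        with pytest.warns(UserWarning, match="precision"):
            m = metrics_from_confusion(cm)
        assert m["precision"] == 0.0
        assert m["recall"] == 0.0
        assert m["f1"] == 0.0
        assert m["accuracy"] == 0.5

    def test_matches_hand_formulas_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(0, 20, 4)
            if tp + fp + fn + tn == 0:
                continue
            cm = np.array([[tn, fp], [fn, tp]])
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics_from_confusion(cm)
            acc, pre, rec, f1 = binary_metrics_by_hand(tp, fp, fn, tn)
            assert m["accuracy"] == pytest.approx(acc)
            assert m["precision"] == pytest.approx(pre)
            assert m["recall"] == pytest.approx(rec)
            assert m["f1"] == pytest.approx(f1)

    def test_f1_harmonic_mean_identity(self):
        cm = np.array([[7, 3], [2, 8]])
        m = metrics_from_confusion(cm)
        expected = 2 * m["precision"] * m["recall"] \
            / (m["precision"] + m["recall"])
        assert m["f1"] == pytest.approx(expected, abs=1e-12)

    def test_balanced_accuracy_equals_macro_recall(self):
        rng = np.random.default_rng(1)
        y_true = np.repeat(np.arange(5), 15)
        y_pred = np.where(rng.random(75) < 0.7, y_true,
                          rng.integers(0, 5, 75))
        cm = confusion_matrix(y_true, y_pred)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(m["recall"], abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((2, 2), dtype=int))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        auc, _, _ = roc_auc(scores, labels, positive_class=1)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 0] * 5)
        auc, _, _ = roc_auc(scores, labels, positive_class=1)
        assert auc == pytest.approx(0.5)

    def test_three_quarters_fixture(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([1, 0, 1, 0])
        auc, _, _ = roc_auc(scores, labels, positive_class=1)
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.integers(0, 2, n)
        # discretized scores force ties to exercise rank-averaging
        scores = np.round(rng.random(n) + 0.3 * labels, 1)
        auc, _, _ = roc_auc(scores, labels, positive_class=1)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels, 1),
                                    abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]), 1)


class TestGprDistributions:
    def test_noise_free_normals_all_pass(self, tiny_dataset):
        normals = [s for s in tiny_dataset
                   if s.label.error_class == ErrorClass.NORMAL]
        out = gpr_distributions(normals, CLINICAL_CRITERIA)
        for crit in CLINICAL_CRITERIA:
            summary = out["normal"][crit.label]
            assert summary["min"] == summary["max"] == 100.0

    def test_noise_free_dose_errors_all_pass_3_3(self, tiny_dataset):
        dosed = [s for s in tiny_dataset
                 if s.label.error_class == ErrorClass.DOSE]
        out = gpr_distributions(dosed, [CLINICAL_CRITERIA[0]])
        summary = out["dose"]["3%/3 mm"]
        assert summary["min"] == 100.0

    def test_permutation_invariance(self, tiny_dataset):
        subset = [s for s in tiny_dataset
                  if s.label.error_class == ErrorClass.NORMAL]
        a = gpr_distributions(subset, [CLINICAL_CRITERIA[0]])
        b = gpr_distributions(subset[::-1], [CLINICAL_CRITERIA[0]])
        assert a == b


def _fake_results(samples, fail_mask, criteria):
    """GammaResults failing exactly where fail_mask is set."""
    out = []
    for fail in fail_mask:
        gpr = 50.0 if fail else 100.0
        out.append(GammaResult(gamma_map=np.zeros((21, 66)), gpr=gpr,
                               n_analyzed=100,
                               passed=gpr > criteria.pass_rate_threshold,
                               criteria=criteria))
    return out


class TestBinaryCompare:
    def test_all_pass_gpr_blind_to_dose(self, tiny_dataset):
        crit = CLINICAL_CRITERIA[0]
        subset = [s for s in tiny_dataset
                  if s.label.error_class in (ErrorClass.NORMAL,
                                             ErrorClass.DOSE)]
        y = np.array([int(s.label.error_class) for s in subset])
        results = {crit.label: _fake_results(subset, [False] * len(subset),
                                             crit)}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = binary_compare(y, subset, results, [crit])
        row = table[(table.pairing == "dose vs normal")
                    & (table.method == crit.label)].iloc[0]
        assert row.accuracy == pytest.approx(0.5)
        assert row.recall == 0.0
        assert row.precision == 0.0

    def test_perfect_cnn_rows(self, tiny_dataset):
        crit = CLINICAL_CRITERIA[0]
        y = np.array([int(s.label.error_class) for s in tiny_dataset])
        results = {crit.label: _fake_results(
            tiny_dataset, [False] * len(tiny_dataset), crit)}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = binary_compare(y, tiny_dataset, results, [crit])
        cnn = table[table.method == "CNN"]
        assert (cnn[["accuracy", "precision", "recall", "f1"]] == 1.0) \
            .all().all()

    def test_oracle_gpr_classifier(self, tiny_dataset):
        # GPR fails exactly the couch plans -> perfect couch-vs-normal row
        crit = CLINICAL_CRITERIA[0]
        fails = [s.label.error_class == ErrorClass.COUCH
                 for s in tiny_dataset]
        y = np.array([int(s.label.error_class) for s in tiny_dataset])
        results = {crit.label: _fake_results(tiny_dataset, fails, crit)}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = binary_compare(y, tiny_dataset, results, [crit])
        row = table[(table.pairing == "couch vs normal")
                    & (table.method == crit.label)].iloc[0]
        assert (row.accuracy, row.precision, row.recall) == (1.0, 1.0, 1.0)

    def test_row_layout(self, tiny_dataset):
        y = np.array([int(s.label.error_class) for s in tiny_dataset])
        results = {c.label: _fake_results(tiny_dataset,
                                          [False] * len(tiny_dataset), c)
                   for c in CLINICAL_CRITERIA}
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = binary_compare(y, tiny_dataset, results,
                                   CLINICAL_CRITERIA)
        assert len(table[table.method == "CNN"]) == 5
        assert len(table[table.method != "CNN"]) == 15  # 5 pairings x 3


class TestBuildReport:
    def test_report_structure(self, tiny_dataset):
        rng = np.random.default_rng(0)
        y = np.array([int(s.label.error_class) for s in tiny_dataset])
        probs = np.full((len(tiny_dataset), 5), 0.025)
        probs[np.arange(len(y)), y] = 0.9  # near-perfect predictions
        probs /= probs.sum(axis=1, keepdims=True)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = build_report(probs, tiny_dataset, [CLINICAL_CRITERIA[0]])
        assert report.accuracy == 1.0
        assert report.normal_vs_error_auc == 1.0
        assert set(report.per_class_auc) == set(CLASS_NAMES)
        d = report.to_dict()
        assert d["confusion"][0][0] == 4
        import json
        json.dumps(d)  # must be JSON-serializable
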