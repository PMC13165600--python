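"""Evaluation metrics: confusion matrices, agreement, kappa, one-vs-all
ROC-AUC, per-class collapse and permutation importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from accelhar import (
    CLASS_ORDER,
    ConfusionMatrix,
    cohens_kappa,
    evaluate_predictions,
    per_class_metrics,
    percent_agreement,
    permutation_importance,
    roc_auc_ova,
)
from accelhar.evaluation import collapse_binary, plot_importance

# Published worked examples: hip-placement test-set confusion matrices
# (rows = predicted, columns = observed; class order walking, running,
# jumping) with the overall agreement/kappa they imply.
RF_COUNTS = [[480, 6, 10], [2, 163, 14], [9, 39, 799]]
SVM_COUNTS = [[480, 8, 20], [1, 185, 17], [10, 15, 786]]
KNN_COUNTS = [[482, 9, 35], [0, 185, 24], [9, 14, 764]]


def pairwise_auc_oracle(indicator, scores):
    """Brute-force AUC: concordant pairs plus half ties over all pairs."""
    positives = [s for s, y in zip(scores, indicator) if y == 1]
    negatives = [s for s, y in zip(scores, indicator) if y == 0]
    total = concordant = 0.0
    for p in positives:
        for n in negatives:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = [c for c in CLASS_ORDER for _ in range(10)]
        cm = ConfusionMatrix.from_labels(labels, labels)
        np.testing.assert_array_equal(cm.counts, np.diag([10, 10, 10]))

    def test_single_observation(self):
        cm = ConfusionMatrix.from_labels(["running"], ["jumping"])
        assert cm.counts.sum() == 1
        assert cm.counts[2, 1] == 1  # predicted jumping, observed running

    def test_published_column_percentages(self):
        cm = ConfusionMatrix(np.array(RF_COUNTS))
        pct = cm.column_percentages()
        assert round(pct[0, 0], 1) == 97.8
        assert round(pct[1, 1], 1) == 78.4
        assert round(pct[2, 2], 1) == 97.1
        assert cm.total == 1522
        np.testing.assert_allclose(pct.sum(axis=0), 100.0)

    def test_column_sums_are_observed_class_counts(self):
        rng = np.random.default_rng(1)
        observed = rng.choice(CLASS_ORDER, 60)
        predicted = rng.choice(CLASS_ORDER, 60)
        cm = ConfusionMatrix.from_labels(observed, predicted)
        for j, label in enumerate(CLASS_ORDER):
            assert cm.observed_totals[j] == (observed == label).sum()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside the class set"):
            ConfusionMatrix.from_labels(["walking"], ["swimming"])


class TestAgreementAndKappa:
    @pytest.mark.parametrize(
        "counts,agreement,kappa",
        [
            (RF_COUNTS, 94.7, 0.909),
            (SVM_COUNTS, 95.3, 0.920),
            (KNN_COUNTS, 94.0, 0.899),
        ],
    )
    def test_published_worked_examples(self, counts, agreement, kappa):
        cm = ConfusionMatrix(np.array(counts))
        assert round(percent_agreement(cm), 1) == agreement
        assert round(cohens_kappa(cm), 3) == kappa

    def test_degenerate_matrices(self):
        perfect = ConfusionMatrix(np.diag([5, 7, 9]))
        assert percent_agreement(perfect) == 100.0
        assert cohens_kappa(perfect) == pytest.approx(1.0)
        wrong = ConfusionMatrix(np.array([[0, 4, 0], [0, 0, 4], [4, 0, 0]]))
        assert percent_agreement(wrong) == 0.0

    def test_kappa_matches_sklearn_on_random_labelings(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            observed = rng.choice(CLASS_ORDER, 40)
            predicted = rng.choice(CLASS_ORDER, 40)
            cm = ConfusionMatrix.from_labels(observed, predicted)
            expected = cohen_kappa_score(observed, predicted, labels=list(CLASS_ORDER))
            assert cohens_kappa(cm) == pytest.approx(expected, abs=1e-12)

    def test_kappa_one_iff_perfect_agreement(self):
        rng = np.random.default_rng(4)
        observed = rng.choice(CLASS_ORDER, 50)
        predicted = observed.copy()
        predicted[0] = CLASS_ORDER[(list(CLASS_ORDER).index(predicted[0]) + 1) % 3]
        cm = ConfusionMatrix.from_labels(observed, predicted)
        assert cohens_kappa(cm) < 1.0

    def test_label_permutation_null_centers_kappa_on_zero(self):
        rng = np.random.default_rng(11)
        observed = rng.choice(CLASS_ORDER, 200, p=[0.3, 0.2, 0.5])
        kappas = []
        for _ in range(50):
            permuted = rng.permutation(observed)
            kappas.append(cohens_kappa(ConfusionMatrix.from_labels(observed, permuted)))
        kappas = np.asarray(kappas)
        se = kappas.std(ddof=1) / np.sqrt(len(kappas))
        assert abs(kappas.mean()) < 3 * se


class TestRocAuc:
    def test_one_hot_truth_gives_perfect_auc(self):
        observed = [c for c in CLASS_ORDER for _ in range(4)]
        proba = pd.get_dummies(pd.Series(observed)).astype(float)[list(CLASS_ORDER)]
        per_class, macro = roc_auc_ova(observed, proba)
        assert all(v == 1.0 for v in per_class.values())
        assert macro == 1.0

    def test_anti_ranked_scores_give_zero_auc(self):
        observed = ["walking"] * 4 + ["running"] * 4
        scores = np.zeros((8, 3))
        scores[:4, 0] = 0.0  # walking windows scored lowest for walking
        scores[4:, 0] = 1.0
        scores[:4, 1] = 1.0
        scores[4:, 1] = 0.0
        scores[:, 2] = 0.5
        with pytest.warns(UserWarning, match="jumping"):
            per_class, _ = roc_auc_ova(observed, scores)
        assert per_class["walking"] == 0.0
        assert per_class["running"] == 0.0
        assert "jumping" not in per_class

    def test_hand_written_toy_matches_pair_oracle(self):
        observed = ["walking", "running", "walking", "jumping", "running", "walking"]
        scores = np.array(
            [
                [0.7, 0.2, 0.1],
                [0.3, 0.5, 0.2],
                [0.6, 0.3, 0.1],
                [0.2, 0.3, 0.5],
                [0.4, 0.4, 0.2],
                [0.4, 0.4, 0.2],
            ]
        )
        per_class, macro = roc_auc_ova(observed, scores)
        for j, label in enumerate(CLASS_ORDER):
            indicator = [1 if o == label else 0 for o in observed]
            assert per_class[label] == pytest.approx(
                pairwise_auc_oracle(indicator, scores[:, j])
            )
        assert macro == pytest.approx(np.mean(list(per_class.values())))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        labels=st.lists(st.sampled_from(CLASS_ORDER), min_size=2, max_size=12),
        seed=st.integers(0, 1000),
    )
    def test_matches_pair_oracle_on_all_small_inputs(self, labels, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=(len(labels), 3))
        present = set(labels)
        if len(present) == 1:
            return  # no class has a defined one-vs-all AUC
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_class, _ = roc_auc_ova(labels, scores)
        for j, label in enumerate(CLASS_ORDER):
            if label not in per_class:
                continue
            indicator = [1 if o == label else 0 for o in labels]
            assert per_class[label] == pytest.approx(
                pairwise_auc_oracle(indicator, scores[:, j])
            )


class TestPerClassMetrics:
    def test_perfect_predictions(self):
        observed = [c for c in CLASS_ORDER for _ in range(5)]
        proba = pd.get_dummies(pd.Series(observed)).astype(float)[list(CLASS_ORDER)]
        cm = ConfusionMatrix.from_labels(observed, observed)
        metrics = per_class_metrics(cm, observed, proba)
        for label in CLASS_ORDER:
            assert metrics[label]["percent_agreement"] == 100.0
            assert metrics[label]["kappa"] == pytest.approx(1.0)
            assert metrics[label]["roc_auc"] == 1.0

    def test_published_binary_collapse_for_walking(self):
        cm = ConfusionMatrix(np.array(RF_COUNTS))
        binary = collapse_binary(cm, "walking")
        np.testing.assert_array_equal(binary.counts, [[480, 16], [11, 1015]])

    def test_constant_predictor_agreement_equals_prevalence(self):
        observed = ["walking"] * 3 + ["running"] * 5 + ["jumping"] * 2
        predicted = ["walking"] * 10
        cm = ConfusionMatrix.from_labels(observed, predicted)
        metrics = per_class_metrics(cm)
        assert metrics["walking"]["percent_agreement"] == pytest.approx(30.0)


class TestPermutationImportance:
    @staticmethod
    def _threshold_predictor(matrix):
        """1-feature rule: classify by mean_y level, ignoring everything else."""
        values = matrix["mean_y"].to_numpy()
        return np.where(values < 2.5, "walking", np.where(values < 7.5, "running", "jumping"))

    def _matrix(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.choice(CLASS_ORDER, n)
        level = {"walking": 0.0, "running": 5.0, "jumping": 10.0}
        return (
            pd.DataFrame(
                {
                    "mean_y": [level[l] + rng.normal(0, 0.1) for l in labels],
                    "sd_x": rng.normal(0, 1, n),
                }
            ),
            labels,
        )

    def test_predictive_feature_dominates_null_feature(self):
        matrix, labels = self._matrix()
        report = permutation_importance(
            self._threshold_predictor, matrix, labels, ["mean_y", "sd_x"], n_repeats=5, seed=1
        )
        assert report.iloc[0]["feature"] == "mean_y"
        assert report.iloc[0]["importance"] > 30.0

    def test_unused_feature_has_null_importance(self):
        matrix, labels = self._matrix(seed=2)
        report = permutation_importance(
            self._threshold_predictor, matrix, labels, ["sd_x"], n_repeats=10, seed=3
        )
        row = report.iloc[0]
        assert abs(row["importance"]) <= max(2 * row["sd"], 1e-12)

    def test_deterministic_given_seed(self):
        matrix, labels = self._matrix(seed=4)
        a = permutation_importance(
            self._threshold_predictor, matrix, labels, ["mean_y", "sd_x"], n_repeats=4, seed=9
        )
        b = permutation_importance(
            self._threshold_predictor, matrix, labels, ["mean_y", "sd_x"], n_repeats=4, seed=9
        )
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_repeats_rejected(self):
        matrix, labels = self._matrix()
        with pytest.raises(ValueError, match="n_repeats"):
            permutation_importance(
                self._threshold_predictor, matrix, labels, ["mean_y"], n_repeats=0
            )

    def test_plot_importance_returns_axis(self):
        frame = pd.DataFrame(
            {"feature": ["a", "b"], "importance": [2.0, 1.0], "sd": [0.1, 0.1]}
        )
        ax = plot_importance(frame, top=2)
        assert ax.get_xlabel().startswith("Decrease")


class TestEvaluateReport:
    def test_report_structure_and_bounds(self):
        rng = np.random.default_rng(21)
        observed = rng.choice(CLASS_ORDER, 90)
        proba = rng.dirichlet([1, 1, 1], size=90)
        predicted = np.asarray(CLASS_ORDER, dtype=object)[np.argmax(proba, axis=1)]
        report = evaluate_predictions(observed, predicted, proba)
        assert 0 <= report.percent_agreement <= 100
        assert 0 <= report.roc_auc <= 1
        assert -1 <= report.kappa <= 1
        payload = report.to_dict()
        assert set(payload["per_class"]) == set(CLASS_ORDER)
        assert payload["confusion"]["total"] == 90

    def test_metrics_invariant_to_sample_order(self):
        rng = np.random.default_rng(22)
        observed = rng.choice(CLASS_ORDER, 60)
        proba = rng.dirichlet([1, 1, 1], size=60)
        predicted = np.asarray(CLASS_ORDER, dtype=object)[np.argmax(proba, axis=1)]
        order = rng.permutation(60)
        a = evaluate_predictions(observed, predicted, proba)
        b = evaluate_predictions(observed[order], predicted[order], proba[order])
        assert a.percent_agreement == pytest.approx(b.percent_agreement)
        assert a.kappa == pytest.approx(b.kappa)
        assert a.roc_auc == pytest.approx(b.roc_auc)
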