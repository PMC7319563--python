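"""Validation machinery: folds, metrics against textbook formulas, Fisher test,
and the end-to-end protocol loop."""

import numpy as np
import pandas as pd
import pytest

from memstab.evaluate import (
    CrossValProtocol,
    classification_metrics,
    fisher_r_to_z,
    make_folds,
    regression_metrics,
    run_protocol,
)


# ---------------------------------------------------------------------------
# independent textbook-formula oracles (kept deliberately naive)

def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def spearman_oracle(x, y):
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    return pearson_oracle(ranks(x), ranks(y))


def kendall_taub_oracle(x, y):
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    return (concordant - discordant) / np.sqrt((n0 - tx) * (n0 - ty))


def mcc_oracle(true, pred, positive):
    tp = np.sum((true == positive) & (pred == positive))
    tn = np.sum((true != positive) & (pred != positive))
    fp = np.sum((true != positive) & (pred == positive))
    fn = np.sum((true == positive) & (pred != positive))
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return ((tp * tn) - (fp * fn)) / denom if denom else 0.0


def f1_oracle(true, pred, positive):
    tp = np.sum((true == positive) & (pred == positive))
    fp = np.sum((true != positive) & (pred == positive))
    fn = np.sum((true == positive) & (pred != positive))
    return 2 * tp / (2 * tp + fp + fn)


def auc_oracle(true, scores, positive):
    """Mann–Whitney pair counting (equals the trapezoidal ROC area)."""
    pos = np.asarray(scores)[np.asarray(true) == positive]
    neg = np.asarray(scores)[np.asarray(true) != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert (m["pearson"], m["spearman"], m["kendall"], m["rmse"]) == (1, 1, 1, 0)

    def test_kendall_on_three_points(self):
        m = regression_metrics([1, 2, 3], [1, 3, 2])
        assert m["kendall"] == pytest.approx((2 - 1) / 3)

    def test_matches_textbook_formulas_on_random_fixture(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        m = regression_metrics(x, y)
        assert m["pearson"] == pytest.approx(pearson_oracle(x, y), abs=1e-10)
        assert m["spearman"] == pytest.approx(spearman_oracle(x, y), abs=1e-10)
        assert m["kendall"] == pytest.approx(kendall_taub_oracle(x, y), abs=1e-10)
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean((x - y) ** 2)), abs=1e-10)

    def test_zero_variance_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="zero variance"):
            regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        true = np.array(["benign"] * 5 + ["pathogenic"] * 5)
        scores = np.r_[np.zeros(5), np.ones(5)]
        m = classification_metrics(true, true, scores, positive_label="pathogenic")
        assert (m["mcc"], m["f1"], m["auc"]) == (1.0, 1.0, 1.0)

    def test_blind_test_shaped_confusion_matrix(self):
        true = np.array(["pathogenic"] * 38 + ["benign"] * 16)
        m = classification_metrics(true, true, positive_label="pathogenic")
        assert m["mcc"] == 1.0

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(7)
        true = np.where(rng.random(100) > 0.4, "pathogenic", "benign")
        scores = rng.normal(size=100) + (true == "pathogenic")
        pred = np.where(scores > 0.5, "pathogenic", "benign")
        m = classification_metrics(true, pred, scores, positive_label="pathogenic")
        assert m["mcc"] == pytest.approx(mcc_oracle(true, pred, "pathogenic"), abs=1e-10)
        assert m["f1"] == pytest.approx(f1_oracle(true, pred, "pathogenic"), abs=1e-10)
        assert m["auc"] == pytest.approx(auc_oracle(true, scores, "pathogenic"), abs=1e-10)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(11)
        true = np.array(["a", "b"] * 500)
        scores = rng.normal(size=1000)
        m = classification_metrics(true, true, scores, positive_label="b")
        assert m["auc"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            classification_metrics(["a"] * 5, ["a"] * 5)


class TestFisherRtoZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_r_to_z(0.5, 100, 0.5, 200)
        assert z == 0.0 and p == 1.0

    def test_significant_difference_at_published_sample_size(self):
        _, p = fisher_r_to_z(0.72, 342, 0.48, 342)
        assert p < 0.05

    def test_matches_direct_formula(self):
        r1, n1, r2, n2 = 0.63, 150, 0.41, 220
        z, p = fisher_r_to_z(r1, n1, r2, n2)
        z_direct = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        from scipy.stats import norm

        assert z == pytest.approx(z_direct, abs=1e-12)
        assert p == pytest.approx(2 * norm.sf(abs(z_direct)), abs=1e-12)

    def test_antisymmetry(self):
        z1, p1 = fisher_r_to_z(0.7, 100, 0.3, 100)
        z2, p2 = fisher_r_to_z(0.3, 100, 0.7, 100)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z(1.0, 100, 0.5, 100)
        with pytest.raises(ValueError):
            fisher_r_to_z(0.5, 3, 0.5, 100)


class TestMakeFolds:
    def test_balanced_singletons_stratify_exactly(self):
        labels = np.array(["a", "b"] * 10)
        folds = make_folds(labels, np.arange(20), n_folds=10, seed=0)
        for k in range(10):
            assert sorted(labels[folds == k]) == ["a", "b"]

    def test_pairs_never_split(self):
        # 30 groups of 2 records each
        groups = np.repeat(np.arange(30), 2)
        labels = np.tile(["a", "b"], 30)[:60]
        folds = make_folds(labels, groups, n_folds=5, seed=3)
        for g in np.unique(groups):
            assert len(np.unique(folds[groups == g])) == 1

    def test_seed_determinism_and_variation(self):
        labels = np.array(["a", "b"] * 20)
        groups = np.arange(40)
        f1 = make_folds(labels, groups, 10, seed=1)
        f2 = make_folds(labels, groups, 10, seed=1)
        f3 = make_folds(labels, groups, 10, seed=2)
        np.testing.assert_array_equal(f1, f2)
        assert (f1 != f3).any()

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            make_folds(["a", "b"] * 3, [0, 0, 1, 1, 2, 2], n_folds=10)


class TestRunProtocol:
    def test_noiseless_linear_data_recovers(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(300, 5)), columns=[f"f{i}" for i in range(5)])
        y = (X["f0"] + 0.5 * X["f1"]).to_numpy()
        report = run_protocol(
            X, y, np.arange(300), task="stability",
            protocol=CrossValProtocol(10, 1), seed=1,
        )
        assert report.per_repetition[0]["pearson"] >= 0.95

    def test_bookkeeping_covers_every_record_each_repetition(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 80)
        protocol = CrossValProtocol(n_folds=5, repetitions=3)
        report = run_protocol(X, y, np.arange(80), task="stability", protocol=protocol, seed=2,
                              hyperparams={"n_estimators": 30})
        assert len(report.per_repetition) == 3
        assert len(report.fold_assignments) == 3
        for folds in report.fold_assignments:
            assert sorted(np.unique(folds)) == list(range(5))
            assert len(folds) == 80

    def test_shuffled_targets_have_no_signal(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"f{i}" for i in range(5)])
        y = (X["f0"] + 0.5 * X["f1"]).to_numpy()
        y_shuffled = rng.permutation(y)
        report = run_protocol(
            X, y_shuffled, np.arange(200), task="stability",
            protocol=CrossValProtocol(10, 1), seed=4, hyperparams={"n_estimators": 100},
        )
        assert abs(report.per_repetition[0]["pearson"]) <= 0.15

    def test_summary_mean_and_sd(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.normal(0, 0.2, 100)
        report = run_protocol(
            X, y, np.arange(100), task="stability",
            protocol=CrossValProtocol(5, 2), seed=6, hyperparams={"n_estimators": 30},
        )
        mean, sd = report.summary["pearson"]
        vals = [rep["pearson"] for rep in report.per_repetition]
        assert mean == pytest.approx(np.mean(vals))
        assert sd == pytest.approx(np.std(vals, ddof=1))
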