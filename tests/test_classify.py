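import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from autofluor.classify import (make_folds, roc_auc, run_automl_backend,
                                run_comparison, summarize_fold_aucs,
                                train_rf_and_score)
from autofluor.errors import ValidationError
from autofluor.model import FeatureTable
from autofluor.benchmarks import gaussian_shift_table


def brute_force_auc(scores, labels, positive):
    """Oracle: pairwise concordance counting with ties worth 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _table(n_per_class=10, seed=0, delta=0.0, n_features=2):
    return gaussian_shift_table(delta=delta, n_per_class=n_per_class, seed=seed)


class TestMakeFolds:
    def test_even_cell_folds(self):
        table = _table(5)
        plan = make_folds(table, n_folds=5)
        sizes = [len(plan.test_ids(f)) for f in range(5)]
        assert sizes == [2] * 5
        # stratified: one cell of each class per fold
        lab = dict(zip(table.cell_ids, table.labels))
        for f in range(5):
            assert sorted(lab[c] for c in plan.test_ids(f)) == ["A", "B"]

    def test_patient_grouping_keeps_patients_whole(self):
        table = _table(30)
        plan = make_folds(table, n_folds=5, grouping="patient", seed=3)
        pat = dict(zip(table.cell_ids, table.patient_ids))
        fold_of_patient = {}
        for cid, f in plan.assignment.items():
            fold_of_patient.setdefault(pat[cid], set()).add(f)
        assert all(len(folds) == 1 for folds in fold_of_patient.values())

    def test_deterministic_under_seed(self):
        table = _table(12)
        assert make_folds(table, seed=9).assignment == make_folds(table, seed=9).assignment

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(_table(2), n_folds=5)


class TestRocAuc:
    def test_perfect_and_inverted_scores(self):
        labels = np.array(["A"] * 4 + ["B"] * 4)
        scores = (labels == "B").astype(float)
        _, auc = roc_auc(scores, labels, positive_label="B")
        assert auc == 1.0
        _, auc = roc_auc(1 - scores, labels, positive_label="B")
        assert auc == 0.0

    def test_tie_convention(self):
        _, auc = roc_auc([0.2, 0.2], ["A", "B"], positive_label="B")
        assert auc == 0.5

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(77)
        for _ in range(500):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[:2] = [0, 1]
            scores = np.round(rng.normal(size=n), int(rng.integers(0, 3)))
            _, auc = roc_auc(scores, labels, positive_label=1)
            assert auc == pytest.approx(brute_force_auc(scores, labels, 1), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)
        _, auc = roc_auc(scores, labels, positive_label=1)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_curve_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(6)
        labels = np.array([0, 1] * 10)
        pts, _ = roc_auc(rng.normal(size=20), labels, positive_label=1)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], ["A", "A"])


class TestRandomForest:
    def test_separable_data_perfect_auc(self):
        table = _table(20, delta=8.0)
        tr = FeatureTable(table.data.iloc[::2])
        te = FeatureTable(table.data.iloc[1::2])
        scores = train_rf_and_score(tr, te, ["shift_feature"], "B", seed=0)
        _, auc = roc_auc(scores, te.labels, positive_label="B")
        assert auc == 1.0

    def test_degenerate_training_set_rejected(self):
        table = _table(10, delta=1.0)
        tr = FeatureTable(table.data[table.data.group_label == "A"])
        with pytest.raises(ValidationError, match="one class"):
            train_rf_and_score(tr, table, ["shift_feature"], "B", seed=0)

    def test_memorized_duplicate_scores_its_own_class(self):
        table = _table(20, delta=6.0)
        tr = table
        dup = FeatureTable(table.data.iloc[[0]])  # class A training cell
        scores = train_rf_and_score(tr, dup, ["shift_feature"], "B", seed=0)
        assert scores[0] < 0.5


class TestBackends:
    def test_unregistered_backend_reports_unavailable(self):
        table = _table(10, delta=2.0)
        scores, status = run_automl_backend(table, table, ["shift_feature"], "B",
                                            {"name": "nonexistent"})
        assert scores is None and "unavailable" in status

    def test_builtin_logistic_on_separable_data(self):
        table = _table(15, delta=8.0)
        scores, status = run_automl_backend(table, table, ["shift_feature"], "B",
                                            {"name": "logistic"})
        assert status == "ok:logistic"
        _, auc = roc_auc(scores, table.labels, positive_label="B")
        assert auc == 1.0


class TestRunComparison:
    def test_separable_cohort_unit_auc_zero_ci_width(self):
        table = _table(20, delta=10.0)
        res = run_comparison(table, "A", "B", selection_mode="global", k=1,
                             seed=0)["random_forest"]
        assert res.per_fold_auc == [1.0] * 5
        assert res.mean_auc == 1.0
        assert res.ci95 == (1.0, 1.0)

    def test_complement_symmetry_under_positive_label_swap(self):
        # the same scores evaluated with the opposite positive class give
        # exactly 1 - AUC, ties included
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = np.round(rng.normal(size=n), 1)
            _, auc_b = roc_auc(scores, labels, positive_label=1)
            _, auc_a = roc_auc(scores, labels, positive_label=0)
            assert auc_a == pytest.approx(1 - auc_b, abs=1e-12)

    def test_comparison_orientation_invariance(self):
        # swapping the argument order re-orients the scorer with it, so the
        # reported discrimination is identical
        table = _table(20, delta=1.0, seed=4)
        r1 = run_comparison(table, "A", "B", selection_mode="global", k=1,
                            seed=2)["random_forest"]
        r2 = run_comparison(table, "B", "A", selection_mode="global", k=1,
                            seed=2)["random_forest"]
        np.testing.assert_allclose(r1.per_fold_auc, r2.per_fold_auc, atol=1e-12)

    def test_fold_mode_never_selects_on_test_cells(self, mini_features):
        table, _ = mini_features
        res = run_comparison(table, "A", "B", selection_mode="fold",
                             seed=1)["random_forest"]
        all_cells = set(table.subset(["A", "B"]).cell_ids)
        for f, train_cells in enumerate(res.fold_train_cells):
            test_cells = all_cells - set(train_cells)
            assert test_cells  # nonempty fold
            assert not set(train_cells) & test_cells

    def test_constant_feature_does_not_move_auc(self):
        table = _table(25, delta=1.5, seed=8)
        aug = table.data.copy()
        aug["constant"] = 1.0
        table2 = FeatureTable(aug)
        shifts = []
        for seed in range(5):
            a = run_comparison(table, "A", "B", selection_mode="global", k=1,
                               seed=seed)["random_forest"].mean_auc
            b = run_comparison(table2, "A", "B", seed=seed, selection=None,
                               selection_mode="global", k=2)["random_forest"].mean_auc
            shifts.append(a - b)
        assert abs(np.mean(shifts)) < 0.02

    def test_backend_and_rf_reported_together(self):
        table = _table(15, delta=3.0)
        results = run_comparison(table, "A", "B", selection_mode="global", k=1,
                                 classifiers=("random_forest", "automl"),
                                 backend_config={"name": "logistic"}, seed=0)
        assert set(results) == {"random_forest", "automl"}
        assert results["automl"].classifier_id == "automl[logistic]"
        assert results["automl"].mean_auc > 0.9

    def test_missing_backend_degrades_gracefully(self):
        table = _table(15, delta=3.0)
        results = run_comparison(table, "A", "B", selection_mode="global", k=1,
                                 classifiers=("random_forest", "automl"),
                                 backend_config={"name": "ghost"}, seed=0)
        assert results["random_forest"].per_fold_auc
        assert results["automl"].per_fold_auc == []
        assert "unavailable" in results["automl"].status


def test_ci_formula_uses_t_with_four_dof():
    aucs = [0.8, 0.85, 0.9, 0.95, 1.0]
    mean, var, (lo, hi) = summarize_fold_aucs(aucs)
    from scipy.stats import t
    hw = t.ppf(0.975, 4) * np.sqrt(np.var(aucs, ddof=1) / 5)
    assert mean == pytest.approx(0.9)
    assert hi - mean == pytest.approx(hw)
    assert mean - lo == pytest.approx(hw)
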