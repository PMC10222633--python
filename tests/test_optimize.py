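import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_recall_fscore_support

from sri.core import WeightSet, quality_bin, sri_score
from sri.errors import ConfigurationError, DegenerateInputError, ValidationError
from sri.optimize import (
    ClassifierSpec,
    WeightGrid,
    class_weights,
    grid_search,
    kfold_cv,
    precision_recall_f1,
    stratified_split,
    train_eval,
    weight_grid,
)
from sri.synth import SynthTableSpec, synth_feature_table

TRUE_W = WeightSet(2.5, 1.0, -1.0, -3.0)
SUB_GRID = WeightGrid(
    c_plusplus=(2.0, 2.5, 3.0),
    c_plus=(0.5, 1.0, 1.5),
    c_minus=(-1.5, -1.0, -0.5),
    c_minusminus=(-4.0, -3.0, -2.5),
)


def make_table(seed=0, n=150, separation=6.0):
    return synth_feature_table(SynthTableSpec(
        n_recordings=n, true_weights=TRUE_W, class_separation=separation,
        seed=seed,
    ))


class TestWeightGrid:
    def test_default_grid_cardinality(self):
        grid = weight_grid()
        assert len(grid.c_plus) == 20
        assert len(grid.c_minus) == 20
        assert len(grid.c_plusplus) == 30
        assert len(grid.c_minusminus) == 30
        assert grid.n_combinations == 360_000

    def test_default_grid_boundaries(self):
        grid = weight_grid()
        assert grid.c_plusplus[0] == 2.0 and grid.c_plusplus[-1] == 4.9
        assert grid.c_plus[0] == 0.1 and grid.c_plus[-1] == 2.0
        assert grid.c_minus[0] == -2.0 and grid.c_minus[-1] == -0.1
        assert grid.c_minusminus[0] == -4.9 and grid.c_minusminus[-1] == -2.0

    def test_single_value_grid(self):
        grid = weight_grid(c_plusplus=(2.0, 2.0), c_plus=(1.0, 1.0),
                           c_minus=(-1.0, -1.0), c_minusminus=(-3.0, -3.0))
        assert grid.n_combinations == 1

    @pytest.mark.parametrize("sizes", [(2, 3, 4, 5), (1, 1, 1, 1), (7, 2, 3, 1)])
    def test_cardinality_matches_enumeration(self, sizes):
        vals = {
            "c_plusplus": tuple(2.0 + 0.1 * i for i in range(sizes[0])),
            "c_plus": tuple(0.1 + 0.1 * i for i in range(sizes[1])),
            "c_minus": tuple(-2.0 + 0.1 * i for i in range(sizes[2])),
            "c_minusminus": tuple(-4.0 + 0.1 * i for i in range(sizes[3])),
        }
        grid = WeightGrid(**vals)
        enumerated = list(grid.combinations())
        assert len(enumerated) == grid.n_combinations == int(np.prod(sizes))
        brute = set(itertools.product(*vals.values()))
        assert {(w.c_plusplus, w.c_plus, w.c_minus, w.c_minusminus)
                for w in enumerated} == brute

    def test_inconsistent_range_rejected(self):
        with pytest.raises(ConfigurationError):
            weight_grid(c_plus=(0.1, 0.15))
        with pytest.raises(ConfigurationError):
            weight_grid(step=-0.1)


class TestClassWeights:
    def test_balanced_case(self):
        labels = ["poor"] * 4 + ["medium"] * 4 + ["good"] * 4
        assert class_weights(labels) == {"poor": 1.0, "medium": 1.0, "good": 1.0}

    def test_two_class_example(self):
        labels = ["a"] * 25 + ["b"] * 75
        w = class_weights(labels)
        assert w["a"] == pytest.approx(2.0)
        assert w["b"] == pytest.approx(100 / (75 * 2))

    def test_weighted_supports_sum_to_total(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 50, size=rng.integers(2, 5))
            labels = sum(([f"c{i}"] * int(c) for i, c in enumerate(counts)), [])
            w = class_weights(labels)
            total = sum(counts)
            assert sum(w[f"c{i}"] * c for i, c in enumerate(counts)) == \
                pytest.approx(total)


class TestStratifiedSplit:
    def test_1220_items_split_976_244(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1220, 3))
        y = np.array((["poor"] * 500 + ["medium"] * 420 + ["good"] * 300))
        (Xtr, ytr), (Xte, yte) = stratified_split(X, y, 0.8, seed=1)
        assert len(ytr) == 976
        assert len(yte) == 244

    def test_class_proportions_preserved(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 2))
        y = np.array(["a"] * 50 + ["b"] * 30 + ["c"] * 20)
        (_, ytr), (_, yte) = stratified_split(X, y, 0.8, seed=0)
        for cls, n in (("a", 50), ("b", 30), ("c", 20)):
            assert abs((ytr == cls).sum() - 0.8 * n) <= 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 2))
        y = np.array(["a", "b", "c"] * 20)
        s1 = stratified_split(X, y, 0.8, seed=7)
        s2 = stratified_split(X, y, 0.8, seed=7)
        assert np.array_equal(s1[0][0], s2[0][0])
        assert np.array_equal(s1[1][1], s2[1][1])

    def test_singleton_class_goes_to_train(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((41, 2))
        y = np.array(["a"] * 20 + ["b"] * 20 + ["c"])
        (_, ytr), (_, yte) = stratified_split(X, y, 0.8, seed=0)
        assert (ytr == "c").sum() == 1
        assert (yte == "c").sum() == 0


class TestMetrics:
    def test_diagonal_matrix_perfect(self):
        m = precision_recall_f1(np.diag([5, 3, 2]), ("poor", "medium", "good"))
        assert m.macro_f1 == 1.0
        assert m.f1_sd == 0.0
        assert not m.undefined_flags

    def test_symmetric_two_class(self):
        m = precision_recall_f1([[2, 1], [1, 2]])
        assert np.allclose(m.precision, 2 / 3)
        assert np.allclose(m.recall, 2 / 3)
        assert np.allclose(m.f1, 2 / 3)

    def test_all_predicted_one_class(self):
        cm = [[10, 0, 0], [10, 0, 0], [10, 0, 0]]
        m = precision_recall_f1(cm, ("a", "b", "c"))
        assert m.macro_recall == pytest.approx(1 / 3)
        assert "precision[b]" in m.undefined_flags

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        from sklearn.metrics import confusion_matrix

        cm = confusion_matrix(y_true, y_pred, labels=[0, 1, 2])
        m = precision_recall_f1(cm, ("0", "1", "2"))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1, 2], zero_division=0)
        assert np.allclose(m.precision, p)
        assert np.allclose(m.recall, r)
        assert np.allclose(m.f1, f)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            precision_recall_f1([[1, -1], [0, 2]])


class TestTrainEval:
    @pytest.mark.parametrize("family", ["DT", "RF", "SVM", "AdaBoost"])
    def test_separable_data_perfect_f1(self, family):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((30, 4)) + 12 * k for k in range(3)])
        y = np.array(["poor"] * 30 + ["medium"] * 30 + ["good"] * 30)
        spec = ClassifierSpec(family=family, seed=0, n_estimators=20)
        (tr, te) = stratified_split(X, y, 0.8, seed=0)
        metrics = train_eval(spec, tr, te, class_weights(tr[1]))
        assert metrics.macro_f1 == 1.0

    def test_shuffled_labels_near_chance(self):
        f1s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((150, 4))
            y = np.array(["poor", "medium", "good"] * 50)
            spec = ClassifierSpec(family="DT", seed=seed)
            tr, te = stratified_split(X, y, 0.8, seed=seed)
            f1s.append(train_eval(spec, tr, te, class_weights(tr[1])).macro_f1)
        assert np.mean(f1s) == pytest.approx(1 / 3, abs=0.1)

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((90, 4))
        y = np.array(["poor", "medium", "good"] * 30)
        spec = ClassifierSpec(family="RF", seed=5, n_estimators=10)
        tr, te = stratified_split(X, y, 0.8, seed=3)
        m1 = train_eval(spec, tr, te, class_weights(tr[1]))
        m2 = train_eval(spec, tr, te, class_weights(tr[1]))
        assert np.array_equal(m1.confusion, m2.confusion)
        assert m1.macro_f1 == m2.macro_f1

    def test_single_class_training_target_rejected(self):
        X = np.zeros((10, 2))
        y = np.array(["poor"] * 10)
        spec = ClassifierSpec(family="DT")
        with pytest.raises(DegenerateInputError):
            train_eval(spec, (X, y), (X, y))


class TestGridSearch:
    def test_sixteen_point_subgrid_evaluates_all(self):
        table, labels = make_table(seed=0)
        grid = WeightGrid(c_plusplus=(2.0, 3.0), c_plus=(0.5, 1.5),
                          c_minus=(-1.5, -0.5), c_minusminus=(-4.0, -2.5))
        res = grid_search(table, labels, ClassifierSpec("DT", seed=0), grid, seed=0)
        assert len(res.records) == 16
        finite = res.records["f1"].dropna()
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_memoized_result_equals_standalone_reevaluation(self):
        table, labels = make_table(seed=1)
        res = grid_search(table, labels, ClassifierSpec("DT", seed=0),
                          SUB_GRID, seed=0)
        # re-run an arbitrary single combination standalone
        row = res.records.iloc[37]
        single = WeightGrid(
            c_plusplus=(row.c_plusplus,), c_plus=(row.c_plus,),
            c_minus=(row.c_minus,), c_minusminus=(row.c_minusminus,),
        )
        res1 = grid_search(table, labels, ClassifierSpec("DT", seed=0),
                           single, seed=0)
        assert res1.records.iloc[0]["f1"] == row["f1"]
        assert res1.records.iloc[0]["precision"] == row["precision"]

    def test_best_set_attains_maximum(self):
        table, labels = make_table(seed=2)
        res = grid_search(table, labels, ClassifierSpec("DT", seed=0),
                          SUB_GRID, seed=0)
        assert res.best_f1 == res.records["f1"].max()
        for w in res.best_weights:
            mask = ((res.records.c_plusplus == w.c_plusplus)
                    & (res.records.c_plus == w.c_plus)
                    & (res.records.c_minus == w.c_minus)
                    & (res.records.c_minusminus == w.c_minusminus))
            assert res.records[mask]["f1"].iloc[0] == pytest.approx(res.best_f1)

    def test_recovers_generating_weights(self):
        """With well-separated class-conditional features, the best set
        must contain weights whose induced labels agree >= 95% with the
        generating weights' labels (parameter recovery)."""
        for seed in range(3):
            table, labels = make_table(seed=seed, n=150)
            res = grid_search(table, labels, ClassifierSpec("DT", seed=0),
                              SUB_GRID, seed=seed)
            true_y = [quality_bin(sri_score(lab, TRUE_W)) for lab in labels]
            best_agreement = max(
                np.mean([quality_bin(sri_score(lab, w)) == t
                         for lab, t in zip(labels, true_y)])
                for w in res.best_weights
            )
            assert res.best_f1 >= 0.95
            assert best_agreement >= 0.95


class TestKFoldCV:
    def test_fold_times_repeat_count(self):
        table, labels = make_table(seed=3, n=90)
        df = kfold_cv(table, labels, TRUE_W, ClassifierSpec("DT", seed=0),
                      k=2, repeats=5, seed=0)
        assert len(df) == 10

    def test_separable_data_all_perfect(self):
        table, labels = make_table(seed=4, n=90, separation=12.0)
        df = kfold_cv(table, labels, TRUE_W, ClassifierSpec("DT", seed=0),
                      k=5, repeats=2, seed=0)
        assert np.allclose(df["f1"], 1.0)

    def test_deterministic_under_seed(self):
        table, labels = make_table(seed=5, n=90)
        df1 = kfold_cv(table, labels, TRUE_W, ClassifierSpec("DT", seed=0),
                       k=2, repeats=3, seed=9)
        df2 = kfold_cv(table, labels, TRUE_W, ClassifierSpec("DT", seed=0),
                       k=2, repeats=3, seed=9)
        pd.testing.assert_frame_equal(df1, df2)

    def test_class_smaller_than_k_rejected(self):
        table, labels = make_table(seed=6, n=12)
        with pytest.raises(ConfigurationError):
            kfold_cv(table, labels, TRUE_W, ClassifierSpec("DT"), k=10,
                     repeats=1, seed=0)
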