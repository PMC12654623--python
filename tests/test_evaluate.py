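import itertools

import numpy as np
import pytest
from scipy import stats

from hybridbci.evaluate import (
    ClassifierSpec,
    anova_select,
    compute_metrics,
    predict,
    repeat_and_average,
    train_classifier,
    wilcoxon_exact,
    wolpaw_itr,
)
from hybridbci.features import FeatureTable


def _table(X, labels, names=None):
    X = np.asarray(X, dtype=float)
    names = names or [f"f{i}" for i in range(X.shape[1])]
    n = X.shape[0]
    return FeatureTable(X, names, np.asarray(labels), np.array(["m"] * n),
                        np.array(["s"] * n))


def _separable(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    Xa = rng.standard_normal((n_per_class, 3)) + [6, 0, 0]
    Xb = rng.standard_normal((n_per_class, 3)) - [6, 0, 0]
    return _table(np.vstack([Xa, Xb]), ["a"] * n_per_class + ["b"] * n_per_class)


class TestClassifiers:
    @pytest.mark.parametrize("family", ["bagging", "random_forest", "svm_ovo"])
    def test_separable_problem_is_learned(self, family):
        table = _separable()
        spec = ClassifierSpec(family=family, seed=0,
                              search_iters=5, search_folds=3)
        model = train_classifier(spec, table)
        np.testing.assert_array_equal(predict(model, table), table.labels)

    def test_same_seed_gives_identical_predictions(self):
        table = _separable(seed=3)
        test = _table(np.random.default_rng(9).standard_normal((15, 3)),
                      ["a"] * 15)
        p1 = predict(train_classifier(ClassifierSpec(seed=7), table), test)
        p2 = predict(train_classifier(ClassifierSpec(seed=7), table), test)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(ClassifierSpec(),
                             _table(np.zeros((5, 2)) + np.arange(5)[:, None],
                                    ["a"] * 5))

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            train_classifier(ClassifierSpec(), _table(np.empty((0, 2)), []))

    def test_column_permutation_realigned_by_name(self):
        table = _separable(seed=1)
        model = train_classifier(ClassifierSpec(seed=0), table)
        test = _table(np.random.default_rng(2).standard_normal((10, 3)),
                      ["a"] * 10)
        permuted = test.select_features(["f2", "f0", "f1"])
        np.testing.assert_array_equal(predict(model, test),
                                      predict(model, permuted))

    def test_default_configurations(self):
        assert ClassifierSpec("bagging").n_trees == 100
        assert ClassifierSpec("bagging").max_depth == 15
        assert ClassifierSpec("random_forest").n_trees == 50
        assert ClassifierSpec("svm_ovo").search_iters == 30


class TestAnovaSelect:
    def _toy(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(["a", "b", "c", "d"], 5)
        X = np.column_stack([
            rng.standard_normal(20),                       # uninformative
            np.repeat([0.0, 1.0, 2.0, 3.0], 5),           # class code, 0 within-var
            np.full(20, 3.3),                              # constant
            np.repeat([0.0, 5.0, 0.0, 5.0], 5) + rng.standard_normal(20),
        ])
        return _table(X, labels, names=["noise", "code", "const", "strong"])

    def test_constant_feature_dropped(self):
        sel = anova_select(self._toy(), alpha=0.05)
        i = sel.feature_names.index("const")
        assert sel.f_statistic[i] == 0.0
        assert sel.p_value[i] == pytest.approx(1.0)
        assert "const" not in sel.selected

    def test_zero_within_variance_feature_retained(self):
        sel = anova_select(self._toy(), alpha=0.05)
        i = sel.feature_names.index("code")
        assert np.isinf(sel.f_statistic[i])
        assert sel.p_value[i] == 0.0
        assert "code" in sel.selected

    def test_f_statistic_matches_independent_oracle(self):
        """Per-feature F equals scipy's one-way ANOVA to 1e-10."""
        table = self._toy()
        sel = anova_select(table, alpha=0.05)
        groups = [table.X[table.labels == c] for c in "abcd"]
        for i in (0, 3):  # finite-F columns
            f_ref = stats.f_oneway(*[g[:, i] for g in groups]).statistic
            assert sel.f_statistic[i] == pytest.approx(f_ref, abs=1e-10)

    def test_retained_set_monotone_in_alpha(self):
        table = self._toy()
        alphas = [0.001, 0.01, 0.05, 0.5, 1.0]
        sets = [set(anova_select(table, a).selected) for a in alphas]
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_too_small_class_errors(self):
        with pytest.raises(ValueError):
            anova_select(_table(np.zeros((3, 2)) + np.arange(3)[:, None],
                                ["a", "a", "b"]))


class TestComputeMetrics:
    def test_perfect_predictions(self):
        truth = np.array(["a", "b", "a", "b"])
        rep = compute_metrics(truth, truth, ["a", "b"])
        assert rep.overall_accuracy == 100.0
        assert rep.precision == rep.recall == rep.f1 == 100.0
        assert all(v == 100.0 for v in rep.per_class_accuracy.values())

    def test_macro_recall_equals_overall_when_balanced(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c", "d"]
        for _ in range(10):
            truth = np.repeat(classes, 25)
            predicted = rng.choice(classes, size=100)
            rep = compute_metrics(truth, predicted, classes)
            assert rep.recall == pytest.approx(rep.overall_accuracy, abs=1e-12)

    def test_unseen_predicted_label_errors(self):
        with pytest.raises(ValueError, match="not in class list"):
            compute_metrics(np.array(["a"]), np.array(["z"]), ["a", "b"])


class TestWolpawItr:
    def test_perfect_four_class(self):
        assert wolpaw_itr(1.0, 4, 2.5) == pytest.approx(48.0)

    def test_chance_level_is_zero(self):
        assert wolpaw_itr(0.25, 4, 2.5) == 0.0

    def test_reference_accuracy_value(self):
        # direct evaluation of the bit-rate formula at P=0.9429, N=4, T=2.5 s
        assert wolpaw_itr(0.9429, 4, 2.5) == pytest.approx(38.2482, abs=1e-3)

    def test_monotone_in_accuracy(self):
        vals = [wolpaw_itr(p, 4, 2.5) for p in np.linspace(0.25, 1.0, 40)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_below_chance_errors(self):
        with pytest.raises(ValueError):
            wolpaw_itr(0.2, 4)


class TestWilcoxonExact:
    def test_single_positive_pair(self):
        assert wilcoxon_exact([1.0], [0.0]) == pytest.approx(1.0)

    def test_four_consistent_pairs_give_p_125(self):
        a = [97.40, 93.80, 92.80, 100.0]
        b = [93.14, 90.26, 88.92, 96.02]
        assert wilcoxon_exact(a, b) == pytest.approx(0.125)

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        w_all = np.array([np.sum(ranks[list(signs)])
                          for signs in itertools.product([False, True], repeat=n)])
        cdf = np.mean(w_all <= w_obs + 1e-9)
        sf = np.mean(w_all >= w_obs - 1e-9)
        p_brute = min(1.0, 2 * min(cdf, sf))
        assert wilcoxon_exact(a, b) == pytest.approx(p_brute, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_matches_scipy_exact(self, n):
        rng = np.random.default_rng(100 + n)
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        ref = stats.wilcoxon(a, b, method="exact").pvalue
        assert wilcoxon_exact(a, b) == pytest.approx(ref, abs=1e-12)

    def test_zero_differences_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero difference"):
            p = wilcoxon_exact([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert 0 < p <= 1

    def test_p_always_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for n in range(1, 11):
            a, b = rng.standard_normal(n), rng.standard_normal(n)
            assert 0 < wilcoxon_exact(a, b) <= 1


class TestRepeatAndAverage:
    def _report(self, acc):
        return compute_metrics(np.array(["a", "b"]),
                               np.array(["a", "b" if acc else "a"]), ["a", "b"])

    def test_deterministic_closure_average_equals_single(self):
        rep = repeat_and_average(lambda seed: self._report(True), 5, base_seed=0)
        assert rep.overall_accuracy == 100.0
        assert rep.n_repetitions == 5
        assert len(rep.per_repetition) == 5

    def test_same_base_seed_reproduces(self):
        seen = []

        def run(seed):
            seen.append(seed)
            return self._report(True)

        repeat_and_average(run, 3, base_seed=42)
        first = list(seen)
        seen.clear()
        repeat_and_average(run, 3, base_seed=42)
        assert seen == first
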