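"""MDL discretization, mRMR ranking, forward selection, OOB importance."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from sulfenpred.evaluation import CVSpec
from sulfenpred.selection import (
    discretize_matrix,
    forward_incremental_select,
    mdl_discretize,
    mrmr_rank,
    mutual_information,
    rf_permutation_importance,
)


def mi_counter(a, b) -> float:
    """Independent plug-in MI via Counter (natural log)."""
    n = len(a)
    pa = Counter(a)
    pb = Counter(b)
    pab = Counter(zip(a, b))
    total = 0.0
    for (x, z), c in pab.items():
        pxy = c / n
        total += pxy * math.log(pxy / ((pa[x] / n) * (pb[z] / n)))
    return total


class TestMDLDiscretize:
    def test_separable_feature_single_cut(self):
        v = np.r_[np.zeros(30), np.ones(30)]
        y = np.r_[np.zeros(30), np.ones(30)]
        codes, cuts = mdl_discretize(v, y)
        assert cuts == [0.5]
        assert set(codes[:30]) == {0} and set(codes[30:]) == {1}

    def test_uniform_noise_rejected(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(size=200)
        y = rng.integers(0, 2, 200)
        _, cuts = mdl_discretize(v, y)
        assert cuts == []

    def test_constant_vector_single_bin(self):
        codes, cuts = mdl_discretize(np.ones(40), np.r_[np.zeros(20), np.ones(20)])
        assert cuts == [] and set(codes) == {0}

    def test_requires_two_classes(self):
        with pytest.raises(ValueError, match="2 classes"):
            mdl_discretize(np.arange(10.0), np.zeros(10))

    def test_multi_interval_feature(self):
        # class 1 occupies the middle band: two cuts needed
        v = np.r_[np.linspace(0, 1, 40), np.linspace(2, 3, 40),
                  np.linspace(4, 5, 40)]
        y = np.r_[np.zeros(40), np.ones(40), np.zeros(40)]
        _, cuts = mdl_discretize(v, y)
        assert len(cuts) == 2
        assert cuts[0] < 2.0 < 3.0 < cuts[1]


class TestMutualInformation:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_counter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 100)
        b = rng.integers(0, 3, 100)
        assert mutual_information(a, b) == pytest.approx(
            mi_counter(a.tolist(), b.tolist()), abs=1e-12
        )

    def test_identical_vectors_give_entropy(self):
        a = np.r_[np.zeros(50), np.ones(50)].astype(int)
        assert mutual_information(a, a) == pytest.approx(math.log(2))


class TestMrmrRank:
    def test_label_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = np.c_[y.astype(float), rng.normal(size=200)]
        ranking = mrmr_rank(X, y, 2, ["label_copy", "noise"])
        assert ranking[0][0] == "label_copy"

    def test_redundant_copy_penalized(self):
        # f1: strong (noisy) label proxy; f2: exact copy of f1; f3: weak
        # independently noisy proxy. MID must rank f1, f3, f2.
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        flip1 = rng.random(400) < 0.05
        f1 = np.where(flip1, 1 - y, y).astype(float)
        f2 = f1.copy()
        flip3 = rng.random(400) < 0.30
        f3 = np.where(flip3, 1 - y, y).astype(float)
        X = np.c_[f1, f2, f3]
        ranking = [n for n, _ in mrmr_rank(X, y, 3, ["f1", "f2", "f3"])]
        assert ranking == ["f1", "f3", "f2"]

    def test_step_one_is_argmax_marginal_mi(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 150)
        X = rng.normal(size=(150, 10)) + 0.8 * y[:, None] * rng.random(10)
        D = discretize_matrix(X, y)
        mis = [mi_counter(D[:, j].tolist(), y.tolist()) for j in range(10)]
        ranking = mrmr_rank(X, y, 1, discretized=D)
        assert ranking[0][0] == f"f{int(np.argmax(mis))}"

    def test_all_constant_matrix_is_error(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(ValueError, match="constant"):
            mrmr_rank(np.ones((40, 3)), y, 2)


class TestForwardSelection:
    def make_toy(self, seed=0, n=120, n_noise=9):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        sep = y + rng.normal(0, 0.05, n)  # perfectly separating
        noise = rng.normal(size=(n, n_noise))
        X = np.c_[sep, noise]
        names = ["sep"] + [f"noise{i}" for i in range(n_noise)]
        return X, y, names

    def test_separating_feature_selected_alone(self):
        X, y, names = self.make_toy()
        ranking = [(n, 0.0) for n in names]
        res = forward_incremental_select(
            ranking, X, y, names, cv=CVSpec(3, 0), patience=5, rf_trees=25
        )
        assert res.selected == ["sep"]

    def test_matches_exhaustive_search_on_toy(self):
        """The greedy walk finds the subset exhaustive search ranks best."""
        X, y, names = self.make_toy(seed=3, n=60, n_noise=5)
        cv = CVSpec(3, 0)
        res = forward_incremental_select(
            [(n, 0.0) for n in names], X, y, names, cv=cv, patience=6,
            rf_trees=25,
        )
        from sulfenpred.selection import _cv_auc, _default_wrappers
        rf, svm = _default_wrappers(cv.seed, 25)
        best = (-1.0, None)
        for r in range(1, len(names) + 1):
            for combo in itertools.combinations(range(len(names)), r):
                Xs = X[:, list(combo)]
                score = min(_cv_auc(rf, Xs, y, cv, False),
                            _cv_auc(svm, Xs, y, cv, True))
                # prefer smaller subsets on ties (first seen at smaller r)
                if score > best[0]:
                    best = (score, combo)
        assert [names[j] for j in best[1]] == res.selected

    def test_duplicate_informative_feature_kept_once(self):
        X, y, names = self.make_toy()
        X = np.c_[X[:, 0], X[:, 0], X[:, 1:]]
        names = ["sep", "sep_copy"] + names[1:]
        res = forward_incremental_select(
            [(n, 0.0) for n in names], X, y, names, cv=CVSpec(3, 0),
            patience=5, rf_trees=25,
        )
        assert res.selected == ["sep"]

    def test_all_noise_stays_near_chance(self):
        rng = np.random.default_rng(5)
        n = 300
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = rng.normal(size=(n, 8))
        names = [f"n{i}" for i in range(8)]
        res = forward_incremental_select(
            [(nm, 0.0) for nm in names], X, y, names, cv=CVSpec(3, 1),
            patience=8, rf_trees=25,
        )
        _, auc_rf, auc_svm = res.trajectory[res.peak_index]
        assert 0.4 <= auc_rf <= 0.6
        assert 0.4 <= auc_svm <= 0.6

    def test_deterministic_and_serializable(self, tmp_path):
        X, y, names = self.make_toy(seed=9, n=80, n_noise=4)
        ranking = [(n, 0.0) for n in names]
        kw = dict(cv=CVSpec(3, 2), patience=4, rf_trees=25)
        r1 = forward_incremental_select(ranking, X, y, names, **kw)
        r2 = forward_incremental_select(ranking, X, y, names, **kw)
        assert r1.selected == r2.selected
        assert r1.trajectory == r2.trajectory
        p = tmp_path / "sel.json"
        r1.to_json(p)
        r3 = type(r1).from_json(p)
        assert r3.selected == r1.selected
        assert r3.peak_index == r1.peak_index

    def test_empty_ranking_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            forward_incremental_select([], np.zeros((10, 1)), np.zeros(10), ["f"])


class TestPermutationImportance:
    def make_forest(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        informative = y + rng.normal(0, 0.3, n)
        null = rng.normal(size=n)
        constant = np.zeros(n)  # never split on
        X = np.c_[informative, null, constant]
        rf = RandomForestClassifier(n_estimators=60, random_state=1).fit(X, y)
        return rf, X, y

    def test_null_feature_near_zero(self):
        rf, X, y = self.make_forest()
        imp = rf_permutation_importance(rf, X, y, seed=0)
        assert abs(imp[1]) < 0.02

    def test_label_feature_dominates(self):
        rf, X, y = self.make_forest()
        imp = rf_permutation_importance(rf, X, y, seed=0)
        assert imp[0] > imp[1] and imp[0] > imp[2]
        assert imp[0] > 0.1

    def test_never_split_feature_exactly_zero(self):
        rf, X, y = self.make_forest()
        imp = rf_permutation_importance(rf, X, y, seed=0)
        assert imp[2] == 0.0

    def test_no_bootstrap_is_error(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=5, bootstrap=False,
                                    random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="bootstrap"):
            rf_permutation_importance(rf, X, y)
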