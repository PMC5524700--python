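"""Split enumeration, PLS fitting, LOO validation, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gridqsar.errors import FitError, GridQSARError
from gridqsar.pls import (ModelScore, enumerate_splits, evaluate, fit_pls,
                          loo_q2, predict, predict_external, q_squared,
                          rank_models, rmse)


class TestEnumerateSplits:
    def test_ten_choose_three(self):
        codes = list("ABCEFHIJKL")
        plans = enumerate_splits(codes, 3, external=("D", "G"))
        assert len(plans) == 120
        assert len({p.id for p in plans}) == 120
        for p in plans:
            assert len(p.train_codes) == 7
            assert not set(p.train_codes) & set(p.test_codes)
            assert set(p.train_codes) | set(p.test_codes) == set(codes)
        # every code sits in exactly C(9,2) = 36 test sets
        counts = {c: sum(c in p.test_codes for p in plans) for c in codes}
        assert set(counts.values()) == {36}

    @pytest.mark.parametrize("n,k,expected", [(3, 1, 3), (4, 2, 6)])
    def test_small_enumerations(self, n, k, expected):
        plans = enumerate_splits(list("ABCD")[:n], k)
        assert len(plans) == expected

    def test_deterministic_lexicographic_order(self):
        plans = enumerate_splits(list("DCBA"), 2)
        assert [p.id for p in plans][:3] == ["AB", "AC", "AD"]

    def test_oversized_test_rejected(self):
        with pytest.raises(ValueError):
            enumerate_splits(list("ABC"), 3)

    def test_external_overlap_rejected(self):
        with pytest.raises(ValueError):
            enumerate_splits(list("ABC"), 1, external=("A",))


class TestFitPLS:
    def test_noiseless_single_descriptor(self):
        X = np.arange(5.0).reshape(-1, 1)
        y = 3.0 * X.ravel() + 2.0
        model = fit_pls(X, y, n_components=1)
        q2, err = evaluate(model, X, y)
        assert q2 == pytest.approx(1.0)
        assert err == pytest.approx(0.0, abs=1e-10)

    def test_full_rank_matches_normal_equations(self, rng):
        # PLS with p components on an n > p full-rank problem is OLS
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = fit_pls(X, y, n_components=3)
        Xd = np.column_stack([np.ones(8), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(predict(model, X), Xd @ beta, atol=1e-8)

    def test_deterministic(self, rng):
        X = rng.normal(size=(7, 40))
        y = rng.normal(size=7)
        m1 = fit_pls(X, y, n_components=2)
        m2 = fit_pls(X, y, n_components=2)
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert m1.intercept == m2.intercept

    def test_zero_column_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(6, 5))
        y = rng.normal(size=6)
        m1 = fit_pls(X, y, n_components=2)
        X2 = np.column_stack([X, np.zeros(6)])
        m2 = fit_pls(X2, y, n_components=2)
        np.testing.assert_allclose(predict(m1, X),
                                   predict(m2, X2), atol=1e-10)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(FitError):
            fit_pls(rng.normal(size=(5, 3)), np.ones(5), 1)

    def test_degenerate_x_rejected(self):
        with pytest.raises(FitError):
            fit_pls(np.ones((5, 3)), np.arange(5.0), 1)

    def test_component_bounds_enforced(self, rng):
        with pytest.raises(FitError):
            fit_pls(rng.normal(size=(4, 10)), rng.normal(size=4),
                    n_components=4)  # > n - 1

    def test_column_misalignment_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        model = fit_pls(X, rng.normal(size=5), 1)
        with pytest.raises(GridQSARError):
            predict(model, X[["b", "a", "c"]])


class TestScores:
    def test_q2_and_rmse_hand_example(self):
        # y=(0,10), yhat=(3,7): rmse 3, q2 = 1 - 18/50 = 0.64
        assert rmse([0.0, 10.0], [3.0, 7.0]) == pytest.approx(3.0)
        assert q_squared([0.0, 10.0], [3.0, 7.0]) == pytest.approx(0.64)

    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert q_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0

    def test_constant_offset_rmse(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y + 1.0) == pytest.approx(1.0)

    def test_mean_predictor_inflation(self):
        # leave-one-out mean predictions of y=(1,2,3): (2.5, 2, 1.5),
        # PRESS = 4.5, TSS = 2 -> q2 = -1.25
        y = np.array([1.0, 2.0, 3.0])
        preds = np.array([2.5, 2.0, 1.5])
        assert q_squared(y, preds) == pytest.approx(-1.25)

    def test_loo_q2_noiseless_linear(self):
        X = np.linspace(0, 1, 6).reshape(-1, 1)
        y = 5.0 * X.ravel() - 1.0
        assert loo_q2(X, y, n_components=1) >= 0.99


class TestRanking:
    def score(self, sid, q2, err):
        return ModelScore(split_id=sid, n_components=2, q2_train_loo=0.5,
                          r2_train=0.9, rmse_train=1.0, q2_test=q2,
                          rmse_test=err)

    def test_sorted_by_rmse(self):
        ranked = rank_models([self.score("A", 0.5, 20.0),
                              self.score("B", 0.5, 10.0)], 0.1, 40.0)
        assert [s.split_id for s in ranked] == ["B", "A"]

    def test_q2_cutoff_excludes(self):
        ranked = rank_models([self.score("A", 0.05, 10.0)], q2_min=0.1,
                             rmse_max=40.0)
        assert ranked == []

    def test_tie_broken_by_q2_then_id(self):
        ranked = rank_models([self.score("B", 0.6, 10.0),
                              self.score("A", 0.8, 10.0),
                              self.score("C", 0.8, 10.0)], 0.1, 40.0)
        assert [s.split_id for s in ranked] == ["A", "C", "B"]


class TestExternal:
    def test_training_row_consistency(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = fit_pls(X, y, n_components=2)
        np.testing.assert_allclose(predict_external(model, X[:1]),
                                   predict(model, X)[:1])

    def test_zero_coefficient_model_predicts_intercept(self):
        from gridqsar.pls import PLSModel
        model = PLSModel(labels=("a", "b"), coefficients=np.zeros(2),
                         intercept=7.0, n_components=1)
        np.testing.assert_allclose(predict_external(model, np.ones((3, 2))),
                                   7.0)
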