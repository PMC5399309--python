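import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmcsb import (
    ConfusionMatrix,
    FitError,
    LogisticFit,
    cross_validate,
    fit_cart,
    fit_logistic,
    predict,
    predict_proba,
    split_train_test,
)
from mmcsb.classify import _aggregate_cells, evaluate
from oracles import grid_search_logistic_mle


def cells_to_data(cells: dict) -> tuple[np.ndarray, np.ndarray]:
    """Expand {(lpm, spm): (n_pos, n_neg)} into per-observation arrays."""
    X, y = [], []
    for (l, s), (n_pos, n_neg) in cells.items():
        X += [[l, s]] * (n_pos + n_neg)
        y += [True] * n_pos + [False] * n_neg
    return np.array(X, dtype=bool), np.array(y, dtype=bool)


class TestFitLogistic:
    def test_single_predictor_reduces_to_closed_form_log_odds(self):
        # 2x2 counts 40/10 vs 10/40 -> beta_lpm = log(40*40/(10*10)) = log 16
        X, y = cells_to_data({(1, 0): (40, 10), (0, 0): (10, 40)})
        fit = fit_logistic(X, y)
        assert fit.coefficients[1] == pytest.approx(np.log(16), abs=1e-6)
        assert fit.odds_ratios[1] == pytest.approx(16.0, rel=1e-6)
        assert not fit.separation_flag

    def test_odds_ratios_are_exponentiated_coefficients(self):
        X, y = cells_to_data(
            {(0, 0): (5, 40), (0, 1): (20, 10), (1, 0): (25, 8), (1, 1): (30, 3)}
        )
        fit = fit_logistic(X, y)
        np.testing.assert_allclose(fit.odds_ratios, np.exp(fit.coefficients))
        np.testing.assert_allclose(np.log(fit.odds_ratios), fit.coefficients)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 6)

    def test_matches_grid_search_mle(self):
        X, y = cells_to_data(
            {(0, 0): (6, 44), (0, 1): (18, 12), (1, 0): (26, 9), (1, 1): (28, 4)}
        )
        fit = fit_logistic(X, y)
        design, counts = _aggregate_cells(X, y)
        oracle = grid_search_logistic_mle(design, counts)
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-3)

    def test_separation_flagged_with_usable_predictions(self):
        rng = np.random.default_rng(1)
        lpm = np.arange(100) < 50
        spm = rng.uniform(size=100) < 0.4
        fit = fit_logistic(np.column_stack([lpm, spm]), lpm)
        assert fit.separation_flag and not fit.converged
        assert np.all(np.abs(fit.coefficients) <= 15 + 1e-9)
        assert (predict(fit, np.column_stack([lpm, spm])) == lpm).all()

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 2), dtype=bool)
        with pytest.raises(FitError):
            fit_logistic(X, np.ones(10, dtype=bool))

    def test_wald_interval_covers_coefficient(self):
        X, y = cells_to_data(
            {(0, 0): (10, 40), (0, 1): (20, 15), (1, 0): (30, 10), (1, 1): (35, 5)}
        )
        fit = fit_logistic(X, y, ci_level=0.95)
        assert (fit.coef_cis[:, 0] < fit.coefficients).all()
        assert (fit.coefficients < fit.coef_cis[:, 1]).all()
        np.testing.assert_allclose(fit.or_cis, np.exp(fit.coef_cis))


class TestFitCart:
    def test_label_equals_feature_gives_pure_split(self):
        X, y = cells_to_data({(1, 0): (40, 0), (1, 1): (10, 0), (0, 0): (0, 30), (0, 1): (0, 20)})
        tree = fit_cart(X, y)
        assert tree.root.feature == "lpm"
        for leaf in tree.leaves():
            assert leaf.error_rate == 0.0

    def test_bedside_rule_shape(self):
        # LPM is the stronger predictor; SPM resolves the LPM-absent branch
        cells = {(1, 0): (200, 10), (1, 1): (150, 5), (0, 1): (80, 20), (0, 0): (15, 300)}
        X, y = cells_to_data(cells)
        tree = fit_cart(X, y)
        assert tree.root.feature == "lpm"
        assert tree.root.present.is_leaf and tree.root.present.label
        assert tree.root.absent.feature == "spm"
        assert tree.root.absent.present.label is True
        assert tree.root.absent.absent.label is False

    def test_uninformative_features_yield_single_leaf(self):
        # identical class mix in every cell -> zero Gini gain everywhere
        cells = {(0, 0): (10, 30), (0, 1): (5, 15), (1, 0): (20, 60), (1, 1): (1, 3)}
        X, y = cells_to_data(cells)
        tree = fit_cart(X, y)
        assert tree.root.is_leaf
        assert tree.root.label is False

    def test_single_class_gives_single_leaf(self):
        X = np.zeros((8, 2), dtype=bool)
        tree = fit_cart(X, np.ones(8, dtype=bool))
        assert tree.root.is_leaf and tree.root.label is True

    def test_predictions_match_sklearn_cell_majorities(self):
        """Independent CART oracle: per-cell predictions must agree."""
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(7)
        grid = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=bool)
        for _ in range(25):
            cells = {
                tuple(c): (int(rng.integers(1, 50)), int(rng.integers(1, 50)))
                for c in grid
            }
            X, y = cells_to_data(cells)
            mine = predict(fit_cart(X, y), grid)
            sk = DecisionTreeClassifier(criterion="gini", random_state=0).fit(X, y)
            np.testing.assert_array_equal(mine, sk.predict(grid).astype(bool))


class TestPredict:
    def _fit_with_coefs(self, coefs) -> LogisticFit:
        c = np.asarray(coefs, dtype=float)
        z = np.zeros_like(c)
        cis = np.column_stack([c, c])
        return LogisticFit(
            coefficients=c, standard_errors=z, ci_level=0.95, coef_cis=cis,
            odds_ratios=np.exp(c), or_cis=np.exp(cis), p_values=z,
            loglik=0.0, aic=6.0, converged=True, separation_flag=False,
        )

    def test_published_coefficients_reproduce_baseline_probability(self):
        fit = self._fit_with_coefs([-2.54, 5.23, 5.15])
        p = predict_proba(fit, np.array([[0, 0]], dtype=bool))
        assert p[0] == pytest.approx(0.073, abs=0.001)
        assert not predict(fit, np.array([[0, 0]], dtype=bool))[0]
        assert predict(fit, np.array([[1, 0]], dtype=bool))[0]

    def test_tree_rule_predictions(self):
        cells = {(1, 0): (90, 5), (1, 1): (90, 5), (0, 1): (60, 10), (0, 0): (5, 95)}
        X, y = cells_to_data(cells)
        tree = fit_cart(X, y)
        grid = np.array([[1, 0], [0, 1], [0, 0], [1, 1]], dtype=bool)
        np.testing.assert_array_equal(predict(tree, grid), [True, True, False, True])


class TestSplit:
    def test_equal_halves(self):
        df = pd.DataFrame({"x": range(1970)})
        train, test = split_train_test(df, 0.5, seed=0)
        assert len(train) == 985 and len(test) == 985
        assert sorted(pd.concat([train, test])["x"]) == list(range(1970))

    def test_seed_reproducibility(self):
        df = pd.DataFrame({"x": range(100)})
        a, _ = split_train_test(df, 0.5, seed=3)
        b, _ = split_train_test(df, 0.5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_odd_row_goes_to_test(self):
        df = pd.DataFrame({"x": range(3)})
        train, test = split_train_test(df, 0.5, seed=0)
        assert len(train) == 1 and len(test) == 2

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_train_test(pd.DataFrame({"x": [1]}), 1.5, seed=0)


class TestCrossValidate:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(2)
        lpm = rng.uniform(size=60) < 0.5
        spm = rng.uniform(size=60) < 0.4
        y = lpm | (spm & (rng.uniform(size=60) < 0.8))
        y ^= rng.uniform(size=60) < 0.05
        return np.column_stack([lpm, spm]), y

    def test_repeats_times_folds_records(self, table):
        X, y = table
        cv = cross_validate(X, y, "cart", repeats=10, folds=10, seed=0)
        assert cv.n_fold_records == 100

    def test_each_observation_tested_once_per_repeat(self, table):
        X, y = table
        cv = cross_validate(X, y, "logistic", repeats=4, folds=6, seed=1)
        counts = np.zeros(len(y), dtype=int)
        for block in cv.fold_test_indices:
            counts[block] += 1
        assert (counts == 4).all()

    def test_leave_one_out_mmce_equals_direct_count(self):
        cells = {(1, 0): (4, 1), (0, 1): (2, 1), (0, 0): (1, 3)}
        X, y = [], []
        for (l, s), (np_, nn) in cells.items():
            X += [[l, s]] * (np_ + nn)
            y += [True] * np_ + [False] * nn
        X, y = np.array(X, dtype=bool), np.array(y, dtype=bool)
        cv = cross_validate(X, y, "cart", repeats=1, folds=len(y), seed=0)
        # direct leave-one-out on the same data
        errors = 0
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            model = fit_cart(X[mask], y[mask])
            errors += int(predict(model, X[i : i + 1])[0] != y[i])
        assert cv.mean["mmce"] == pytest.approx(errors / len(y))

    def test_too_few_observations_rejected(self, table):
        X, y = table
        with pytest.raises(ValueError):
            cross_validate(X[:5], y[:5], "logistic", repeats=1, folds=10)


class TestModelAgreement:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.data())
    def test_identical_confusions_when_cell_rules_coincide(self, data):
        """When logistic and CART induce the same label on each of the four
        feature cells, their confusion matrices on any dataset coincide."""
        cells = {
            (l, s): (data.draw(st.integers(1, 60)), data.draw(st.integers(1, 60)))
            for l in (0, 1)
            for s in (0, 1)
        }
        X, y = cells_to_data(cells)
        logit = fit_logistic(X, y)
        cart = fit_cart(X, y)
        grid = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=bool)
        if (predict(logit, grid) == predict(cart, grid)).all():
            cm_l, _ = evaluate(logit, X, y)
            cm_c, _ = evaluate(cart, X, y)
            assert (cm_l.tp, cm_l.fn, cm_l.fp, cm_l.tn) == (
                cm_c.tp,
                cm_c.fn,
                cm_c.fp,
                cm_c.tn,
            )
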