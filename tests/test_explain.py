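"""Attribution: gain-share importance, exact Shapley values, correlations.

The Shapley production path (coalition enumeration with Shapley weights)
is cross-checked against two independently written oracles: the
permutation definition (average marginal contribution over all d!
orderings) at small d, and a from-scratch subset-enumeration
reimplementation at the full nine features.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from thumbrot.exceptions import CapabilityError, UsageError
from thumbrot.explain import (
    AttributionResult,
    correlation_matrix,
    feature_importance,
    importance_from_gains,
    shapley_values,
    tree_gain_table,
)


# --- independent oracles --------------------------------------------------


def naive_value_function(predict, x, background, subset):
    """v(S): background rows with the subset's features set to x, averaged."""
    block = np.array(background, dtype=float, copy=True)
    for i in subset:
        block[:, i] = x[i]
    return float(np.mean(predict(block)))


def permutation_shapley(predict, x, background):
    """The permutation definition, enumerated exhaustively (small d only)."""
    d = len(x)
    phi = np.zeros(d)
    for order in itertools.permutations(range(d)):
        present: list[int] = []
        v_prev = naive_value_function(predict, x, background, present)
        for i in order:
            present.append(i)
            v_now = naive_value_function(predict, x, background, present)
            phi[i] += v_now - v_prev
            v_prev = v_now
    return phi / math.factorial(d)


def subset_shapley(predict, x, background):
    """Subset-formula reimplementation, written independently of the
    production path (explicit combinations, per-subset loops)."""
    d = len(x)
    phi = np.zeros(d)
    indices = list(range(d))
    for i in indices:
        others = [j for j in indices if j != i]
        for size in range(d):
            w = (
                math.factorial(size)
                * math.factorial(d - size - 1)
                / math.factorial(d)
            )
            for S in itertools.combinations(others, size):
                gain = naive_value_function(
                    predict, x, background, list(S) + [i]
                ) - naive_value_function(predict, x, background, list(S))
                phi[i] += w * gain
    return phi


# --- importance -----------------------------------------------------------


class TestFeatureImportance:
    def test_single_feature_tree_gets_full_share(self):
        gains = pd.DataFrame(
            {"tree": [0, 0], "feature": ["a", "a"], "gain": [2.0, 3.0]}
        )
        res = importance_from_gains(gains, feature_names=["a", "b"])
        assert res.per_feature == {"a": 1.0, "b": 0.0}

    def test_equal_gain_symmetry(self):
        gains = pd.DataFrame(
            {
                "tree": [0, 0, 1, 1, 2, 2],
                "feature": ["a", "b"] * 3,
                "gain": [5.0, 5.0, 1.0, 1.0, 9.0, 9.0],
            }
        )
        res = importance_from_gains(gains)
        assert res.per_feature["a"] == pytest.approx(0.5)
        assert res.per_feature["b"] == pytest.approx(0.5)

    def test_shares_sum_to_one_on_fitted_model(self, fitted_gbt):
        res = feature_importance(fitted_gbt)
        assert res.kind == "importance"
        assert sum(res.per_feature.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0.0 for v in res.per_feature.values())

    def test_non_tree_model_rejected(self, noisy_table):
        from thumbrot.models import train

        linear = train("linear", noisy_table, seed=0)
        with pytest.raises(CapabilityError):
            feature_importance(linear)

    def test_gain_table_shape(self, fitted_gbt):
        gains = tree_gain_table(fitted_gbt)
        assert set(gains.columns) == {"tree", "feature", "gain"}
        assert (gains["gain"] >= 0.0).all()

    def test_top_feature_rank_stable_across_seeds(self, noisy_table):
        """The dominant predictor should not depend on the fitting seed."""
        from thumbrot.models import ModelSpec, train

        spec = ModelSpec(
            "gradient_boosted_trees",
            search_space={"est__n_estimators": [60]},
            tuning_folds=3,
        )
        tops = {
            feature_importance(train(spec, noisy_table, seed=s)).ranking()[0]
            for s in range(5)
        }
        assert len(tops) == 1


# --- Shapley --------------------------------------------------------------


class TestShapley:
    def test_additivity_on_fitted_model(self, fitted_gbt, noisy_split):
        train_tab, test_tab = noisy_split
        background = train_tab[fitted_gbt.feature_names].head(32)
        row = test_tab.iloc[0][fitted_gbt.feature_names]
        attr = shapley_values(fitted_gbt, row, background)
        pred = float(fitted_gbt.predict(test_tab.head(1))[0])
        assert attr.baseline + sum(attr.per_feature.values()) == pytest.approx(
            pred, abs=1e-6
        )

    def test_ignored_feature_gets_zero(self):
        predict = lambda X: 3.0 * X[:, 0] + 1.0
        rng = np.random.default_rng(0)
        bg = rng.normal(size=(20, 3))
        attr = shapley_values(predict, np.array([1.0, 5.0, -2.0]), bg)
        assert attr.per_feature["x1"] == pytest.approx(0.0, abs=1e-12)
        assert attr.per_feature["x2"] == pytest.approx(0.0, abs=1e-12)

    def test_additive_model_gives_centred_terms(self):
        """For f = g1(x1) + g2(x2), the Shapley value of feature i is
        gi(xi) minus its background mean."""
        g1 = lambda v: v**2
        g2 = lambda v: np.sin(v)
        predict = lambda X: g1(X[:, 0]) + g2(X[:, 1])
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(50, 2))
        x = np.array([1.3, -0.4])
        attr = shapley_values(predict, x, bg)
        assert attr.per_feature["x0"] == pytest.approx(
            g1(x[0]) - g1(bg[:, 0]).mean(), abs=1e-9
        )
        assert attr.per_feature["x1"] == pytest.approx(
            g2(x[1]) - g2(bg[:, 1]).mean(), abs=1e-9
        )

    def test_symmetric_features_get_equal_values(self):
        predict = lambda X: X[:, 0] * X[:, 1]
        bg = np.zeros((5, 2))
        attr = shapley_values(predict, np.array([2.0, 2.0]), bg)
        assert attr.per_feature["x0"] == pytest.approx(attr.per_feature["x1"])

    def test_matches_permutation_oracle_small_d(self):
        rng = np.random.default_rng(7)
        W = rng.normal(size=(3, 3))
        predict = lambda X: np.einsum("ni,ij,nj->n", X, W, X) + X[:, 2]
        bg = rng.normal(size=(12, 3))
        x = rng.normal(size=3)
        attr = shapley_values(predict, x, bg)
        oracle = permutation_shapley(predict, x, bg)
        got = np.array([attr.per_feature[f"x{i}"] for i in range(3)])
        assert np.allclose(got, oracle, atol=1e-9)

    def test_matches_subset_oracle_on_fitted_model(self, fitted_gbt, noisy_split):
        """Full nine-feature check against the independent enumeration."""
        train_tab, test_tab = noisy_split
        names = fitted_gbt.feature_names
        bg = train_tab[names].head(8)
        row = test_tab.iloc[3][names]
        attr = shapley_values(fitted_gbt, row, bg)
        predict = lambda X: fitted_gbt.predict(X)
        oracle = subset_shapley(predict, row.to_numpy(), bg.to_numpy())
        got = np.array([attr.per_feature[n] for n in names])
        assert np.max(np.abs(got - oracle)) < 1e-6

    def test_feature_mismatch_rejected(self, fitted_gbt, noisy_split):
        train_tab, _ = noisy_split
        bad_bg = train_tab[fitted_gbt.feature_names[:5]].head(5)
        row = train_tab.iloc[0][fitted_gbt.feature_names]
        with pytest.raises(UsageError):
            shapley_values(fitted_gbt, row, bad_bg)

    def test_empty_background_rejected(self):
        with pytest.raises(UsageError):
            shapley_values(lambda X: X[:, 0], np.array([1.0]), np.empty((0, 1)))

    def test_result_frame_ranked_by_magnitude(self):
        attr = AttributionResult(
            per_feature={"a": 0.1, "b": -2.0, "c": 0.5}, kind="shapley", baseline=0.0
        )
        frame = attr.to_frame()
        assert list(frame["feature"]) == ["b", "c", "a"]
        assert list(frame["rank"]) == [1, 2, 3]


# --- correlation matrix ---------------------------------------------------


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, noisy_table):
        corr = correlation_matrix(noisy_table)
        assert np.allclose(corr, corr.T, atol=1e-12)
        assert np.allclose(np.diag(corr), 1.0, atol=1e-12)
        assert "true_angle" in corr.columns

    def test_perfect_anticorrelation(self):
        x = np.linspace(0, 1, 20)
        corr = correlation_matrix(pd.DataFrame({"x": x, "y": -x}))
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_constant_column_warns_nan(self):
        df = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(df)
        assert np.isnan(corr.loc["x", "c"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(UsageError):
            correlation_matrix(pd.DataFrame({"x": [1.0]}))

    def test_angle_correlates_positively_with_thumb_area(self, noiseless_table):
        corr = correlation_matrix(noiseless_table)
        assert corr.loc["true_angle", "norm_tip_size"] > 0.0
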