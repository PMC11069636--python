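"""Splitting, training, evaluation, and the family comparison."""

import numpy as np
import pandas as pd
import pytest

from thumbrot.exceptions import FitError, UsageError
from thumbrot.features import PREDICTOR_COLUMNS
from thumbrot.models import (
    ComparisonReport,
    ModelSpec,
    SplitSpec,
    ThumbAngleModel,
    ThumbAngleResults,
    compare_models,
    evaluate,
    split_dataset,
    train,
)


def synthetic_table(n=200, seed=0, noise=0.0, fn=None):
    """A labelled table with controllable feature-to-angle structure."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(n, len(PREDICTOR_COLUMNS))),
        columns=PREDICTOR_COLUMNS,
    )
    if fn is None:
        fn = lambda X: 2.0 * X["tip_angle"] + 1.0
    y = fn(X) + rng.normal(0.0, noise, size=n)
    table = X.copy()
    table.insert(0, "true_angle", y)
    return table


class TestSplit:
    def test_default_counts_on_study_size(self):
        table = synthetic_table(n=9000, fn=lambda X: np.repeat(np.arange(0, 100, 10), 900))
        train_tab, test_tab = split_dataset(table, SplitSpec(seed=0))
        assert len(train_tab) == 7200 and len(test_tab) == 1800
        assert len(set(train_tab.index) & set(test_tab.index)) == 0

    def test_stratification_covers_every_angle(self, noisy_table):
        train_tab, test_tab = split_dataset(noisy_table, SplitSpec(seed=1))
        assert set(train_tab["true_angle"].round()) == set(
            test_tab["true_angle"].round()
        )

    def test_same_seed_same_membership(self, noisy_table):
        a, _ = split_dataset(noisy_table, SplitSpec(seed=5))
        b, _ = split_dataset(noisy_table, SplitSpec(seed=5))
        assert list(a.index) == list(b.index)

    def test_tiny_test_set_warns(self):
        table = synthetic_table(n=10, fn=lambda X: X["tip_angle"])
        with pytest.warns(UserWarning, match="test partition"):
            train_tab, test_tab = split_dataset(
                table, SplitSpec(train_fraction=0.9, stratify_by_angle=False)
            )
        assert len(train_tab) == 9 and len(test_tab) == 1

    def test_group_by_subject_keeps_subjects_whole(self, noisy_frames):
        from thumbrot.features import feature_table

        table, _ = feature_table(noisy_frames, include_subject=True)
        train_tab, test_tab = split_dataset(
            table, SplitSpec(seed=0, group_by_subject=True)
        )
        assert not set(train_tab["subject_id"]) & set(test_tab["subject_id"])

    def test_invalid_inputs(self):
        with pytest.raises(UsageError):
            SplitSpec(train_fraction=1.2)
        with pytest.raises(UsageError):
            split_dataset(pd.DataFrame(), SplitSpec())
        with pytest.raises(UsageError):
            split_dataset(pd.DataFrame({"tip_angle": [1.0, 2.0]}), SplitSpec())


class TestTrain:
    def test_linear_recovers_exact_linear_map(self):
        table = synthetic_table(n=100)
        results = train("linear", table, seed=0)
        pred = results.predict(table)
        assert np.allclose(pred, table["true_angle"], atol=1e-6)

    def test_trees_beat_linear_on_step_function(self):
        step = lambda X: np.where(X["tip_angle"] > 0.5, 60.0, 10.0)
        table = synthetic_table(n=400, fn=step)
        lin = evaluate(train("linear", table, seed=0), table)
        gbt = evaluate(
            train(
                ModelSpec(
                    "gradient_boosted_trees",
                    search_space={"est__n_estimators": [100]},
                    tuning_folds=3,
                ),
                table,
                seed=0,
            ),
            table,
        )
        assert gbt.rmse < lin.rmse

    def test_elastic_net_shrinks_to_mean_at_huge_alpha(self):
        table = synthetic_table(n=150, noise=0.5)
        spec = ModelSpec(
            "elastic_net", search_space={"est__alpha": [1e9], "est__l1_ratio": [0.5]}
        )
        results = train(spec, table, seed=0)
        pred = results.predict(table)
        assert np.allclose(pred, table["true_angle"].mean(), atol=1e-3)

    def test_unknown_family_rejected(self):
        with pytest.raises(UsageError):
            ModelSpec("random_forest")

    def test_too_few_rows_rejected(self):
        table = synthetic_table(n=6)
        with pytest.raises(UsageError, match="fold"):
            ThumbAngleModel.from_dataframe(table, spec=ModelSpec("linear", tuning_folds=5))

    def test_summary_mentions_family_and_features(self, fitted_gbt):
        text = fitted_gbt.summary()
        assert "gradient_boosted_trees" in text
        assert "norm_tip_size" in text

    def test_save_load_roundtrip_predictions(self, fitted_gbt, noisy_table, tmp_path):
        path = fitted_gbt.save(tmp_path / "model.pkl")
        loaded = ThumbAngleResults.load(path)
        assert loaded.feature_names == fitted_gbt.feature_names
        a = fitted_gbt.predict(noisy_table.head(20))
        b = loaded.predict(noisy_table.head(20))
        assert np.array_equal(a, b)


class TestEvaluate:
    def test_perfect_predictor(self):
        table = synthetic_table(n=100)
        report = evaluate(train("linear", table, seed=0), table)
        assert report.rmse == pytest.approx(0.0, abs=1e-6)
        assert report.mae == pytest.approx(0.0, abs=1e-6)
        assert report.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_per_angle_mean_and_sd_convention(self):
        """Residuals {+3, -3} at one level: mean 0, sample SD = 3*sqrt(2)...
        no — with n=2 and ddof=1, SD = |r1 - r2| / sqrt(2) = 4.2426;
        the documented sample convention is asserted by hand arithmetic."""

        class Stub:
            family = "stub"
            feature_names = list(PREDICTOR_COLUMNS)

            def predict(self, data):
                return np.array([27.0, 33.0, 10.0])

        table = synthetic_table(n=3).copy()
        table["true_angle"] = [30.0, 30.0, 10.0]
        report = evaluate(Stub(), table)
        row30 = report.per_angle[report.per_angle["angle"] == 30].iloc[0]
        assert row30["residual_mean"] == pytest.approx(0.0)
        assert row30["residual_sd"] == pytest.approx(np.std([3.0, -3.0], ddof=1))
        row10 = report.per_angle[report.per_angle["angle"] == 10].iloc[0]
        assert row10["residual_mean"] == pytest.approx(0.0)
        assert np.isnan(row10["residual_sd"])  # single observation

    def test_constant_predictor_reports_nan_correlation(self):
        class Constant:
            family = "stub"
            feature_names = list(PREDICTOR_COLUMNS)

            def predict(self, data):
                return np.full(len(data), 45.0)

        table = synthetic_table(n=50)
        with pytest.warns(UserWarning, match="Pearson"):
            report = evaluate(Constant(), table)
        assert np.isnan(report.pearson_r)

    def test_rmse_at_least_mae(self, fitted_gbt, noisy_split):
        _, test_tab = noisy_split
        report = evaluate(fitted_gbt, test_tab)
        assert report.rmse >= report.mae >= 0.0

    def test_grouped_means_consistent_with_overall_mean(self, fitted_gbt, noisy_split):
        _, test_tab = noisy_split
        report = evaluate(fitted_gbt, test_tab)
        weighted = (
            report.per_angle["residual_mean"] * report.per_angle["n"]
        ).sum() / report.per_angle["n"].sum()
        assert weighted == pytest.approx(report.residual_pairs["residual"].mean(), abs=1e-9)

    def test_residual_sign_convention(self):
        """residual = actual - predicted: over-prediction gives negative."""

        class Over:
            family = "stub"
            feature_names = list(PREDICTOR_COLUMNS)

            def predict(self, data):
                return np.full(len(data), 50.0)

        table = synthetic_table(n=30)
        table["true_angle"] = 40.0
        with pytest.warns(UserWarning):
            report = evaluate(Over(), table)
        assert np.all(report.residual_pairs["residual"] == -10.0)

    def test_empty_test_table_rejected(self, fitted_gbt):
        with pytest.raises(UsageError):
            evaluate(fitted_gbt, pd.DataFrame(columns=["true_angle", *PREDICTOR_COLUMNS]))


class TestCompareModels:
    def test_single_spec_rejected(self, noisy_table):
        with pytest.raises(UsageError):
            compare_models(["linear"], noisy_table)

    def test_linear_not_beaten_on_exactly_linear_labels(self):
        table = synthetic_table(n=300, noise=0.0)
        specs = [
            "linear",
            ModelSpec(
                "gradient_boosted_trees",
                search_space={"est__n_estimators": [100]},
                tuning_folds=3,
            ),
        ]
        cmp_ = compare_models(specs, table, SplitSpec(seed=0, stratify_by_angle=False))
        lin = next(r for r in cmp_.reports if r.family == "linear")
        assert lin.rmse <= 0.5  # exact linear structure, no noise

    def test_ranking_sorted_by_rmse(self, noisy_table):
        fast = {
            "linear": {},
            "elastic_net": {"est__alpha": [0.01], "est__l1_ratio": [0.5]},
        }
        specs = [
            ModelSpec(fam, search_space=grid, tuning_folds=3)
            for fam, grid in fast.items()
        ]
        cmp_ = compare_models(specs, noisy_table, SplitSpec(seed=2), seed=2)
        rmses = [r.rmse for r in cmp_.reports]
        assert rmses == sorted(rmses)
        assert set(cmp_.ranking) == {"linear", "elastic_net"}
        assert "RMSE" in cmp_.summary()
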