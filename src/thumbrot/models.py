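"""Regression models mapping the geometric predictors to the rotation angle.

Four families are supported — ordinary linear regression, ElasticNet,
RBF-kernel support-vector regression, and LightGBM gradient-boosted trees —
matching the comparison the method was validated with.  The API follows the
Model/Results idiom: :class:`ThumbAngleModel` is built from a labelled
feature table, its :meth:`~ThumbAngleModel.fit` tunes hyperparameters by
cross-validated RMSE on the training data only and returns a
:class:`ThumbAngleResults` that predicts, evaluates, and summarises.

Evaluation reports the triplet RMSE / MAE / Pearson r plus per-angle
residual statistics (residual = actual - predicted, grouped by true-angle
level), the layout used for the method's residual tables and plots.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from scipy import stats
from sklearn.base import clone
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import (
    GridSearchCV,
    GroupShuffleSplit,
    KFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .exceptions import FitError, UsageError
from .features import PREDICTOR_COLUMNS

__all__ = [
    "FAMILIES",
    "SplitSpec",
    "ModelSpec",
    "ModelReport",
    "ThumbAngleModel",
    "ThumbAngleResults",
    "split_dataset",
    "train",
    "evaluate",
    "compare_models",
    "ComparisonReport",
]

FAMILIES = ("linear", "elastic_net", "svm_regression", "gradient_boosted_trees")

#: Modest default search grids per family; the linear family has nothing to
#: tune.  Scaled families (ElasticNet, SVR) run behind a StandardScaler.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "linear": {},
    "elastic_net": {
        "est__alpha": [0.01, 0.1, 1.0],
        "est__l1_ratio": [0.2, 0.5, 0.8],
    },
    "svm_regression": {
        "est__C": [1.0, 10.0, 100.0],
        "est__epsilon": [0.1],
    },
    "gradient_boosted_trees": {
        "est__n_estimators": [100, 300],
        "est__learning_rate": [0.05, 0.1],
        "est__num_leaves": [31],
    },
}


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition policy.

    80/20 by default, stratified by true-angle level so every protocol
    angle appears in both partitions.  ``group_by_subject`` keeps each
    subject's frames in a single partition — stricter than the frame-level
    split the method was validated with, offered for leakage-sensitive use.
    """

    train_fraction: float = 0.80
    seed: int = 0
    stratify_by_angle: bool = True
    group_by_subject: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise UsageError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction!r}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """One regression family plus its hyperparameter search setup."""

    family: str
    search_space: Mapping[str, list] | None = None
    tuning_folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise UsageError(
                f"unknown model family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.tuning_folds < 2:
            raise UsageError("tuning_folds must be at least 2")

    @property
    def grid(self) -> dict[str, list]:
        return dict(self.search_space) if self.search_space is not None else DEFAULT_GRIDS[self.family]


def _label_column(table: pd.DataFrame) -> str:
    if "true_angle" not in table.columns:
        raise UsageError("table has no 'true_angle' label column")
    return "true_angle"


def split_dataset(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a labelled feature table into train and test partitions.

    The split is disjoint and exhaustive with exactly
    ``round(train_fraction * N)`` training rows, reproducible from the
    seed.  Stratification groups rows by rounded angle level; a grouped
    split uses the ``subject_id`` column instead.
    """
    spec = spec or SplitSpec()
    if len(table) == 0:
        raise UsageError("cannot split an empty table")
    label = _label_column(table)
    n_train = int(round(spec.train_fraction * len(table)))
    n_test = len(table) - n_train
    if n_train == 0 or n_test == 0:
        raise UsageError("split leaves an empty partition; adjust train_fraction")
    if n_test < 10:
        warnings.warn(
            f"test partition has only {n_test} row(s); metrics will be noisy",
            stacklevel=2,
        )
    if spec.group_by_subject:
        if "subject_id" not in table.columns:
            raise UsageError("group_by_subject requires a 'subject_id' column")
        splitter = GroupShuffleSplit(
            n_splits=1, train_size=spec.train_fraction, random_state=spec.seed
        )
        tr_idx, te_idx = next(splitter.split(table, groups=table["subject_id"]))
        return table.iloc[tr_idx], table.iloc[te_idx]
    strat = table[label].round().astype(int) if spec.stratify_by_angle else None
    train_tab, test_tab = train_test_split(
        table, train_size=n_train, random_state=spec.seed, stratify=strat
    )
    return train_tab, test_tab


def _build_estimator(family: str, seed: int) -> Pipeline:
    if family == "linear":
        est = LinearRegression()
    elif family == "elastic_net":
        est = ElasticNet(max_iter=10000, random_state=seed)
    elif family == "svm_regression":
        est = SVR(kernel="rbf", gamma="scale")
    elif family == "gradient_boosted_trees":
        est = LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1)
    else:  # pragma: no cover - guarded by ModelSpec
        raise UsageError(f"unknown model family {family!r}")
    steps = []
    if family in ("elastic_net", "svm_regression"):
        steps.append(("scale", StandardScaler()))
    steps.append(("est", est))
    return Pipeline(steps)


class ThumbAngleModel:
    """A regression family bound to training data, ready to fit.

    Parameters
    ----------
    endog : array-like
        Rotation-angle labels, degrees.
    exog : DataFrame
        Predictor matrix; columns define the feature manifest the fitted
        results will insist on at prediction time.
    spec : ModelSpec
        Family and hyperparameter search setup.
    """

    def __init__(self, endog, exog: pd.DataFrame, spec: ModelSpec):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = pd.DataFrame(exog).reset_index(drop=True)
        self.spec = spec
        if len(self.endog) != len(self.exog):
            raise UsageError("endog and exog lengths differ")
        if len(self.endog) < spec.tuning_folds * 2:
            raise UsageError(
                f"need at least {spec.tuning_folds * 2} rows for "
                f"{spec.tuning_folds}-fold tuning, got {len(self.endog)}"
            )
        self.feature_names = list(self.exog.columns)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        family: str = "gradient_boosted_trees",
        spec: ModelSpec | None = None,
        feature_columns: Sequence[str] | None = None,
    ) -> "ThumbAngleModel":
        """Build a model from a labelled feature table.

        Predictors default to the nine standard columns present in the
        table; ``subject_id`` and the label are never used as predictors.
        """
        label = _label_column(table)
        spec = spec or ModelSpec(family=family)
        if feature_columns is None:
            feature_columns = [c for c in PREDICTOR_COLUMNS if c in table.columns]
            if not feature_columns:
                feature_columns = [
                    c for c in table.columns if c not in (label, "subject_id")
                ]
        return cls(table[label], table[list(feature_columns)], spec)

    def fit(self, seed: int = 0) -> "ThumbAngleResults":
        """Tune hyperparameters by cross-validated RMSE and fit.

        The search uses k-fold CV on the training rows only (shuffled,
        seeded); the best configuration is refit on all training rows.
        """
        pipe = _build_estimator(self.spec.family, seed)
        grid = self.spec.grid
        X = self.exog
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if grid:
                    cv = KFold(self.spec.tuning_folds, shuffle=True, random_state=seed)
                    search = GridSearchCV(
                        pipe,
                        grid,
                        scoring="neg_root_mean_squared_error",
                        cv=cv,
                        n_jobs=1,
                        refit=True,
                    )
                    search.fit(X, self.endog)
                    est = search.best_estimator_
                    best_params = dict(search.best_params_)
                    cv_rmse = -float(search.best_score_)
                else:
                    est = clone(pipe)
                    est.fit(X, self.endog)
                    best_params = {}
                    cv_rmse = float("nan")
        except Exception as exc:
            raise FitError(
                f"fitting family {self.spec.family!r} failed: {exc}"
            ) from exc
        pred = est.predict(X)
        if not np.all(np.isfinite(pred)):
            raise FitError(
                f"family {self.spec.family!r} produced non-finite predictions "
                "on its own training data"
            )
        return ThumbAngleResults(
            model=self, estimator=est, best_params=best_params, cv_rmse=cv_rmse, seed=seed
        )


_SERIAL_VERSION = 1


@dataclass
class ThumbAngleResults:
    """A fitted angle regressor with its tuning record.

    ``predict`` accepts either a feature table (the manifest columns are
    selected by name) or a bare array in manifest order; ``evaluate``
    produces a :class:`ModelReport` on a labelled test table.
    """

    model: ThumbAngleModel
    estimator: Pipeline
    best_params: dict
    cv_rmse: float
    seed: int

    @property
    def family(self) -> str:
        return self.model.spec.family

    @property
    def feature_names(self) -> list[str]:
        return self.model.feature_names

    def predict(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in data.columns]
            if missing:
                raise UsageError(f"prediction input lacks feature columns {missing}")
            X = data[self.feature_names]
        else:
            arr = np.atleast_2d(np.asarray(data, dtype=float))
            if arr.shape[1] != len(self.feature_names):
                raise UsageError(
                    f"expected {len(self.feature_names)} features, got {arr.shape[1]}"
                )
            X = pd.DataFrame(arr, columns=self.feature_names)
        return np.asarray(self.estimator.predict(X), dtype=float)

    def evaluate(self, test_table: pd.DataFrame) -> "ModelReport":
        return evaluate(self, test_table)

    def summary(self) -> str:
        lines = [
            "Thumb rotation-angle regression results",
            "=" * 44,
            f"family:          {self.family}",
            f"n train rows:    {len(self.model.endog)}",
            f"features:        {', '.join(self.feature_names)}",
            f"tuned params:    {self.best_params or '(none to tune)'}",
            f"CV RMSE (train): {self.cv_rmse:.3f} deg"
            if np.isfinite(self.cv_rmse)
            else "CV RMSE (train): n/a",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        """Serialize estimator + feature manifest to a versioned file."""
        path = Path(path)
        payload = {
            "serial_version": _SERIAL_VERSION,
            "family": self.family,
            "feature_names": self.feature_names,
            "best_params": self.best_params,
            "cv_rmse": self.cv_rmse,
            "seed": self.seed,
            "estimator": self.estimator,
            "n_train": len(self.model.endog),
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "ThumbAngleResults":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("serial_version") != _SERIAL_VERSION:
            raise UsageError(
                f"unsupported model file version {payload.get('serial_version')!r}"
            )
        spec = ModelSpec(family=payload["family"])
        # Rebuild a minimal model shell carrying the manifest.
        shell = ThumbAngleModel.__new__(ThumbAngleModel)
        shell.spec = spec
        shell.feature_names = payload["feature_names"]
        shell.endog = np.zeros(payload["n_train"])
        shell.exog = pd.DataFrame(columns=payload["feature_names"])
        return ThumbAngleResults(
            model=shell,
            estimator=payload["estimator"],
            best_params=payload["best_params"],
            cv_rmse=payload["cv_rmse"],
            seed=payload["seed"],
        )


@dataclass
class ModelReport:
    """Test-set evaluation: headline metrics plus per-angle residuals.

    Residuals are actual minus predicted, degrees.  ``per_angle`` has one
    row per rounded true-angle level with the group's count, residual mean
    and sample (n-1) standard deviation; ``residual_pairs`` holds the raw
    (true_angle, residual) points for plotting.
    """

    family: str
    rmse: float
    mae: float
    pearson_r: float
    n_test: int
    per_angle: pd.DataFrame
    residual_pairs: pd.DataFrame

    def __post_init__(self) -> None:
        # Power-mean inequality: quadratic mean >= arithmetic mean of |r|.
        assert self.rmse >= 0.0 and self.mae >= 0.0
        assert self.rmse >= self.mae - 1e-9, (self.rmse, self.mae)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "rmse": self.rmse,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "n_test": self.n_test,
            "per_angle": self.per_angle.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True))
        return path

    def summary(self) -> str:
        lines = [
            f"family: {self.family}   n_test: {self.n_test}",
            f"RMSE {self.rmse:.2f} deg   MAE {self.mae:.2f} deg   "
            f"Pearson r {self.pearson_r:.3f}",
            "",
            "angle  n     resid mean  resid SD",
        ]
        for _, row in self.per_angle.iterrows():
            sd = f"{row['residual_sd']:.2f}" if np.isfinite(row["residual_sd"]) else "n/a"
            lines.append(
                f"{row['angle']:>5.0f}  {int(row['n']):<5d} "
                f"{row['residual_mean']:>9.2f}  {sd:>8}"
            )
        return "\n".join(lines)


def evaluate(results: ThumbAngleResults, test_table: pd.DataFrame) -> ModelReport:
    """Score a fitted model on a labelled test table.

    RMSE = sqrt(mean(residual^2)), MAE = mean(|residual|), Pearson r
    between actual and predicted.  A constant prediction (or constant
    labels) leaves r undefined; it is reported as NaN with a warning.
    """
    if len(test_table) == 0:
        raise UsageError("empty test table")
    label = _label_column(test_table)
    actual = test_table[label].to_numpy(dtype=float)
    predicted = results.predict(test_table)
    residual = actual - predicted
    rmse = float(np.sqrt(np.mean(residual**2)))
    mae = float(np.mean(np.abs(residual)))
    if len(actual) < 2 or np.std(actual) == 0.0 or np.std(predicted) == 0.0:
        warnings.warn(
            "Pearson r undefined (constant actual or predicted values); "
            "reporting NaN",
            stacklevel=2,
        )
        pearson = float("nan")
    else:
        pearson = float(stats.pearsonr(actual, predicted).statistic)
    df = pd.DataFrame(
        {"angle": np.round(actual).astype(int), "residual": residual}
    )
    grouped = (
        df.groupby("angle")["residual"]
        .agg(n="count", residual_mean="mean", residual_sd=lambda s: s.std(ddof=1))
        .reset_index()
        .sort_values("angle")
        .reset_index(drop=True)
    )
    pairs = pd.DataFrame({"true_angle": actual, "residual": residual})
    return ModelReport(
        family=results.family,
        rmse=rmse,
        mae=mae,
        pearson_r=pearson,
        n_test=len(actual),
        per_angle=grouped,
        residual_pairs=pairs,
    )


def train(
    spec: ModelSpec | str, train_table: pd.DataFrame, seed: int = 0
) -> ThumbAngleResults:
    """Fit one family on a labelled training table (functional wrapper)."""
    if isinstance(spec, str):
        spec = ModelSpec(family=spec)
    return ThumbAngleModel.from_dataframe(train_table, spec=spec).fit(seed=seed)


@dataclass
class ComparisonReport:
    """Per-family reports on an identical split, ranked by RMSE.

    Ties in RMSE are broken by MAE.
    """

    reports: list[ModelReport]
    results: list[ThumbAngleResults]

    @property
    def ranking(self) -> list[str]:
        return [r.family for r in self.reports]

    @property
    def best(self) -> ThumbAngleResults:
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": r.family,
                    "rmse": r.rmse,
                    "mae": r.mae,
                    "pearson_r": r.pearson_r,
                }
                for r in self.reports
            ]
        )

    def summary(self) -> str:
        out = ["Model comparison (ranked by test RMSE)", "=" * 40]
        for rank, r in enumerate(self.reports, 1):
            out.append(
                f"{rank}. {r.family:<24} RMSE {r.rmse:6.2f}  MAE {r.mae:6.2f}  "
                f"r {r.pearson_r:.3f}"
            )
        return "\n".join(out)


def compare_models(
    specs: Sequence[ModelSpec | str],
    table: pd.DataFrame,
    split: SplitSpec | None = None,
    seed: int = 0,
) -> ComparisonReport:
    """Train and evaluate several families on one identical split."""
    if len(specs) < 2:
        raise UsageError("compare_models needs at least two model specs")
    split = split or SplitSpec(seed=seed)
    train_tab, test_tab = split_dataset(table, split)
    fitted: list[ThumbAngleResults] = []
    reports: list[ModelReport] = []
    for spec in specs:
        res = train(spec, train_tab, seed=seed)
        fitted.append(res)
        reports.append(evaluate(res, test_tab))
    order = sorted(range(len(reports)), key=lambda i: (reports[i].rmse, reports[i].mae))
    return ComparisonReport(
        reports=[reports[i] for i in order], results=[fitted[i] for i in order]
    )
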