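"""Feature attribution and exploratory diagnostics.

Three tools interpret a fitted angle regressor:

* tree-ensemble *feature importance* — each tree's split gains are
  normalized to shares within the tree, and shares are averaged across
  trees, giving a probability vector over features;
* *Shapley values* — the game-theoretic per-prediction attribution.  With
  nine features, exact computation is cheap: all 2^9 feature coalitions are
  enumerated, absent features are marginalized over a background sample,
  and each feature's contribution is the Shapley-weighted average of its
  marginal gains.  Contributions plus the background baseline equal the
  model's prediction (additivity/efficiency);
* the *feature correlation matrix* — Pearson correlations among the
  predictors (and the label when present), the heatmap view used for
  exploratory analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CapabilityError, UsageError

__all__ = [
    "AttributionResult",
    "feature_importance",
    "tree_gain_table",
    "shapley_values",
    "correlation_matrix",
]


@dataclass(frozen=True)
class AttributionResult:
    """Per-feature attribution, either importance shares or Shapley values.

    ``kind`` is ``"importance"`` (shares, summing to 1) or ``"shapley"``
    (degrees, summing with ``baseline`` to the explained prediction).
    """

    per_feature: dict[str, float]
    kind: str
    baseline: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (feature, value, rank), largest |value| first."""
        items = sorted(
            self.per_feature.items(), key=lambda kv: abs(kv[1]), reverse=True
        )
        return pd.DataFrame(
            [
                {"feature": name, "value": val, "rank": i + 1}
                for i, (name, val) in enumerate(items)
            ]
        )

    def ranking(self) -> list[str]:
        return list(self.to_frame()["feature"])


def _extract_booster(model):
    """Pull a LightGBM booster out of the accepted model wrappers."""
    from .models import ThumbAngleResults

    if isinstance(model, ThumbAngleResults):
        model = model.estimator
    # unwrap sklearn pipeline
    if hasattr(model, "named_steps"):
        model = model.named_steps.get("est", model)
    if hasattr(model, "booster_"):
        return model.booster_, getattr(model, "feature_name_", None)
    if hasattr(model, "trees_to_dataframe"):
        return model, None
    return None, None


def tree_gain_table(model) -> pd.DataFrame:
    """Per-split gain records (columns: tree, feature, gain) of a tree
    ensemble.  Raises :class:`CapabilityError` for non-tree models."""
    booster, names = _extract_booster(model)
    if booster is None:
        raise CapabilityError(
            "feature importance requires a tree-ensemble model exposing "
            "per-split gain (the gradient_boosted_trees family)"
        )
    df = booster.trees_to_dataframe()
    splits = df[df["split_feature"].notna()]
    return pd.DataFrame(
        {
            "tree": splits["tree_index"].to_numpy(),
            "feature": splits["split_feature"].to_numpy(),
            "gain": splits["split_gain"].to_numpy(dtype=float),
        }
    )


def importance_from_gains(
    gains: pd.DataFrame, feature_names: Sequence[str] | None = None
) -> AttributionResult:
    """Importance shares from a per-split gain table.

    Within each tree the per-feature gains are normalized by the tree's
    total gain; those per-tree shares are then averaged over all trees with
    at least one split.  The result is a probability vector.
    """
    required = {"tree", "feature", "gain"}
    if not required.issubset(gains.columns):
        raise UsageError(f"gain table needs columns {sorted(required)}")
    per_tree = gains.groupby(["tree", "feature"])["gain"].sum().reset_index()
    totals = per_tree.groupby("tree")["gain"].transform("sum")
    per_tree = per_tree[totals > 0].copy()
    per_tree["share"] = per_tree["gain"] / totals[totals > 0]
    n_trees = per_tree["tree"].nunique()
    if n_trees == 0:
        raise UsageError("no tree in the ensemble has a positive-gain split")
    shares = (per_tree.groupby("feature")["share"].sum() / n_trees).to_dict()
    if feature_names is not None:
        shares = {name: shares.get(name, 0.0) for name in feature_names}
    return AttributionResult(per_feature=shares, kind="importance")


def feature_importance(model) -> AttributionResult:
    """Normalized gain-share importance of a fitted tree ensemble."""
    from .models import ThumbAngleResults

    feature_names = None
    if isinstance(model, ThumbAngleResults):
        feature_names = model.feature_names
    return importance_from_gains(tree_gain_table(model), feature_names)


# --- Shapley values -------------------------------------------------------


def _predict_fn(model) -> tuple[Callable[[np.ndarray], np.ndarray], list[str] | None]:
    from .models import ThumbAngleResults

    if isinstance(model, ThumbAngleResults):
        names = model.feature_names
        return (lambda X: model.predict(X)), names
    if callable(model) and not hasattr(model, "predict"):
        return model, None
    return (lambda X: np.asarray(model.predict(X), dtype=float)), None


def shapley_values(
    model,
    row,
    background,
    feature_names: Sequence[str] | None = None,
) -> AttributionResult:
    """Exact Shapley attribution of one prediction.

    For every coalition S of present features, the value function
    v(S) = E_b[f(x_S, b_!S)] replaces absent features by background rows
    and averages the prediction.  Feature i's Shapley value is the
    coalition-weighted average of v(S + i) - v(S) over all S not
    containing i, with weight |S|! (d - |S| - 1)! / d!.  All 2^d
    coalitions are enumerated — exact, and cheap for the nine-feature
    setting this package targets.

    Parameters
    ----------
    model : fitted results, estimator, or callable X -> predictions.
    row : the observation to explain (Series, dict, or 1D array in
        feature order).
    background : DataFrame or 2D array over which absent features are
        marginalized (typically the training partition).
    feature_names : required when model and row carry no names.

    Returns an :class:`AttributionResult` with ``baseline`` = v(empty set)
    (the mean background prediction); baseline plus the contributions
    equals the model's prediction for ``row``.
    """
    predict, model_names = _predict_fn(model)
    if isinstance(background, pd.DataFrame):
        bg_names = list(background.columns)
    else:
        bg_names = None
    names = list(feature_names or model_names or bg_names or [])

    if isinstance(row, pd.Series):
        row_names = list(row.index)
        if names and set(names) - set(row_names):
            raise UsageError(
                f"row lacks features {sorted(set(names) - set(row_names))}"
            )
        names = names or row_names
        x = row[names].to_numpy(dtype=float)
    elif isinstance(row, dict):
        names = names or list(row)
        missing = set(names) - set(row)
        if missing:
            raise UsageError(f"row lacks features {sorted(missing)}")
        x = np.array([row[n] for n in names], dtype=float)
    else:
        x = np.asarray(row, dtype=float).ravel()
        if not names:
            names = [f"x{i}" for i in range(x.size)]
        if x.size != len(names):
            raise UsageError(
                f"row has {x.size} values but {len(names)} feature names"
            )

    if isinstance(background, pd.DataFrame):
        missing = set(names) - set(background.columns)
        if missing:
            raise UsageError(f"background lacks features {sorted(missing)}")
        B = background[names].to_numpy(dtype=float)
    else:
        B = np.atleast_2d(np.asarray(background, dtype=float))
        if B.shape[1] != len(names):
            raise UsageError(
                f"background has {B.shape[1]} columns but {len(names)} features"
            )
    if B.shape[0] == 0:
        raise UsageError("background set is empty")

    d = len(names)
    n_bg = B.shape[0]
    subsets = list(range(1 << d))
    # Build one big prediction batch: for each subset, the background rows
    # with the subset's features replaced by the explained row's values.
    batch = np.empty((len(subsets) * n_bg, d), dtype=float)
    for k, mask in enumerate(subsets):
        block = B.copy()
        for i in range(d):
            if mask >> i & 1:
                block[:, i] = x[i]
        batch[k * n_bg : (k + 1) * n_bg] = block
    preds = np.asarray(predict(batch), dtype=float).reshape(len(subsets), n_bg)
    v = preds.mean(axis=1)  # v[mask] = value of coalition `mask`

    fact = [math.factorial(k) for k in range(d + 1)]
    phi = np.zeros(d)
    for mask in subsets:
        s = bin(mask).count("1")
        for i in range(d):
            if mask >> i & 1:
                continue
            w = fact[s] * fact[d - s - 1] / fact[d]
            phi[i] += w * (v[mask | (1 << i)] - v[mask])
    return AttributionResult(
        per_feature=dict(zip(names, phi.tolist())),
        kind="shapley",
        baseline=float(v[0]),
    )


# --- correlation matrix ---------------------------------------------------


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the numeric feature columns.

    Symmetric with unit diagonal; includes ``true_angle`` when present.
    Constant columns produce NaN rows/columns and a warning.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise UsageError("need at least two rows to correlate")
    constant = [c for c in numeric.columns if numeric[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant column(s) {constant}: correlation undefined, NaN entries",
            stacklevel=2,
        )
    return numeric.corr(method="pearson")
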