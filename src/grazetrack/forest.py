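"""Random-Forest behavior classifier: tuning, importance, partial dependence.

The classifier is a standard Random Forest (scikit-learn ensemble
underneath).  What this module adds is the study protocol around it:

* an explicit grid search over ``mtry`` (features tried per split) and
  ``ntree`` (forest size) scored by repeated stratified cross-validation,
  with deterministic tie-breaking toward the smaller, more parsimonious
  setting;
* *mean decrease in Gini* variable importance computed from the tree
  internals — for each feature, the count-weighted Gini-impurity
  decrease is accumulated over every node split on that feature in
  every tree and the total divided by the number of trees (this is the
  classical unnormalized definition, not the normalized importance the
  ensemble object exposes);
* partial-dependence curves on the vote-share scale: the probability a
  row is called nongrazing is the fraction of trees voting nongrazing,
  and the curve at a grid value v is that probability averaged over the
  training rows with the target column overwritten by v.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

NONGRAZING = "nongrazing"


class DegenerateLabelsError(ValueError):
    """Training labels contain fewer than two classes."""


class ModelConfigError(ValueError):
    """Hyperparameter setting incompatible with the data."""


@dataclass
class ModelConfig:
    """Hyperparameters and evaluation protocol for the behavior model."""

    mtry_grid: tuple = tuple(range(1, 11))
    ntree_grid: tuple = (500, 1000, 1500, 2000)
    selection_metric: str = "accuracy"  # or "kappa"
    cv_folds: int = 10
    cv_repeats: int = 5
    seed: int = 0
    class_labels: tuple = ("grazing", "nongrazing")
    # fixed setting used when fitting/evaluating without a grid search
    mtry: int | None = None  # None -> floor(sqrt(n_features))
    ntree: int = 500
    # minimum rows per leaf; raise it when fitting low-dimensional models
    # whose fully-grown trees would memorize single observations
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if not self.mtry_grid or not self.ntree_grid:
            raise ModelConfigError("hyperparameter grids must be non-empty")
        if self.selection_metric not in ("accuracy", "kappa"):
            raise ModelConfigError("selection_metric must be 'accuracy' or 'kappa'")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise ModelConfigError("cv_folds >= 2 and cv_repeats >= 1 required")


@dataclass
class FittedModel:
    """A trained forest plus the bookkeeping needed to reproduce it."""

    estimator: RandomForestClassifier
    mtry: int
    ntree: int
    feature_names: list[str]
    seed: int

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_


@dataclass
class PartialDependenceCurve:
    """Marginal effect of one feature on the nongrazing vote share."""

    feature: str
    grid: np.ndarray
    prob_nongrazing: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.prob_nongrazing = np.asarray(self.prob_nongrazing, dtype=float)
        if self.grid.shape != self.prob_nongrazing.shape:
            raise ValueError("grid and probabilities must align")
        if len(self.grid) > 1 and np.any(np.diff(self.grid) < 0):
            raise ValueError("grid must be sorted ascending")


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    arr = np.asarray(features, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def fit_forest(
    features, labels, config: ModelConfig, mtry: int | None = None, ntree: int | None = None,
    seed: int | None = None,
) -> FittedModel:
    """Fit one forest with a fixed hyperparameter setting."""
    X, names = _as_matrix(features)
    y = np.asarray(labels, dtype=object)
    if np.any(pd.isna(X)):
        raise ValueError("features contain missing values; filter rows first")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    p = X.shape[1]
    m = mtry if mtry is not None else (config.mtry if config.mtry is not None else int(np.sqrt(p)))
    m = max(1, m)
    if m > p:
        raise ModelConfigError(f"mtry={m} exceeds the {p} available features")
    t = ntree if ntree is not None else config.ntree
    rs = int(seed if seed is not None else config.seed) % 2**31
    est = RandomForestClassifier(
        n_estimators=t,
        max_features=m,
        min_samples_leaf=config.min_samples_leaf,
        random_state=rs,
        n_jobs=1,
    )
    est.fit(X, y)
    return FittedModel(estimator=est, mtry=m, ntree=t, feature_names=names, seed=rs)


def vote_share_nongrazing(model: FittedModel, features) -> np.ndarray:
    """Fraction of trees voting nongrazing for each row."""
    X, _ = _as_matrix(features)
    classes = list(model.estimator.classes_)
    idx = classes.index(NONGRAZING)
    votes = np.zeros(X.shape[0])
    for tree in model.estimator.estimators_:
        votes += tree.predict(X) == idx
    return votes / len(model.estimator.estimators_)


def predict(model: FittedModel, features) -> np.ndarray:
    """Majority-vote class per row."""
    share = vote_share_nongrazing(model, features)
    grazing = [c for c in model.estimator.classes_ if c != NONGRAZING][0]
    return np.where(share > 0.5, NONGRAZING, grazing).astype(object)


def tune_and_train(features, labels, config: ModelConfig):
    """Explicit (mtry, ntree) grid search with repeated-CV scoring.

    Every pair is scored by the configured repeated stratified CV; the
    winner maximizes the selection metric with ties broken toward
    smaller ``mtry``, then smaller ``ntree``.  The final model is refit
    on all rows with the winning pair.  Returns ``(FittedModel,
    report)`` where the report is one row per grid point.
    """
    from .evaluation import cross_validate  # deferred: evaluation imports this module

    X, names = _as_matrix(features)
    p = X.shape[1]
    if max(config.mtry_grid) > p:
        raise ModelConfigError(
            f"mtry grid reaches {max(config.mtry_grid)} but only {p} features are present"
        )
    rows = []
    best = None
    for m, t in sorted(product(config.mtry_grid, config.ntree_grid)):
        cv = cross_validate(features, labels, replace(config, mtry=m, ntree=t))
        score = cv.mean_accuracy if config.selection_metric == "accuracy" else cv.mean_kappa
        rows.append(
            {
                "mtry": m,
                "ntree": t,
                "cv_accuracy": cv.mean_accuracy,
                "cv_kappa": cv.mean_kappa,
                "score": score,
            }
        )
        if best is None or score > best[0] + 1e-12:
            best = (score, m, t)
    _, m_best, t_best = best
    model = fit_forest(features, labels, config, mtry=m_best, ntree=t_best)
    report = pd.DataFrame(rows)
    report.attrs["selected"] = {"mtry": m_best, "ntree": t_best}
    return model, report


def gini_importance(model: FittedModel) -> pd.DataFrame:
    """Mean decrease in Gini per feature, with ranks.

    For every tree and every internal node split on feature j, the
    impurity decrease ``n_node * G_node - n_left * G_left - n_right *
    G_right`` (sample-count weighted) is accumulated into feature j's
    total; totals are divided by the number of trees.
    """
    p = len(model.feature_names)
    acc = np.zeros(p)
    for est in model.estimator.estimators_:
        t = est.tree_
        left, right = t.children_left, t.children_right
        internal = left != -1
        w, g = t.weighted_n_node_samples, t.impurity
        dec = w[internal] * g[internal]
        dec = dec - w[left[internal]] * g[left[internal]]
        dec = dec - w[right[internal]] * g[right[internal]]
        np.add.at(acc, t.feature[internal], dec)
    acc = acc / len(model.estimator.estimators_)
    out = pd.DataFrame({"feature": model.feature_names, "mean_decrease_gini": acc})
    out["rank"] = out["mean_decrease_gini"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank").reset_index(drop=True)


def leaf_probability_nongrazing(model: FittedModel, features) -> np.ndarray:
    """Mean per-tree leaf class fraction of nongrazing for each row.

    Unlike the vote share (which thresholds each tree's leaf at its
    majority and therefore estimates an indicator of the decision
    boundary), the leaf-fraction average tracks the conditional class
    probability itself.
    """
    X, _ = _as_matrix(features)
    classes = list(model.estimator.classes_)
    idx = classes.index(NONGRAZING)
    return model.estimator.predict_proba(X)[:, idx]


def partial_dependence(
    model: FittedModel,
    features,
    feature_name: str,
    grid_size: int = 50,
    grid_percentiles: tuple = (5.0, 95.0),
    max_rows: int | None = 1000,
    seed: int = 0,
    prob: str = "vote",
    grid: np.ndarray | None = None,
) -> PartialDependenceCurve:
    """Partial dependence of the nongrazing probability on one feature.

    The grid spans the feature's 5th–95th percentile (field convention
    that keeps the curve inside the data support); at each grid value
    the named column is overwritten in every (sub-sampled) training row
    and the predicted nongrazing probability averaged.  ``prob`` picks
    the probability scale: ``"vote"`` (fraction of trees voting
    nongrazing, the reporting convention) or ``"leaf"`` (mean leaf class
    fraction, which tracks the conditional probability and is the right
    scale when a threshold is read off the curve).
    """
    if prob not in ("vote", "leaf"):
        raise ValueError("prob must be 'vote' or 'leaf'")
    if isinstance(features, pd.DataFrame):
        if feature_name not in features.columns:
            raise KeyError(f"unknown feature {feature_name!r}")
        col = list(features.columns).index(feature_name)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if feature_name not in model.feature_names:
            raise KeyError(f"unknown feature {feature_name!r}")
        col = model.feature_names.index(feature_name)

    if max_rows is not None and X.shape[0] > max_rows:
        rng = np.random.default_rng(seed % 2**31)
        X = X[rng.choice(X.shape[0], max_rows, replace=False)]

    if grid is None:
        vals = X[:, col]
        lo, hi = np.percentile(vals, grid_percentiles)
        grid = np.unique(np.linspace(lo, hi, grid_size))
    else:
        grid = np.sort(np.asarray(grid, dtype=float))

    n = X.shape[0]
    stacked = np.tile(X, (len(grid), 1))
    for k, v in enumerate(grid):
        stacked[k * n : (k + 1) * n, col] = v
    scorer = vote_share_nongrazing if prob == "vote" else leaf_probability_nongrazing
    share = scorer(model, stacked)
    probs = share.reshape(len(grid), n).mean(axis=1)
    return PartialDependenceCurve(feature=feature_name, grid=grid, prob_nongrazing=probs)
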