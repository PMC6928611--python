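"""Model evaluation: agreement metrics, repeated CV, interval sweep,
and threshold extraction from partial-dependence curves.

Overall accuracy is the fraction of correctly classified fixes;
per-class accuracy is row-wise recall (correct calls of a class over
all fixes observed in that class); Cohen's κ corrects agreement for
chance using the row × column marginal expectation,

    kappa = (p_o - p_e) / (1 - p_e),

and is the preferred score here because grazing dominates the class mix
(~80%), so raw accuracy flatters a classifier that ignores nongrazing.

The interval sweep re-evaluates the movement-metric model for every
time interval T on the 100–800 s grid: the feature set is restricted to
columns with lag <= T / cadence, incomplete rows are dropped, and the
repeated-CV metrics recorded.  The optimal interval is the smallest T
whose mean κ comes within a tolerance of the best mean κ over all T —
a formalization of "κ has stabilized".  Posture-only (tri-axial) models
have no window, so their metrics are constant across T by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import forest as _forest
from .forest import ModelConfig, PartialDependenceCurve

GRAZING = "grazing"
NONGRAZING = "nongrazing"


@dataclass
class ConfusionMatrix:
    """2x2 observed x predicted counts, rows observed, columns predicted."""

    counts: np.ndarray
    labels: tuple = (GRAZING, NONGRAZING)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square on the label set")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_pairs(cls, observed, predicted, labels=(GRAZING, NONGRAZING)) -> "ConfusionMatrix":
        obs = np.asarray(observed, dtype=object)
        pred = np.asarray(predicted, dtype=object)
        if obs.shape != pred.shape:
            raise ValueError("observed and predicted must align")
        k = len(labels)
        counts = np.zeros((k, k), dtype=np.int64)
        index = {lab: i for i, lab in enumerate(labels)}
        for o, p in zip(obs, pred):
            counts[index[o], index[p]] += 1
        return cls(counts=counts, labels=tuple(labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label sets differ")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass
class EvalReport:
    """Agreement metrics for one confusion matrix."""

    overall_accuracy: float
    kappa: float
    per_class_accuracy: dict
    n: int
    degenerate_marginals: bool = False

    @property
    def defined(self) -> bool:
        return self.n > 0


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Overall accuracy, row-wise per-class accuracy, and Cohen's κ.

    An empty matrix yields NaN metrics (flagged via ``n == 0``); if both
    marginals are degenerate (chance agreement is 1) κ is defined as 0
    and flagged.
    """
    n = cm.total
    if n == 0:
        return EvalReport(
            overall_accuracy=math.nan,
            kappa=math.nan,
            per_class_accuracy={lab: math.nan for lab in cm.labels},
            n=0,
        )
    diag = np.diag(cm.counts).astype(float)
    rows = cm.row_totals().astype(float)
    cols = cm.col_totals().astype(float)
    overall = float(diag.sum() / n)
    per_class = {
        lab: (float(diag[i] / rows[i]) if rows[i] > 0 else math.nan)
        for i, lab in enumerate(cm.labels)
    }
    p_e = float((rows * cols).sum() / (n * n))
    if p_e >= 1.0 - 1e-15:
        return EvalReport(overall, 0.0, per_class, n, degenerate_marginals=True)
    kappa = (overall - p_e) / (1.0 - p_e)
    return EvalReport(overall, float(kappa), per_class, n)


def confusion(observed, predicted) -> ConfusionMatrix:
    """2x2 tally of observed vs predicted behavior."""
    return ConfusionMatrix.from_pairs(observed, predicted)


# --------------------------------------------------------------------------
# Repeated stratified cross-validation
# --------------------------------------------------------------------------


@dataclass
class CVResult:
    """Out-of-fold results of repeated stratified cross-validation."""

    matrices: list  # one pooled ConfusionMatrix per repeat
    reports: list  # one EvalReport per repeat
    mean_accuracy: float
    sd_accuracy: float
    mean_kappa: float
    sd_kappa: float
    n: int


def cross_validate(features, labels, config: ModelConfig) -> CVResult:
    """Stratified k-fold CV repeated with distinct fold seeds.

    Every row is scored exactly once per repeat; out-of-fold predictions
    are pooled into one confusion matrix per repeat and the reported
    metrics are means (with SDs) over repeats.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else None
    y = np.asarray(labels, dtype=object)
    if len(y) != X.shape[0]:
        raise ValueError("features and labels must align")

    matrices, reports = [], []
    for r in range(config.cv_repeats):
        fold_seed = (int(config.seed) + 7919 * (r + 1)) % 2**31
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=fold_seed)
        pred = np.empty(len(y), dtype=object)
        for f, (tr, te) in enumerate(skf.split(X, y.astype(str))):
            model = _forest.fit_forest(
                pd.DataFrame(X[tr], columns=names) if names else X[tr],
                y[tr],
                config,
                seed=(fold_seed + 131 * f) % 2**31,
            )
            pred[te] = _forest.predict(model, X[te])
        cm = ConfusionMatrix.from_pairs(y, pred, labels=config.class_labels)
        matrices.append(cm)
        reports.append(metrics(cm))
    acc = np.array([rep.overall_accuracy for rep in reports])
    kap = np.array([rep.kappa for rep in reports])
    return CVResult(
        matrices=matrices,
        reports=reports,
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std(ddof=0)),
        mean_kappa=float(kap.mean()),
        sd_kappa=float(kap.std(ddof=0)),
        n=len(y),
    )


# --------------------------------------------------------------------------
# Interval sweep
# --------------------------------------------------------------------------


@dataclass
class SweepReport:
    """Per-interval evaluation of each model type, plus the optimum."""

    table: pd.DataFrame  # interval_s, model_type, metrics, n_rows, top features
    optimal_interval_s: float | None
    delta: float


def _complete_rows(frame: pd.DataFrame, cols: list[str], label_ok: np.ndarray) -> np.ndarray:
    return label_ok & ~frame[cols].isna().any(axis=1).to_numpy()


def interval_sweep(
    gps_features: pd.DataFrame,
    accel_features: pd.DataFrame,
    labels,
    config: ModelConfig,
    intervals=tuple(range(100, 801, 50)),
    model_types=("gps", "tri", "gps-tri"),
    cadence_s: float = 50.0,
    delta: float = 0.05,
    include_angles: bool = True,
    min_per_fold_per_class: int = 5,
) -> SweepReport:
    """Evaluate each model type at each time interval.

    GPS feature sets are restricted per interval (lag <= T / cadence)
    and rows missing any required column are dropped for that interval;
    the posture (tri-axial) feature set has no window so it is evaluated
    once on all labeled rows and repeated across intervals.  Intervals
    whose retained rows fall below ``min_per_fold_per_class`` for either
    class are skipped.  The optimal interval is the smallest T whose
    mean κ (GPS model) is within ``delta`` of the maximum over T.
    """
    from .accel import FEATURE_COLUMNS as TRI_COLUMNS
    from .geo import model_columns_for_interval

    y = np.asarray(labels, dtype=object)
    label_ok = np.array([l in (GRAZING, NONGRAZING) for l in y])
    rows = []

    tri_cache = None
    if "tri" in model_types or "gps-tri" in model_types:
        mask = label_ok & ~accel_features[TRI_COLUMNS].isna().any(axis=1).to_numpy()
        if mask.sum() > 0 and len(np.unique(y[mask])) == 2:
            tri_cache = cross_validate(accel_features.loc[mask, TRI_COLUMNS], y[mask], config)
            tri_model = _forest.fit_forest(
                accel_features.loc[mask, TRI_COLUMNS], y[mask], config
            )
            tri_top = list(_forest.gini_importance(tri_model)["feature"].head(4))

    for T in intervals:
        gps_cols = model_columns_for_interval(T, cadence_s, include_angles)
        gps_mask = _complete_rows(gps_features, gps_cols, label_ok)

        for model_type in model_types:
            if model_type == "tri":
                if tri_cache is None:
                    continue
                cv, top, n_rows = tri_cache, tri_top, int(tri_cache.n)
            else:
                if model_type == "gps":
                    feats = gps_features.loc[gps_mask, gps_cols]
                    mask = gps_mask
                else:  # gps-tri
                    mask = gps_mask & ~accel_features[TRI_COLUMNS].isna().any(axis=1).to_numpy()
                    feats = pd.concat(
                        [
                            gps_features.loc[mask, gps_cols].reset_index(drop=True),
                            accel_features.loc[mask, TRI_COLUMNS].reset_index(drop=True),
                        ],
                        axis=1,
                    )
                y_sub = y[mask]
                counts = pd.Series(y_sub).value_counts()
                if (
                    len(counts) < 2
                    or counts.min() < min_per_fold_per_class * config.cv_folds
                ):
                    continue
                cv = cross_validate(feats, y_sub, config)
                fitted = _forest.fit_forest(feats, y_sub, config)
                top = list(_forest.gini_importance(fitted)["feature"].head(4))
                n_rows = int(mask.sum())
            rows.append(
                {
                    "interval_s": T,
                    "model_type": model_type,
                    "accuracy_mean": cv.mean_accuracy,
                    "accuracy_sd": cv.sd_accuracy,
                    "kappa_mean": cv.mean_kappa,
                    "kappa_sd": cv.sd_kappa,
                    "n_rows": n_rows,
                    "top_features": ",".join(top),
                }
            )

    table = pd.DataFrame(rows)
    optimal = None
    if len(table) and "gps" in model_types:
        gps_tab = table[table["model_type"] == "gps"].sort_values("interval_s")
        if len(gps_tab):
            best = gps_tab["kappa_mean"].max()
            ok = gps_tab[gps_tab["kappa_mean"] >= best - delta]
            optimal = float(ok["interval_s"].iloc[0])
    return SweepReport(table=table, optimal_interval_s=optimal, delta=delta)


# --------------------------------------------------------------------------
# Threshold extraction from partial-dependence curves
# --------------------------------------------------------------------------


@dataclass
class ThresholdResult:
    """Plateau threshold read off a partial-dependence curve."""

    found: bool
    threshold: float | None
    plateau_level: float | None
    low_confidence: bool = False


def threshold_from_pd(curve: PartialDependenceCurve, eps: float = 0.02) -> ThresholdResult:
    """Smallest grid value from which the curve stays at its plateau.

    The plateau level is the mean over the top decile of grid positions;
    the threshold is the first grid value after which every point stays
    within ``eps`` of that level.  A curve with overall range <= eps is
    structureless (no threshold); a threshold landing inside the
    plateau-defining decile (e.g. a monotone ramp) is flagged low
    confidence.
    """
    p = curve.prob_nongrazing
    g = curve.grid
    if len(g) == 0:
        return ThresholdResult(found=False, threshold=None, plateau_level=None)
    if float(np.nanmax(p) - np.nanmin(p)) <= eps:
        return ThresholdResult(found=False, threshold=None, plateau_level=float(np.nanmean(p)))
    tail = max(1, math.ceil(0.1 * len(g)))
    plateau = float(np.nanmean(p[-tail:]))
    # a curve still drifting through its own tail (e.g. a monotone ramp)
    # would never settle within eps of the tail mean; widen the band to
    # the tail's own spread so such curves yield an edge threshold
    # flagged low-confidence rather than no threshold at all
    tol = max(eps, float(np.nanmax(np.abs(p[-tail:] - plateau))))
    within = np.abs(p - plateau) <= tol
    # smallest k with all(within[k:])
    k = len(g)
    for j in range(len(g) - 1, -1, -1):
        if within[j]:
            k = j
        else:
            break
    if k >= len(g):
        return ThresholdResult(found=False, threshold=None, plateau_level=plateau)
    return ThresholdResult(
        found=True,
        threshold=float(g[k]),
        plateau_level=plateau,
        low_confidence=k >= len(g) - tail,
    )
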