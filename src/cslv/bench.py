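"""Model-evaluation harness: task construction, cross-validated model
search with a leaderboard and stacked ensembles, repeated-holdout AUC,
the grouped-mean height curve, and permutation feature importance.

The search emulates an AutoML-style protocol with a deterministic trial
budget instead of a wall clock: a fixed zoo of model families
(regularized linear/logistic, gradient-boosted trees, random forest,
small feed-forward network) is evaluated over fixed per-family
hyperparameter grids, every candidate scored by k-fold cross-validated
out-of-fold predictions, and two stacked ensembles (all models / best
of each family) are added on top.  Everything is reproducible from one
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone, is_classifier
from sklearn.ensemble import (
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
    StackingClassifier,
    StackingRegressor,
)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

CLASSIFICATION = "binary_classification"
REGRESSION = "regression"


@dataclass
class TaskSpec:
    """What to predict and how to evaluate it.

    For classification, ``positive``/``negative`` name the two class
    labels drawn from ``label_column``; for regression the target is
    ``target`` (height) and predictors are age plus every CSLV column,
    with under-age samples removed.
    """

    mode: str
    positive: str | None = None
    negative: str | None = None
    label_column: str = "group_label"
    target: str = "height"
    feature_columns: list[str] | None = None
    train_fraction: float = 0.8
    n_repeats: int = 5
    cv_folds: int = 10
    trial_budget: int = 24
    min_age: float = 21.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class RocResult:
    """An ROC curve (thresholds at every distinct score) and its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class RepeatedAuc:
    aucs: list[float]
    mean: float
    sd: float
    n_repeats: int


@dataclass
class GroupedCurve:
    """Samples ranked by prediction, cut into near-equal groups."""

    table: pd.DataFrame  # columns: group, size, mean_predicted, mean_actual
    n_groups: int


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # columns: feature, importance_mean, importance_sd
    base_score: float
    metric: str
    n_repeats: int


@dataclass
class Leaderboard:
    """Ranked candidates by cross-validated metric (AUC desc / RMSE asc)."""

    table: pd.DataFrame  # columns: rank, model_id, family, metric
    metric: str


# ---------------------------------------------------------------------------
# ROC / AUC


def auc_roc(scores, labels) -> RocResult:
    """ROC curve and AUC for binary labels.

    AUC equals the Mann-Whitney statistic P(score_pos > score_neg) +
    0.5 * P(tie); the reported value is the trapezoidal area under the
    full curve (no intermediate points dropped).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be 1-d and the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# Task construction


def build_task(
    features: pd.DataFrame, phenotypes: pd.DataFrame, spec: TaskSpec
) -> pd.DataFrame:
    """Join features with phenotypes and apply the task's filters.

    Returns a modeling table whose first column is the target:
    ``label`` (1 = positive class) for classification, or the
    regression target.  Regression predictors are age plus the feature
    columns only — sex and group label never enter.
    """
    pheno = phenotypes.set_index("sample_id")
    common = features.index.intersection(pheno.index)
    feats = features.loc[common]
    pheno = pheno.loc[common]
    feature_cols = spec.feature_columns or list(features.columns)

    if spec.mode == CLASSIFICATION:
        if spec.positive is None or spec.negative is None:
            raise ValueError("classification needs positive and negative labels")
        labels = pheno[spec.label_column]
        mask = labels.isin([spec.positive, spec.negative])
        y = (labels[mask] == spec.positive).astype(int)
        counts = y.value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError(
                f"need at least 2 samples per class for "
                f"({spec.positive!r}, {spec.negative!r}); got {counts.to_dict()}"
            )
        table = feats.loc[mask, feature_cols].copy()
        table.insert(0, "label", y)
        return table

    # regression: height ~ age + CSLV, adults only, no missing target
    mask = (pheno["age"] >= spec.min_age) & pheno[spec.target].notna()
    table = feats.loc[mask, feature_cols].copy()
    table.insert(0, "age", pheno.loc[mask, "age"])
    table.insert(0, spec.target, pheno.loc[mask, spec.target])
    return table


def split_counts(n: int, train_fraction: float = 0.8) -> tuple[int, int]:
    """Train/test sizes for an n-row table: floor of the fractional
    product, exact when n * train_fraction is an integer."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    product = n * train_fraction
    nearest = round(product)
    # snap to integer when the exact product is integral but the binary
    # float representation is a hair off (e.g. 161820 * 0.8)
    if math.isclose(product, nearest, rel_tol=0.0, abs_tol=1e-9 * max(1.0, n)):
        n_train = int(nearest)
    else:
        n_train = int(math.floor(product))
    return n_train, n - n_train


# ---------------------------------------------------------------------------
# Model zoo


def _family_grid(mode: str, seed: int) -> list[tuple[str, str, object]]:
    """The fixed candidate zoo: (family, model_id, estimator) triples,
    interleaved across families so a trial budget keeps every family."""
    rs = seed % (2**31)
    if mode == CLASSIFICATION:
        grids = {
            "glm": [
                ("glm_C0.1", make_pipeline(StandardScaler(), LogisticRegression(C=0.1, max_iter=2000))),
                ("glm_C1", make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=2000))),
                ("glm_C10", make_pipeline(StandardScaler(), LogisticRegression(C=10.0, max_iter=2000))),
            ],
            "gbm": [
                ("gbm_lr0.1", HistGradientBoostingClassifier(learning_rate=0.1, max_iter=150, random_state=rs)),
                ("gbm_lr0.05", HistGradientBoostingClassifier(learning_rate=0.05, max_iter=300, random_state=rs)),
            ],
            "drf": [
                ("drf_sqrt", RandomForestClassifier(n_estimators=150, max_features="sqrt", random_state=rs, n_jobs=1)),
                ("drf_half", RandomForestClassifier(n_estimators=150, max_features=0.5, random_state=rs, n_jobs=1)),
            ],
            "deeplearning": [
                ("dl_a1e-4", make_pipeline(StandardScaler(), MLPClassifier(hidden_layer_sizes=(32, 16), alpha=1e-4, max_iter=400, random_state=rs))),
                ("dl_a1e-2", make_pipeline(StandardScaler(), MLPClassifier(hidden_layer_sizes=(32, 16), alpha=1e-2, max_iter=400, random_state=rs))),
            ],
        }
    else:
        grids = {
            "glm": [
                ("glm_a0.1", make_pipeline(StandardScaler(), Ridge(alpha=0.1))),
                ("glm_a1", make_pipeline(StandardScaler(), Ridge(alpha=1.0))),
                ("glm_a10", make_pipeline(StandardScaler(), Ridge(alpha=10.0))),
            ],
            "gbm": [
                ("gbm_lr0.1", HistGradientBoostingRegressor(learning_rate=0.1, max_iter=150, random_state=rs)),
                ("gbm_lr0.05", HistGradientBoostingRegressor(learning_rate=0.05, max_iter=300, random_state=rs)),
            ],
            "drf": [
                ("drf_sqrt", RandomForestRegressor(n_estimators=150, max_features="sqrt", random_state=rs, n_jobs=1)),
                ("drf_half", RandomForestRegressor(n_estimators=150, max_features=0.5, random_state=rs, n_jobs=1)),
            ],
            "deeplearning": [
                ("dl_a1e-4", make_pipeline(StandardScaler(), MLPRegressor(hidden_layer_sizes=(32, 16), alpha=1e-4, max_iter=400, random_state=rs))),
                ("dl_a1e-2", make_pipeline(StandardScaler(), MLPRegressor(hidden_layer_sizes=(32, 16), alpha=1e-2, max_iter=400, random_state=rs))),
            ],
        }
    interleaved: list[tuple[str, str, object]] = []
    depth = 0
    while True:
        added = False
        for family, members in grids.items():
            if depth < len(members):
                model_id, est = members[depth]
                interleaved.append((family, model_id, est))
                added = True
        if not added:
            return interleaved
        depth += 1


N_FAMILIES = 4


def default_recipe(mode: str, seed: int = 0):
    """The workhorse single-model recipe (regularized linear model)."""
    rs = seed % (2**31)
    if mode == CLASSIFICATION:
        return make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=2000))
    return HistGradientBoostingRegressor(learning_rate=0.1, max_iter=200, random_state=rs)


def _predict_scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function") and is_classifier(model):
        return model.decision_function(X)
    return model.predict(X)


def _split_xy(table: pd.DataFrame, spec: TaskSpec):
    target = "label" if spec.mode == CLASSIFICATION else spec.target
    if table.columns[0] != target:
        raise ValueError(f"modeling table must have {target!r} as first column")
    y = table[target].to_numpy()
    X = table.drop(columns=[target])
    return X, y


def _rmse(y_true, y_pred) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def model_search(table: pd.DataFrame, spec: TaskSpec):
    """Cross-validated model search over the fixed zoo plus stacked
    ensembles; returns (Leaderboard, best model refit on all rows).

    Every candidate is scored on the same fold partition via its
    out-of-fold predictions (AUC for classification, RMSE for
    regression).  Two stacked ensembles — meta-learner over all
    candidates and over the best of each family — are scored by
    fold-wise refits of the meta-learner on the out-of-fold prediction
    matrix, then the winner is refit on the full table.
    """
    if spec.trial_budget < N_FAMILIES:
        raise ValueError(
            f"trial_budget must cover all {N_FAMILIES} families, got {spec.trial_budget}"
        )
    X, y = _split_xy(table, spec)
    rs = spec.seed % (2**31)
    classification = spec.mode == CLASSIFICATION
    if classification:
        folds = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=rs)
        method = "predict_proba"
    else:
        folds = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=rs)
        method = "predict"
    fold_plan = list(folds.split(X, y))

    candidates = _family_grid(spec.mode, spec.seed)[: spec.trial_budget]
    rows, oof, fitted_family_best = [], {}, {}
    for family, model_id, est in candidates:
        pred = cross_val_predict(clone(est), X, y, cv=fold_plan, method=method, n_jobs=1)
        if classification:
            pred = pred[:, 1]
            metric = auc_roc(pred, y).auc
        else:
            metric = _rmse(y, pred)
        oof[model_id] = pred
        rows.append({"model_id": model_id, "family": family, "metric": metric})
        logger.debug("scored %s (%s): %.5f", model_id, family, metric)

    def better(a, b):  # is metric a better than b?
        return a > b if classification else a < b

    best_of_family: dict[str, str] = {}
    for row in rows:
        cur = best_of_family.get(row["family"])
        if cur is None or better(row["metric"], next(r["metric"] for r in rows if r["model_id"] == cur)):
            best_of_family[row["family"]] = row["model_id"]

    def meta_estimator():
        if classification:
            return LogisticRegression(max_iter=2000)
        return Ridge(alpha=1.0)

    def ensemble_cv_metric(member_ids: list[str]) -> float:
        P = np.column_stack([oof[m] for m in member_ids])
        pred = np.empty(len(y), dtype=float)
        for train_idx, test_idx in fold_plan:
            meta = meta_estimator()
            meta.fit(P[train_idx], y[train_idx])
            pred[test_idx] = _predict_scores(meta, P[test_idx])
        return auc_roc(pred, y).auc if classification else _rmse(y, pred)

    est_by_id = {model_id: est for _, model_id, est in candidates}
    ensembles = {
        "StackedEnsemble_AllModels": [model_id for _, model_id, _ in candidates],
        "StackedEnsemble_BestOfFamily": list(best_of_family.values()),
    }
    for ens_id, members in ensembles.items():
        rows.append(
            {"model_id": ens_id, "family": "ensemble", "metric": ensemble_cv_metric(members)}
        )

    board = pd.DataFrame(rows).sort_values(
        "metric", ascending=not classification, kind="stable"
    )
    board.insert(0, "rank", range(1, len(board) + 1))
    board = board.reset_index(drop=True)
    metric_name = "auc" if classification else "rmse"
    leaderboard = Leaderboard(table=board, metric=metric_name)

    best_id = board.iloc[0]["model_id"]
    if best_id in ensembles:
        members = [(m, clone(est_by_id[m])) for m in ensembles[best_id]]
        stack_cls = StackingClassifier if classification else StackingRegressor
        kwargs = {"stack_method": "predict_proba"} if classification else {}
        best = stack_cls(
            estimators=members, final_estimator=meta_estimator(), cv=fold_plan, n_jobs=1, **kwargs
        )
    else:
        best = clone(est_by_id[best_id])
    best.fit(X, y)
    return leaderboard, best


# ---------------------------------------------------------------------------
# Repeated holdout


def repeated_holdout(table: pd.DataFrame, recipe, spec: TaskSpec) -> RepeatedAuc:
    """Repeated random train/test splits; fit ``recipe`` each time and
    score AUC on the held-out fraction.

    A split whose test set contains a single class is redrawn (logged),
    at most 10 times per repeat.  Two invocations with the same spec
    produce identical per-repeat AUCs.
    """
    if spec.n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 to report a standard deviation")
    X, y = _split_xy(table, spec)
    n = len(y)
    n_train, _ = split_counts(n, spec.train_fraction)
    aucs = []
    for r in range(spec.n_repeats):
        for attempt in range(10):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(r, attempt))
            )
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            if len(np.unique(y[test_idx])) == 2:
                break
            logger.info("repeat %d: single-class test set, redrawing", r)
        else:
            raise RuntimeError(f"repeat {r}: no valid split after 10 redraws")
        model = clone(recipe)
        model.fit(X.iloc[train_idx], y[train_idx])
        scores = _predict_scores(model, X.iloc[test_idx])
        aucs.append(auc_roc(scores, y[test_idx]).auc)
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1))
    return RepeatedAuc(aucs=aucs, mean=mean, sd=sd, n_repeats=spec.n_repeats)


# ---------------------------------------------------------------------------
# Grouped-mean curve


def grouped_mean_curve(predicted, actual, n_groups: int = 50) -> GroupedCurve:
    """Rank samples by prediction, cut into near-equal contiguous groups
    (larger groups first) and report per-group mean predicted/actual."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    n = len(predicted)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n < n_groups:
        raise ValueError(f"need at least n_groups={n_groups} samples, got {n}")
    order = np.argsort(predicted, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + 1] * rem + [base] * (n_groups - rem)
    rows, start = [], 0
    for g, size in enumerate(sizes, start=1):
        idx = order[start : start + size]
        rows.append(
            {
                "group": g,
                "size": size,
                "mean_predicted": float(predicted[idx].mean()),
                "mean_actual": float(actual[idx].mean()),
            }
        )
        start += size
    return GroupedCurve(table=pd.DataFrame(rows), n_groups=n_groups)


# ---------------------------------------------------------------------------
# Permutation importance


def _performance(metric: str, y_true, scores) -> float:
    """Higher-is-better performance under the named metric."""
    if metric == "auc":
        return auc_roc(scores, y_true).auc
    if metric == "rmse":
        return -_rmse(y_true, scores)
    raise ValueError(f"unknown metric {metric!r}")


def permutation_importance(
    model, X: pd.DataFrame, y, metric: str = "auc", n_repeats: int = 5, seed: int = 0
) -> ImportanceReport:
    """Mean drop in performance when one feature column is shuffled.

    The base score is computed once; each feature is permuted
    ``n_repeats`` times and the mean and sd of (base - permuted)
    performance are reported.  For RMSE the drop is the *increase* in
    error, so importances are positive for useful features under every
    metric.
    """
    if hasattr(model, "feature_names_in_"):
        missing = set(model.feature_names_in_) - set(X.columns)
        if missing:
            raise ValueError(f"features absent from table: {sorted(missing)}")
        X = X.loc[:, list(model.feature_names_in_)]
    y = np.asarray(y)
    base = _performance(metric, y, _predict_scores(model, X))
    rng = np.random.default_rng(seed)
    rows = []
    work = X.copy()
    for feature in X.columns:
        saved = work[feature].to_numpy().copy()
        drops = []
        for _ in range(n_repeats):
            work[feature] = rng.permutation(saved)
            drops.append(base - _performance(metric, y, _predict_scores(model, work)))
        work[feature] = saved
        rows.append(
            {
                "feature": feature,
                "importance_mean": float(np.mean(drops)),
                "importance_sd": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    return ImportanceReport(
        table=pd.DataFrame(rows), base_score=base, metric=metric, n_repeats=n_repeats
    )
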