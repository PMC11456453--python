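"""Classification protocol: repeated stratified splits, RFE, tuned models.

The protocol distinguishes early-AD from normal-control participants with
three predictor sets (linguistic features, biomarkers, or both — age and
education always ride along as ordinary predictors) and three models (RBF
support-vector machine, k-nearest neighbors, random forest):

1. the cohort is split 70/30 with stratified sampling, repeated 10 times;
2. on each training set, recursive feature elimination (RFE) with repeated
   stratified cross-validation picks the subset size with the best mean
   accuracy (ties go to the smaller size); feature ranks are recomputed from
   model-specific importance at every elimination step;
3. the model is tuned by grid search (10 values per hyperparameter) with
   repeated cross-validation scored by ROC AUC, then refit on the full
   training set;
4. test-set AUC, specificity, precision, recall and F1 are recorded, and
   per-feature importance (scaled to a maximum of 100) is aggregated over
   the repeats in which RFE selected the feature.

Importance is model specific: Gini-impurity decrease for the random forest,
leave-one-predictor-out AUC change for the SVM, and permutation importance
(mean accuracy drop over random column permutations) for KNN.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "PREDICTOR_SET_NAMES",
    "ClassificationProtocol",
    "ClassificationReport",
    "build_predictor_sets",
    "make_splits",
    "rfe_select",
    "tune_and_train",
    "evaluate",
    "importance",
    "run_classification",
    "aggregate_report",
    "auc_score",
]

MODEL_NAMES = ("svm", "knn", "rf")
PREDICTOR_SET_NAMES = ("linguistic", "biomarkers", "combined")
COVARIATES = ("age", "education")
POSITIVE_CLASS = "early_AD"


@dataclass
class ClassificationProtocol:
    """Protocol knobs; defaults follow the study design.

    The cross-validation fold/repeat counts and grid resolution are exposed
    so that simulation studies can run a lighter but structurally identical
    protocol.
    """

    n_repeats: int = 10
    train_fraction: float = 0.7
    rfe_cv_folds: int = 10
    rfe_cv_repeats: int = 5
    tune_cv_folds: int = 5
    tune_cv_repeats: int = 10
    grid_points: int = 10
    rf_n_estimators: int = 300
    n_permutations: int = 10
    score_threshold: float = 0.5


def build_predictor_sets(feature_names=FEATURE_NAMES) -> dict:
    """The three canonical predictor sets, covariates included in each."""
    linguistic = [*feature_names, *COVARIATES]
    biomarkers = ["suvr", "hippocampus_cm3", *COVARIATES]
    return {
        "linguistic": linguistic,
        "biomarkers": biomarkers,
        "combined": [*feature_names, "suvr", "hippocampus_cm3", *COVARIATES],
    }


def make_splits(y, n_repeats: int = 10, train_fraction: float = 0.7, seed: int = 0):
    """Repeated stratified 70/30 train/test index splits.

    Within-split class proportions match the cohort's up to the stratified
    allocator's rounding (train size is ``round(n * train_fraction)`` overall,
    apportioned per class).  Reproducible from ``seed``.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("outcome must have two classes")
    if counts.min() < 4:
        raise ValueError(f"smallest class has {counts.min()} members; need >= 4")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_fraction, random_state=seed
    )
    return [(train, test) for train, test in splitter.split(np.zeros(len(y)), y)]


# ---------------------------------------------------------------------------
# estimators


def _median_sigma(X: np.ndarray) -> float:
    """Median-heuristic RBF width on (at most 400) standardized rows."""
    if len(X) > 400:
        X = X[:: len(X) // 400 + 1]
    d = pdist(X)
    d = d[d > 0]
    return float(np.median(d)) if len(d) else 1.0


def _build_estimator(name: str, p: int, seed: int, protocol: ClassificationProtocol,
                     params: dict | None = None, n_train: int = 0):
    if name == "svm":
        est = SVC(kernel="rbf", C=1.0)
    elif name == "knn":
        est = KNeighborsClassifier(n_neighbors=5)
    elif name == "rf":
        # leaf size grows with the training set (~1%) so class-probability
        # estimates stay smooth enough to rank test cases reliably; small
        # cohorts keep fully grown trees
        est = RandomForestClassifier(
            n_estimators=protocol.rf_n_estimators,
            min_samples_leaf=max(1, n_train // 100),
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown model {name!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
    if params:
        pipe.set_params(**params)
    return pipe


def _grid(name: str, X: pd.DataFrame, protocol: ClassificationProtocol, n_train: int) -> dict:
    """Hyperparameter grids: 10 values per tunable parameter.

    SVM cost is log-spaced over [0.25, 128] and the kernel width spans
    [0.1x, 10x] a median-heuristic estimate; KNN uses odd neighbor counts
    5..23; the forest's candidate-variables-per-split covers 1..p.
    """
    g = protocol.grid_points
    if name == "svm":
        Xs = StandardScaler().fit_transform(X)
        sigma = _median_sigma(Xs) * np.logspace(-1, 1, g)
        return {
            "model__C": np.logspace(np.log10(0.25), np.log10(128.0), g),
            "model__gamma": 1.0 / (2.0 * sigma**2),
        }
    if name == "knn":
        ks = np.arange(5, 5 + 2 * g, 2)
        ks = ks[ks <= max(5, int(np.floor((n_train * 0.8))))]
        return {"model__n_neighbors": ks}
    if name == "rf":
        p = X.shape[1]
        mtry = np.unique(np.round(np.linspace(1, p, min(g, p))).astype(int))
        return {"model__max_features": [int(m) for m in mtry]}
    raise ValueError(name)


@dataclass
class FittedModel:
    """A tuned pipeline plus everything needed to score new data."""

    pipeline: Pipeline
    model_name: str
    selected: list
    best_params: dict
    platt: LogisticRegression | None = None

    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous score for the early-AD (positive) class."""
        X = X[self.selected]
        if self.model_name == "svm":
            d = self.pipeline.decision_function(X)
            if self.platt is not None:
                return self.platt.predict_proba(d.reshape(-1, 1))[:, 1]
            return d
        return self.pipeline.predict_proba(X)[:, 1]


def tune_and_train(X_train: pd.DataFrame, y_train, selected, model_name: str,
                   protocol: ClassificationProtocol | None = None,
                   seed: int = 0) -> FittedModel:
    """Grid-search tuning by cross-validated AUC, then refit on full train.

    Predictors are standardized and centered inside the pipeline, with the
    scaler statistics estimated on the training folds only.  SVM decision
    values are mapped to probabilities through a logistic (Platt) fit on the
    training data so that the 0.5 threshold metrics are defined.
    """
    protocol = protocol or ClassificationProtocol()
    selected = list(selected)
    if not selected:
        raise ValueError("selected feature set is empty")
    X = X_train[selected]
    y = np.asarray(y_train).astype(int)
    pipe = _build_estimator(model_name, len(selected), seed, protocol, n_train=len(X))
    grid = _grid(model_name, X, protocol, n_train=len(X))
    cv = RepeatedStratifiedKFold(
        n_splits=protocol.tune_cv_folds,
        n_repeats=protocol.tune_cv_repeats,
        random_state=seed,
    )
    search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, n_jobs=None, refit=True)
    search.fit(X, y)
    fitted = FittedModel(
        pipeline=search.best_estimator_,
        model_name=model_name,
        selected=selected,
        best_params=search.best_params_,
    )
    if model_name == "svm":
        d = fitted.pipeline.decision_function(X).reshape(-1, 1)
        if len(np.unique(y)) == 2 and np.ptp(d) > 0:
            fitted.platt = LogisticRegression(C=1e6).fit(d, y)
    return fitted


# ---------------------------------------------------------------------------
# metrics


def auc_score(y_true, scores) -> float:
    """Rank-statistic AUC: concordant score pairs, ties counted one half."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(model: FittedModel, X_test: pd.DataFrame, y_test,
             threshold: float = 0.5) -> dict:
    """Test-set AUC plus 0.5-threshold specificity/precision/recall/F1."""
    y = np.asarray(y_test).astype(int)
    scores = model.predict_score(X_test)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    specificity = tn / (tn + fp) if tn + fp else np.nan
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = np.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "AUC": auc_score(y, scores),
        "specificity": specificity,
        "precision": precision,
        "recall": recall,
        "F1": f1,
    }


# ---------------------------------------------------------------------------
# importance


def _raw_importance(pipeline: Pipeline, model_name: str, X: pd.DataFrame, y,
                    protocol: ClassificationProtocol, seed: int) -> np.ndarray:
    """Unscaled per-feature importance on the training data."""
    y = np.asarray(y).astype(int)
    if model_name == "rf":
        return pipeline.named_steps["model"].feature_importances_.copy()
    if model_name == "svm":
        # AUC change when each predictor is removed and the model refit at
        # the same hyperparameters
        full_auc = auc_score(y, pipeline.decision_function(X))
        params = pipeline.get_params()
        imp = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            cols = [c for i, c in enumerate(X.columns) if i != j]
            if not cols:
                imp[j] = full_auc - 0.5
                continue
            sub = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("model", SVC(kernel="rbf", C=params["model__C"], gamma=params["model__gamma"])),
                ]
            ).fit(X[cols], y)
            imp[j] = full_auc - auc_score(y, sub.decision_function(X[cols]))
        return imp
    if model_name == "knn":
        if protocol.n_permutations < 1:
            raise ValueError("permutation importance needs at least 1 permutation")
        res = permutation_importance(
            pipeline, X, y, scoring="accuracy",
            n_repeats=protocol.n_permutations, random_state=seed,
        )
        return res.importances_mean.copy()
    raise ValueError(model_name)


def importance(model: FittedModel, X_train: pd.DataFrame, y_train,
               protocol: ClassificationProtocol | None = None,
               seed: int = 0) -> pd.Series:
    """Model-specific importance, clipped at zero and scaled to max 100."""
    protocol = protocol or ClassificationProtocol()
    X = X_train[model.selected]
    raw = _raw_importance(model.pipeline, model.model_name, X, y_train, protocol, seed)
    raw = np.clip(raw, 0.0, None)
    top = raw.max()
    scaled = raw * 100.0 / top if top > 0 else np.full_like(raw, 100.0)
    return pd.Series(scaled, index=model.selected)


# ---------------------------------------------------------------------------
# RFE


def _accuracy(pipeline: Pipeline, X, y) -> float:
    return float((pipeline.predict(X) == y).mean())


def _elimination_path(X: pd.DataFrame, y, model_name: str,
                      protocol: ClassificationProtocol, seed: int,
                      X_eval=None, y_eval=None):
    """Eliminate features one at a time, re-ranking by importance each step.

    Returns the elimination order (first eliminated first) and, when an
    evaluation set is given, the held-out accuracy at each subset size.
    """
    cols = list(X.columns)
    order: list = []
    acc_by_size: dict = {}
    while cols:
        pipe = _build_estimator(
            model_name, len(cols), seed, protocol, n_train=len(X)
        ).fit(X[cols], y)
        if X_eval is not None:
            acc_by_size[len(cols)] = _accuracy(pipe, X_eval[cols], y_eval)
        if len(cols) == 1:
            order.append(cols[0])
            break
        imp = _raw_importance(pipe, model_name, X[cols], y, protocol, seed)
        # least important goes first; ties drop the later-listed column
        worst = int(np.flatnonzero(imp == imp.min())[-1])
        order.append(cols.pop(worst))
    return order, acc_by_size


def rfe_select(X_train: pd.DataFrame, y_train, model_name: str,
               protocol: ClassificationProtocol | None = None,
               seed: int = 0) -> list:
    """Recursive feature elimination sized by repeated cross-validation.

    For each candidate size ``s = 1..p`` the mean cross-validated accuracy of
    the model on the top-``s`` features (re-ranked at each elimination step
    within every training fold) is estimated; the size with the best mean
    accuracy wins, ties broken toward the smaller size.  The returned set is
    the top-``s`` features from a final elimination pass on the full training
    data.
    """
    protocol = protocol or ClassificationProtocol()
    y = np.asarray(y_train).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    p = X_train.shape[1]
    if p == 1:
        return list(X_train.columns)
    cv = RepeatedStratifiedKFold(
        n_splits=protocol.rfe_cv_folds,
        n_repeats=protocol.rfe_cv_repeats,
        random_state=seed,
    )
    acc = np.zeros(p + 1)
    n_folds = 0
    for train_idx, test_idx in cv.split(X_train, y):
        _, acc_by_size = _elimination_path(
            X_train.iloc[train_idx], y[train_idx], model_name, protocol, seed,
            X_eval=X_train.iloc[test_idx], y_eval=y[test_idx],
        )
        for s, a in acc_by_size.items():
            acc[s] += a
        n_folds += 1
    mean_acc = acc[1:] / n_folds  # index s-1 = size s
    best_size = int(np.argmax(mean_acc)) + 1  # argmax returns the first (smallest) max
    order, _ = _elimination_path(X_train, y, model_name, protocol, seed)
    selected = order[p - best_size :]  # survivors of the final pass
    return [c for c in X_train.columns if c in set(selected)]


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ClassificationReport:
    """Aggregated metrics, importance and selection frequencies."""

    metrics: pd.DataFrame
    importance: pd.DataFrame
    top_features: dict
    per_repeat: pd.DataFrame = field(repr=False, default=None)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.importance.to_csv(out / "importance.csv", index=False)
        if self.per_repeat is not None:
            self.per_repeat.to_csv(out / "per_repeat.csv", index=False)


def run_classification(cohort: pd.DataFrame, predictor_sets: dict | None = None,
                       models=MODEL_NAMES,
                       protocol: ClassificationProtocol | None = None,
                       seed: int = 0) -> ClassificationReport:
    """Run the full protocol and aggregate the report.

    ``cohort`` must contain ``group`` plus every predictor column.  Rows with
    missing values are excluded from the predictor sets that need them only.
    """
    protocol = protocol or ClassificationProtocol()
    if predictor_sets is None:
        predictor_sets = build_predictor_sets()
    ss = np.random.SeedSequence(seed)
    records = []
    for set_name, columns in predictor_sets.items():
        sub = cohort.dropna(subset=list(columns)).reset_index(drop=True)
        y = (sub["group"] == POSITIVE_CLASS).to_numpy().astype(int)
        X = sub[list(columns)].astype(float)
        split_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        splits = make_splits(
            y, n_repeats=protocol.n_repeats,
            train_fraction=protocol.train_fraction, seed=split_seed,
        )
        for model_name in models:
            for r, (train_idx, test_idx) in enumerate(splits):
                rep_seed = int(
                    np.random.SeedSequence(
                        [seed, zlib.crc32(set_name.encode()) % 2**16,
                         MODEL_NAMES.index(model_name), r]
                    ).generate_state(1)[0] % (2**31)
                )
                X_tr, y_tr = X.iloc[train_idx], y[train_idx]
                X_te, y_te = X.iloc[test_idx], y[test_idx]
                selected = rfe_select(X_tr, y_tr, model_name, protocol, seed=rep_seed)
                fitted = tune_and_train(X_tr, y_tr, selected, model_name, protocol, seed=rep_seed)
                metrics = evaluate(fitted, X_te, y_te, threshold=protocol.score_threshold)
                imp = importance(fitted, X_tr, y_tr, protocol, seed=rep_seed)
                records.append(
                    {
                        "predictor_set": set_name,
                        "model": model_name,
                        "repeat": r,
                        "selected": list(selected),
                        "importance": imp.to_dict(),
                        **metrics,
                    }
                )
    return aggregate_report(records, n_repeats=protocol.n_repeats)


def aggregate_report(records, n_repeats: int | None = None) -> ClassificationReport:
    """Aggregate per-repeat results into the final report.

    Mean importance for a feature is computed over the repeats in which RFE
    selected it; selection frequency is the share of repeats that selected
    it; metrics are plain means over repeats.  The top-5 list per model and
    predictor set is ordered by mean importance.
    """
    records = list(records)
    if not records:
        raise ValueError("no completed runs to aggregate")
    per_repeat = pd.DataFrame(
        [{k: v for k, v in r.items() if k not in ("selected", "importance")} for r in records]
    )
    metric_cols = ["AUC", "specificity", "precision", "recall", "F1"]
    metrics = (
        per_repeat.groupby(["predictor_set", "model"], sort=False)[metric_cols]
        .mean()
        .reset_index()
    )
    imp_rows = []
    top: dict = {}
    for (set_name, model_name), group in pd.DataFrame(records).groupby(
        ["predictor_set", "model"], sort=False
    ):
        total = n_repeats or len(group)
        tally: dict = {}
        for _, row in group.iterrows():
            for feat in row["selected"]:
                tally.setdefault(feat, []).append(row["importance"].get(feat, np.nan))
        stats = []
        for feat, vals in tally.items():
            stats.append(
                {
                    "predictor_set": set_name,
                    "model": model_name,
                    "feature": feat,
                    "mean_importance": float(np.nanmean(vals)),
                    "selection_pct": 100.0 * len(vals) / total,
                }
            )
        stats.sort(key=lambda d: -d["mean_importance"])
        imp_rows.extend(stats)
        top[(set_name, model_name)] = [d["feature"] for d in stats[:5]]
    return ClassificationReport(
        metrics=metrics,
        importance=pd.DataFrame(imp_rows),
        top_features=top,
        per_repeat=per_repeat,
    )
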