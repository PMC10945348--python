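"""Seven-algorithm x five-signature model grid with repeated CV tuning.

Each grid cell tunes one classifier family on the expression of one
signature's genes (standardized with training statistics only) by
mean AUC over repeated stratified k-fold CV, refits the best point on
the full training set, and is scored by AUC on the held-out test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from immunosig.errors import ValidationError
from immunosig.io_formats import BulkCohort, GeneSignature

POSITIVE_CLASS = "NPD"  # scores are P(NPD)

ALGORITHM_ORDER = (
    "SVM",
    "NaiveBayes",
    "RandomForest",
    "KNN",
    "AdaBoost",
    "LogitBoost",
    "NearestCentroid",
)

AUC_GRADES = (
    (0.9, "excellent"),
    (0.8, "very good"),
    (0.7, "good"),
    (0.6, "sufficient"),
    (0.5, "bad"),
)


@dataclass
class ModelRecord:
    algorithm: str
    gene_set: str
    hyperparameters: dict
    cv_mean: float  # mean CV AUC at the selected point (NaN when untuned)
    cv_sd: float
    test_auc: float = float("nan")
    seed: int = 0
    model: object = field(default=None, repr=False)
    feature_genes: list[str] = field(default_factory=list, repr=False)


@dataclass
class GridReport:
    records: list[ModelRecord]
    selected: ModelRecord

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "algorithm": r.algorithm,
                    "gene_set": r.gene_set,
                    "cv_mean": r.cv_mean,
                    "cv_sd": r.cv_sd,
                    "test_auc": r.test_auc,
                    "hyperparameters": repr(r.hyperparameters),
                    "selected": r is self.selected,
                }
                for r in self.records
            ]
        )


class MarginCalibratedSVC(BaseEstimator, ClassifierMixin):
    """Kernel SVM with margin outputs mapped to [0, 1] by a logistic link.

    The link is a one-dimensional logistic regression fit on the
    training decision values; cheaper and more transparent than the
    built-in Platt cross-validation.
    """

    def __init__(self, C: float = 1.0, gamma="scale"):
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        self.svc_ = SVC(C=self.C, gamma=self.gamma)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        d = self.svc_.decision_function(X)
        self._link = LogisticRegression(C=1e6, max_iter=1000)
        self._link.fit(d.reshape(-1, 1), y)
        return self

    def predict_proba(self, X):
        d = self.svc_.decision_function(np.asarray(X, dtype=float))
        return self._link.predict_proba(d.reshape(-1, 1))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]


class NearestCentroidResponseClassifier(BaseEstimator, ClassifierMixin):
    """Correlation-to-centroid two-class classifier (cancerclass style).

    Features are standardized with training statistics; each class gets
    a centroid; a sample's raw score is the difference between its
    Pearson correlation to the positive-class centroid and to the
    negative-class centroid, mapped to [0, 1] by a logistic link fit
    on the training scores. No hyperparameters.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValidationError("nearest-centroid classifier needs two classes")
        self.centroids_ = {c: X[y == c].mean(axis=0) for c in self.classes_}
        d = self._raw_scores(X)
        self._link = LogisticRegression(C=1e6, max_iter=1000)
        self._link.fit(d.reshape(-1, 1), y)
        return self

    def _raw_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        pos = POSITIVE_CLASS if POSITIVE_CLASS in self.classes_ else self.classes_[1]
        neg = next(c for c in self.classes_ if c != pos)
        return np.array(
            [
                _safe_corr(row, self.centroids_[pos]) - _safe_corr(row, self.centroids_[neg])
                for row in X
            ]
        )

    def predict_proba(self, X):
        d = self._raw_scores(X).reshape(-1, 1)
        return self._link.predict_proba(d)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def algorithm_spec(name: str, seed: int) -> tuple[BaseEstimator, dict]:
    """Estimator prototype and hyperparameter grid for one family."""
    if name == "SVM":
        return MarginCalibratedSVC(), {
            "C": [0.1, 1.0, 10.0],
            "gamma": ["scale", 0.01],
        }
    if name == "NaiveBayes":
        return GaussianNB(), {"var_smoothing": [1e-9]}
    if name == "RandomForest":
        return RandomForestClassifier(random_state=seed), {
            "n_estimators": [100, 500],
            "max_depth": [None, 5],
        }
    if name == "KNN":
        return KNeighborsClassifier(), {"n_neighbors": [3, 5, 7, 9]}
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed), {
            "n_estimators": [50, 100, 200]
        }
    if name == "LogitBoost":
        # additive logistic regression: log-loss boosting of depth-1 stumps
        return GradientBoostingClassifier(max_depth=1, random_state=seed), {
            "n_estimators": [50, 100, 200]
        }
    if name == "NearestCentroid":
        return NearestCentroidResponseClassifier(), {}
    raise ValidationError(f"unknown algorithm {name!r}")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_cohort(
    cohort: BulkCohort, train_frac: float = 0.8, seed: int = 0
) -> tuple[BulkCohort, BulkCohort]:
    """Stratified random split; train size = floor(train_frac * n).

    Per-class allocations are proportional (largest-remainder rule)
    and adjusted so both partitions contain both classes.
    """
    n = len(cohort.samples)
    if n < 10:
        raise ValidationError("cohort too small to split (need >= 10 samples)")
    labels = cohort.response
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("both response classes must be present")

    n_train = int(np.floor(train_frac * n))
    rng = np.random.default_rng(seed)
    per_class = {c: [s for s in cohort.samples if labels[s] == c] for c in classes}
    for members in per_class.values():
        rng.shuffle(members)

    quotas = {c: train_frac * len(per_class[c]) for c in classes}
    alloc = {c: int(np.floor(quotas[c])) for c in classes}
    remainder_order = sorted(classes, key=lambda c: quotas[c] - alloc[c], reverse=True)
    i = 0
    while sum(alloc.values()) < n_train:
        alloc[remainder_order[i % len(classes)]] += 1
        i += 1
    while sum(alloc.values()) > n_train:
        alloc[remainder_order[-(1 + i % len(classes))]] -= 1
        i += 1
    for c in classes:  # both partitions must contain both classes
        alloc[c] = min(max(alloc[c], 1), len(per_class[c]) - 1)
        if not 1 <= alloc[c] <= len(per_class[c]) - 1:
            raise ValidationError(f"class {c!r} cannot appear in both partitions")

    train_ids = [s for c in classes for s in per_class[c][: alloc[c]]]
    test_ids = [s for c in classes for s in per_class[c][alloc[c] :]]
    order = {s: k for k, s in enumerate(cohort.samples)}
    train_ids.sort(key=order.get)
    test_ids.sort(key=order.get)
    return cohort.subset_samples(train_ids), cohort.subset_samples(test_ids)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def evaluate_auc(scores, labels) -> float:
    """AUC via the rank (Mann-Whitney) formulation with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE_CLASS
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_grade(auc: float) -> str:
    """Map an AUC to its qualitative band."""
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC {auc} out of [0, 1]")
    for lo, grade in AUC_GRADES:
        if auc >= lo:
            return grade
    return "not useful"


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _feature_frame(cohort: BulkCohort, genes: list[str]) -> pd.DataFrame:
    present = [g for g in genes if g in set(cohort.genes)]
    if not present:
        raise ValidationError("no signature genes present in cohort")
    return cohort.expression[present]


def _cv_auc(
    pipeline: Pipeline,
    X: np.ndarray,
    y: np.ndarray,
    repeats: int,
    folds: int,
    seed: int,
) -> tuple[float, float]:
    """Mean/SD of AUC over repeated stratified k-fold CV."""
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    aucs = []
    for train_idx, val_idx in cv.split(X, y):
        if len(np.unique(y[val_idx])) < 2:
            continue
        est = clone(pipeline)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[val_idx])
        pos_col = list(est.classes_).index(POSITIVE_CLASS)
        aucs.append(evaluate_auc(proba[:, pos_col], y[val_idx]))
    if not aucs:
        raise ValidationError("no valid CV folds")
    return float(np.mean(aucs)), float(np.std(aucs))


def tune_and_train(
    train: BulkCohort,
    gene_set: GeneSignature,
    algorithm: str,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> ModelRecord:
    """Grid-tune one family by repeated-CV AUC and refit on all of train.

    The nearest-centroid family has no grid and is fit directly on the
    whole training set.
    """
    X_frame = _feature_frame(train, list(gene_set.genes))
    X = X_frame.to_numpy(dtype=float)
    y = train.response.to_numpy()
    proto, grid = algorithm_spec(algorithm, seed)

    if not grid:  # untuned family: direct fit
        pipeline = Pipeline([("scale", StandardScaler()), ("clf", clone(proto))])
        pipeline.fit(X, y)
        return ModelRecord(
            algorithm=algorithm,
            gene_set=gene_set.name,
            hyperparameters={},
            cv_mean=float("nan"),
            cv_sd=float("nan"),
            seed=seed,
            model=pipeline,
            feature_genes=list(X_frame.columns),
        )

    best = None
    for params in ParameterGrid(grid):
        clf = clone(proto).set_params(**params)
        pipeline = Pipeline([("scale", StandardScaler()), ("clf", clf)])
        mean_auc, sd_auc = _cv_auc(pipeline, X, y, repeats, folds, seed)
        if best is None or mean_auc > best[0]:
            best = (mean_auc, sd_auc, params)

    mean_auc, sd_auc, params = best
    final = Pipeline(
        [("scale", StandardScaler()), ("clf", clone(proto).set_params(**params))]
    )
    final.fit(X, y)
    return ModelRecord(
        algorithm=algorithm,
        gene_set=gene_set.name,
        hyperparameters=dict(params),
        cv_mean=mean_auc,
        cv_sd=sd_auc,
        seed=seed,
        model=final,
        feature_genes=list(X_frame.columns),
    )


def predict_response_score(
    record: ModelRecord, cohort: BulkCohort
) -> pd.DataFrame:
    """Per-sample P(NPD) and hard PD/NPD label at threshold 0.5.

    Signature genes absent from the cohort are imputed at 0 (the
    training mean on the standardized scale) with a warning.
    """
    if record.model is None:
        raise ValidationError("record has no trained model")
    expr = cohort.expression
    missing = [g for g in record.feature_genes if g not in set(cohort.genes)]
    if missing:
        warnings.warn(f"imputing {len(missing)} missing signature genes")
        scaler: StandardScaler = record.model.named_steps["scale"]
        expr = expr.copy()
        for g in missing:
            pos = record.feature_genes.index(g)
            expr[g] = scaler.mean_[pos]
    X = expr[record.feature_genes].to_numpy(dtype=float)
    proba = record.model.predict_proba(X)
    pos_col = list(record.model.classes_).index(POSITIVE_CLASS)
    score = proba[:, pos_col]
    return pd.DataFrame(
        {
            "sample_id": cohort.samples,
            "score": score,
            "label": np.where(score >= 0.5, "NPD", "PD"),
        },
        index=cohort.samples,
    )


def run_grid(
    train: BulkCohort,
    test: BulkCohort,
    signatures: list[GeneSignature],
    algorithms: tuple[str, ...] = ALGORITHM_ORDER,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> GridReport:
    """Train every (algorithm, signature) cell and select by test AUC.

    Ties are broken by higher CV mean, then by declared algorithm
    order.
    """
    if not signatures:
        raise ValidationError("no signatures supplied")
    records = []
    y_test = test.response.to_numpy()
    for sig, algo in product(signatures, algorithms):
        try:
            record = tune_and_train(
                train, sig, algo, repeats=repeats, folds=folds, seed=seed
            )
            preds = predict_response_score(record, test)
            record.test_auc = evaluate_auc(preds["score"].to_numpy(), y_test)
        except ValidationError as exc:
            raise ValidationError(f"grid cell ({algo}, {sig.name}): {exc}") from exc
        records.append(record)

    def sort_key(r: ModelRecord):
        cv = r.cv_mean if np.isfinite(r.cv_mean) else -np.inf
        return (-r.test_auc, -cv, ALGORITHM_ORDER.index(r.algorithm))

    selected = min(records, key=sort_key)
    return GridReport(records=records, selected=selected)
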