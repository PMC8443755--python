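"""Classifier zoo, feature selection, cross-validated tuning and metrics.

The classification protocol mirrors a small-data benchmarking workflow:
univariate ANOVA-F feature selection (at most 10 features to limit
overfitting), a zoo of scikit-learn classifiers, the number of features
chosen by stratified five-fold cross-validation accuracy with default
hyperparameters, then an exhaustive grid search (stratified CV5) for
hyperparameters, and final evaluation on a protein-balanced holdout.

Feature selection and standardization always live inside the
cross-validation pipeline, so they are re-fit on each training fold and
never see held-out rows.

Cross-validation metrics pool the out-of-fold predictions into a single
confusion matrix, which is what a printed integer CV confusion matrix
corresponds to.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.feature_selection import f_classif
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, NuSVC

from .dataset import round_half_away

__all__ = [
    "ModelSpec",
    "EvalReport",
    "ImportanceReport",
    "ALGORITHMS",
    "default_model_specs",
    "kbest_select",
    "choose_k",
    "grid_search_cv",
    "predict_krr_class",
    "evaluate",
    "f1_from_precision_recall",
    "dummy_stratified",
    "reconstruct_confusion",
    "logistic_importance",
    "build_pipeline",
    "tune_and_evaluate",
]


# ---------------------------------------------------------------------------
# estimator plumbing


class KRRClassifier(BaseEstimator, ClassifierMixin):
    """Kernel ridge regression used as a binary classifier.

    Labels are encoded -1/+1 for the regression fit; a predicted value
    strictly above 0 maps to the active class (ties inactive).
    """

    def __init__(self, alpha=1.0, kernel="linear", gamma=None):
        self.alpha = alpha
        self.kernel = kernel
        self.gamma = gamma

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("KRRClassifier requires exactly two classes")
        encoded = np.where(y == self.classes_[1], 1.0, -1.0)
        self.krr_ = KernelRidge(alpha=self.alpha, kernel=self.kernel, gamma=self.gamma)
        self.krr_.fit(X, encoded)
        return self

    def decision_function(self, X):
        return self.krr_.predict(X)

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def predict_krr_class(values) -> np.ndarray:
    """Map -1/+1-trained regression outputs to labels: active iff > 0."""
    return np.asarray(values, dtype=float) > 0


class MedianBinarizer(BaseEstimator, TransformerMixin):
    """Binarize each feature at its training-fold median (for Bernoulli NB)."""

    def fit(self, X, y=None):
        self.medians_ = np.median(np.asarray(X, dtype=float), axis=0)
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) > self.medians_).astype(float)


class KBestSelector(BaseEstimator, TransformerMixin):
    """Top-k columns by ANOVA F, ties broken toward earlier columns."""

    def __init__(self, k=10):
        self.k = k

    def fit(self, X, y):
        self.indices_ = kbest_select(np.asarray(X, dtype=float), np.asarray(y), self.k)
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.indices_]


@dataclass
class ModelSpec:
    """An algorithm with its hyperparameter grid and preprocessing flag."""

    algorithm: str
    grid: dict  # name -> list of candidate values, declared order
    standardize: bool = True

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")


def _make_estimator(algorithm: str, params: dict):
    factory = ALGORITHMS[algorithm]["factory"]
    return factory(**params)


#: algorithm registry: estimator factories and small default grids.
#: POL3 is a degree-3 polynomial-kernel support-vector classifier.
ALGORITHMS = {
    "LOG": {
        "factory": lambda **p: LogisticRegression(max_iter=5000, **p),
        "grid": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
        "standardize": True,
    },
    "KRR": {
        "factory": lambda **p: KRRClassifier(**p),
        "grid": {"alpha": [0.01, 0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
        "standardize": True,
    },
    "LDA": {
        "factory": lambda **p: LinearDiscriminantAnalysis(**p),
        "grid": {"solver": ["svd", "lsqr"]},
        "standardize": True,
    },
    "QDA": {
        "factory": lambda **p: QuadraticDiscriminantAnalysis(**p),
        "grid": {"reg_param": [0.0, 0.1, 0.5]},
        "standardize": True,
    },
    "SVC": {
        "factory": lambda **p: SVC(**p),
        "grid": {"C": [0.1, 1.0, 10.0, 100.0], "kernel": ["linear", "rbf"]},
        "standardize": True,
    },
    "NuSVC": {
        "factory": lambda **p: NuSVC(**p),
        "grid": {"nu": [0.25, 0.5, 0.75], "kernel": ["linear", "rbf"]},
        "standardize": True,
    },
    "POL3": {
        "factory": lambda **p: SVC(kernel="poly", degree=3, **p),
        "grid": {"C": [0.1, 1.0, 10.0, 100.0]},
        "standardize": True,
    },
    "KNN": {
        "factory": lambda **p: KNeighborsClassifier(**p),
        "grid": {"n_neighbors": [3, 5, 7], "weights": ["uniform", "distance"]},
        "standardize": True,
    },
    "BNB": {
        "factory": lambda **p: BernoulliNB(**p),
        "grid": {"alpha": [0.1, 0.5, 1.0]},
        "standardize": False,  # uses MedianBinarizer instead
    },
    "GNB": {
        "factory": lambda **p: GaussianNB(**p),
        "grid": {"var_smoothing": [1e-9, 1e-7]},
        "standardize": True,
    },
    "GPC": {
        "factory": lambda **p: GaussianProcessClassifier(random_state=0, **p),
        "grid": {"max_iter_predict": [100]},
        "standardize": True,
    },
}


def default_model_specs(algorithms=None) -> list:
    algorithms = algorithms or list(ALGORITHMS)
    return [
        ModelSpec(a, dict(ALGORITHMS[a]["grid"]), ALGORITHMS[a]["standardize"])
        for a in algorithms
    ]


def build_pipeline(spec: ModelSpec, k: int, params: dict | None = None) -> Pipeline:
    """Selection -> scaling -> model pipeline (all fit per training fold)."""
    steps = [("select", KBestSelector(k=k))]
    if spec.algorithm == "BNB":
        steps.append(("binarize", MedianBinarizer()))
    elif spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", _make_estimator(spec.algorithm, params or {})))
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# feature selection


def kbest_select(X, y, k: int) -> np.ndarray:
    """Indices of the top-``k`` features by one-way ANOVA F between classes.

    Ties (including duplicated columns) are broken toward the earlier
    column.  Constant features get F = 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not (1 <= k <= X.shape[1]):
        raise ValueError(f"k must be in [1, {X.shape[1]}], got {k}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    constant = np.ptp(X, axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stats, _ = f_classif(X, y)
    f_stats = np.nan_to_num(f_stats, nan=0.0, posinf=np.finfo(float).max)
    if constant.any():
        warnings.warn(
            f"constant feature(s) at columns {list(np.nonzero(constant)[0])}; F set to 0"
        )
        f_stats[constant] = 0.0
    order = np.argsort(-f_stats, kind="stable")
    return order[:k]


def choose_k(X, y, specs, k_range=range(1, 11), folds: int = 5, seed: int = 0) -> dict:
    """Per-algorithm best number of features by stratified CV accuracy.

    Each spec runs with its scikit-learn default hyperparameters; the k
    maximising mean CV accuracy wins, ties to the smaller k.  Fit
    failures are recorded as skips rather than raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = {}
    for spec in specs:
        best_k, best_acc, skips = None, -np.inf, []
        for k in k_range:
            if k > X.shape[1]:
                continue
            pipe = build_pipeline(spec, k)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    acc = float(np.mean(cross_val_score(pipe, X, y, cv=cv)))
            except Exception as exc:  # recorded skip, per contract
                skips.append((k, repr(exc)))
                continue
            if acc > best_acc:
                best_k, best_acc = k, acc
        out[spec.algorithm] = {"k": best_k, "cv_accuracy": best_acc, "skips": skips}
    return out


# ---------------------------------------------------------------------------
# grid search and evaluation


def _round3(x: float) -> float:
    return round_half_away(x, 3)


@dataclass
class EvalReport:
    """Confusion counts and the derived binary-classification metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self):
        n = self.tp + self.fp + self.fn + self.tn
        if n <= 0:
            raise ValueError("empty confusion matrix")
        self.accuracy = (self.tp + self.tn) / n
        self.precision = self._ratio(self.tp, self.tp + self.fp, "precision")
        self.recall = self._ratio(self.tp, self.tp + self.fn, "recall")
        if np.isnan(self.precision) or np.isnan(self.recall) or (
            self.precision + self.recall == 0
        ):
            warnings.warn("F1 undefined (zero precision and recall)")
            self.f1 = float("nan")
        else:
            self.f1 = f1_from_precision_recall(self.precision, self.recall)

    @staticmethod
    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self, decimals: int = 3) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": round_half_away(self.accuracy, decimals),
            "precision": round_half_away(self.precision, decimals)
            if not np.isnan(self.precision)
            else None,
            "recall": round_half_away(self.recall, decimals)
            if not np.isnan(self.recall)
            else None,
            "f1": round_half_away(self.f1, decimals) if not np.isnan(self.f1) else None,
        }


def evaluate(pred, truth) -> EvalReport:
    """Confusion counts and metrics for boolean predictions vs truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or len(pred) == 0:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn)


def f1_from_precision_recall(p: float, r: float) -> float:
    """Harmonic mean of precision and recall."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p + r == 0:
        raise ValueError("F1 undefined when precision and recall are both 0")
    return 2 * p * r / (p + r)


def grid_search_cv(
    spec: ModelSpec, X, y, k: int, folds: int = 5, seed: int = 0
) -> tuple:
    """Exhaustive stratified-CV grid search for one algorithm.

    Candidates are scored by mean per-fold CV accuracy; ties go to the
    earlier grid point in declared order.  The returned
    :class:`EvalReport` pools the out-of-fold predictions of the best
    candidate into one confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class with {counts.min()} members cannot be split into {folds} "
            "stratified folds; use fewer folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    names = list(spec.grid)
    best_params, best_acc = None, -np.inf
    for combo in itertools.product(*(spec.grid[n] for n in names)):
        params = dict(zip(names, combo))
        pipe = build_pipeline(spec, k, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc = float(np.mean(cross_val_score(pipe, X, y, cv=cv)))
        if acc > best_acc:
            best_params, best_acc = params, acc
    pipe = build_pipeline(spec, k, best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = cross_val_predict(pipe, X, y, cv=cv)
    return best_params, evaluate(pooled.astype(bool), y.astype(bool))


def dummy_stratified(y_train, n_test: int, seed: int = 0) -> np.ndarray:
    """Baseline: i.i.d. draws from the training class frequencies.

    For class prior p the expected accuracy is p^2 + (1-p)^2.
    """
    y_train = np.asarray(y_train, dtype=bool)
    if len(y_train) == 0:
        raise ValueError("empty training labels")
    p = y_train.mean()
    rng = np.random.default_rng(seed)
    return rng.random(n_test) < p


def reconstruct_confusion(
    n: int, accuracy: float, precision: float, recall: float, decimals: int = 3
):
    """Integer confusion matrices consistent with printed rounded metrics.

    Exhaustively enumerates all (TP, FP, FN, TN) with TP+FP+FN+TN = n
    and returns those whose accuracy/precision/recall round (half away
    from zero) to the given values.  Returns a single tuple when the
    solution is unique, a list when several fit, or ``None`` when the
    printed metrics are mutually inconsistent at this n.
    """
    if n > 200:
        raise ValueError("reconstruction supported for n <= 200")
    target = tuple(round_half_away(v, decimals) for v in (accuracy, precision, recall))
    solutions = []
    for tp in range(n + 1):
        for fp in range(n - tp + 1):
            for fn in range(n - tp - fp + 1):
                tn = n - tp - fp - fn
                acc = (tp + tn) / n
                if round_half_away(acc, decimals) != target[0]:
                    continue
                if tp + fp == 0 or tp + fn == 0:
                    continue
                prec = tp / (tp + fp)
                rec = tp / (tp + fn)
                if (
                    round_half_away(prec, decimals) == target[1]
                    and round_half_away(rec, decimals) == target[2]
                ):
                    solutions.append((tp, fp, fn, tn))
    if not solutions:
        return None
    return solutions[0] if len(solutions) == 1 else solutions


@dataclass
class ImportanceReport:
    """Max-normalised absolute coefficients on a 0-100 scale."""

    scores: dict  # feature name -> importance in [0, 100]

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(self.scores.items(), key=lambda t: -t[1]),
            columns=["feature", "importance"],
        )


def logistic_importance(coefficients, feature_names=None) -> ImportanceReport:
    """Importance of standardized-model coefficients: 100 * |c| / max|c|."""
    coefs = np.asarray(coefficients, dtype=float).ravel()
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"feature_{i}" for i in range(len(coefs))]
    )
    if len(names) != len(coefs):
        raise ValueError("feature names and coefficients differ in length")
    top = np.max(np.abs(coefs))
    if top == 0:
        warnings.warn("all coefficients are zero; importances all zero")
        return ImportanceReport(scores={n: 0.0 for n in names})
    return ImportanceReport(
        scores={n: 100.0 * abs(c) / top for n, c in zip(names, coefs)}
    )


# ---------------------------------------------------------------------------
# end-to-end protocol for one (algorithm, response)


def tune_and_evaluate(
    spec: ModelSpec,
    X_train,
    y_train,
    X_holdout,
    y_holdout,
    k_max: int = 10,
    folds: int = 5,
    seed: int = 0,
    feature_names=None,
) -> dict:
    """Full protocol: choose k, grid-search, evaluate CV5 and holdout.

    Returns a report dict with the chosen k, selected feature names,
    best hyperparameters, pooled-CV and holdout :class:`EvalReport`
    data, and (for LOG) max-normalised coefficient importances.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=bool)
    kinfo = choose_k(
        X_train, y_train, [spec], k_range=range(1, min(k_max, X_train.shape[1]) + 1),
        folds=folds, seed=seed,
    )[spec.algorithm]
    k = kinfo["k"]
    if k is None:
        raise RuntimeError(f"{spec.algorithm}: every k failed during selection")
    best_params, cv_report = grid_search_cv(spec, X_train, y_train, k, folds, seed)
    pipe = build_pipeline(spec, k, best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X_train, y_train)
    holdout_pred = pipe.predict(np.asarray(X_holdout, dtype=float)).astype(bool)
    holdout_report = evaluate(holdout_pred, np.asarray(y_holdout, dtype=bool))
    sel = pipe.named_steps["select"].indices_
    selected_names = (
        [feature_names[i] for i in sel] if feature_names is not None else list(map(int, sel))
    )
    report = {
        "algorithm": spec.algorithm,
        "k": int(k),
        "selected_features": selected_names,
        "best_params": best_params,
        "cv": cv_report.as_dict(),
        "holdout": holdout_report.as_dict(),
    }
    model = pipe.named_steps["model"]
    if hasattr(model, "coef_"):
        report["importance"] = logistic_importance(
            model.coef_, selected_names
        ).scores
    return report
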