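"""Classification of phylogenies as structured vs non-structured.

Trees are represented by the eight-statistic feature vector (normalised
cherries/Sackin/Colless, total cophenetic index, ladder length, maximum
width, maximum depth, width-depth ratio).  Five model families are supported:
k-nearest neighbours, support vector machines with linear, polynomial and
radial kernels (regularisation constant fixed at C = 1), and a decision tree.
Hyperparameters are grid-searched by cross-validated accuracy; evaluation
uses stratified 10-fold cross-validation with per-fold sensitivity,
specificity, accuracy and AUC ("structured" is the positive class).
Features are standardised inside each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .design import latin_hypercube_design, LHSDesign  # noqa: F401 (re-export)
from .shape import FEATURE_COLUMNS, statistics_table

__all__ = [
    "MODEL_NAMES", "ClassifierEvaluation", "build_feature_matrix",
    "tune_and_train", "kfold_cross_validate", "evaluate_predictions",
    "roc_auc", "latin_hypercube_design", "sensitivity_experiment",
    "classify_trees",
]

MODEL_NAMES = ("knn", "svm-linear", "svm-polynomial", "svm-radial",
               "decision-tree")
POSITIVE_CLASS = "structured"


@dataclass
class ClassifierEvaluation:
    """Per-fold and mean binary-classification metrics.

    Sensitivity = TP / (TP + FN) and specificity = TN / (TN + FP) with
    "structured" as the positive class; the confusion matrix pools the
    evaluated predictions as [[TN, FP], [FN, TP]].
    """

    per_fold: pd.DataFrame = field(repr=False)
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    confusion: np.ndarray = field(repr=False)
    hyperparameters: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "auc": self.auc, "accuracy": self.accuracy}


def build_feature_matrix(stats_table: pd.DataFrame):
    """Extract (X, y) from a statistics table.

    Deterministic column order (``FEATURE_COLUMNS``); rows with missing
    statistics are rejected, duplicate tree ids are an error.
    """
    if stats_table["tree_id"].duplicated().any():
        raise ValueError("duplicate tree ids in statistics table")
    missing = stats_table[FEATURE_COLUMNS].isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"rows with missing statistics: {list(stats_table.loc[missing, 'tree_id'])}")
    x = stats_table[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = stats_table["label"].to_numpy()
    return x, y


def _median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    """1 / (2 sigma^2) with sigma the median pairwise distance of (a subsample
    of) the standardised features."""
    z = StandardScaler().fit_transform(x)
    if len(z) > 500:
        z = z[rng.choice(len(z), 500, replace=False)]
    d2 = np.sum((z[:, None, :] - z[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / (2 * max(med, 1e-12))


def _model_and_grid(model: str, x: np.ndarray, seed: int):
    rng = np.random.default_rng(seed)
    if model == "knn":
        return KNeighborsClassifier(), {"clf__n_neighbors": [3, 5, 7, 9, 11]}
    if model == "svm-linear":
        return SVC(kernel="linear", C=1.0), {}
    if model == "svm-polynomial":
        return SVC(kernel="poly", C=1.0, coef0=1.0), {
            "clf__degree": [2, 3, 4], "clf__gamma": [0.01, 0.1, 1.0]}
    if model == "svm-radial":
        g0 = _median_heuristic_gamma(x, rng)
        return SVC(kernel="rbf", C=1.0), {
            "clf__gamma": [g0 / 4, g0 / 2, g0, 2 * g0, 4 * g0]}
    if model == "decision-tree":
        return DecisionTreeClassifier(random_state=seed), {
            "clf__ccp_alpha": [0.0001, 0.0003, 0.001, 0.003, 0.01, 0.028, 0.1]}
    raise ValueError(f"unknown model {model!r}")


def tune_and_train(x: np.ndarray, y: np.ndarray, model: str,
                   seed: int = 0, cv: int = 10):
    """Grid-search hyperparameters by cross-validated accuracy and refit.

    Returns ``(fitted_pipeline, best_params)``; the pipeline standardises
    features before the classifier, so scaling is always learned on the
    training data only.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    estimator, grid = _model_and_grid(model, x, seed)
    pipe = Pipeline([("scale", StandardScaler()), ("clf", estimator)])
    if not grid:
        pipe.fit(x, y)
        return pipe, {}
    search = GridSearchCV(
        pipe, grid, scoring="accuracy",
        cv=StratifiedKFold(cv, shuffle=True, random_state=seed), n_jobs=None)
    search.fit(x, y)
    return search.best_estimator_, dict(search.best_params_)


def _scores(fitted, x: np.ndarray) -> np.ndarray:
    """Continuous score for the positive class (decision values for SVMs,
    vote/leaf frequencies otherwise)."""
    clf = fitted.named_steps["clf"] if isinstance(fitted, Pipeline) else fitted
    if hasattr(clf, "decision_function"):
        s = fitted.decision_function(x)
        # orient: sklearn's decision_function is for classes_[1]
        positive_last = list(fitted.classes_)[-1] == POSITIVE_CLASS
        return s if positive_last else -s
    proba = fitted.predict_proba(x)
    pos_idx = list(fitted.classes_).index(POSITIVE_CLASS)
    return proba[:, pos_idx]


def evaluate_predictions(y_true, y_pred, scores=None) -> ClassifierEvaluation:
    """Metrics for one set of aligned predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between truth and predictions")
    pos = y_true == POSITIVE_CLASS
    tp = int(np.sum(pos & (y_pred == POSITIVE_CLASS)))
    fn = int(np.sum(pos & (y_pred != POSITIVE_CLASS)))
    tn = int(np.sum(~pos & (y_pred != POSITIVE_CLASS)))
    fp = int(np.sum(~pos & (y_pred == POSITIVE_CLASS)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(y_true)
    auc = roc_auc(y_true, scores)[0] if scores is not None else np.nan
    fold = pd.DataFrame([{"sensitivity": sens, "specificity": spec,
                          "accuracy": acc, "auc": auc}])
    return ClassifierEvaluation(fold, sens, spec, acc, auc,
                                np.array([[tn, fp], [fn, tp]]))


def roc_auc(y_true, scores):
    """AUC by trapezoidal integration of the ROC curve, plus its points.

    Equals the rank-sum (pairwise concordance) formulation: the probability
    that a random positive outscores a random negative, ties counting half.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == POSITIVE_CLASS
    if pos.all() or not pos.any():
        raise ValueError("both classes required for ROC")
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=POSITIVE_CLASS)
    return float(np.trapezoid(tpr, fpr)), np.column_stack([fpr, tpr])


def kfold_cross_validate(x: np.ndarray, y: np.ndarray, model: str,
                         k_folds: int = 10, seed: int = 0,
                         tune: bool = True) -> ClassifierEvaluation:
    """Stratified k-fold cross-validation of a (tuned) model.

    Hyperparameters are grid-searched once on the full data (the tuned model
    is then scored on stratified folds, scaler refit per training fold);
    metrics are averaged over folds and the confusion matrix pools all
    held-out predictions.
    """
    if len(y) < k_folds:
        raise ValueError("fewer samples than folds")
    if tune:
        fitted, best = tune_and_train(x, y, model, seed=seed, cv=min(k_folds, 5))
        template = fitted
    else:
        estimator, _ = _model_and_grid(model, x, seed)
        template = Pipeline([("scale", StandardScaler()), ("clf", estimator)])
        best = {}
    folds = []
    confusion = np.zeros((2, 2), dtype=int)
    skf = StratifiedKFold(k_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(x, y):
        est = clone(template)
        est.fit(x[train_idx], y[train_idx])
        pred = est.predict(x[test_idx])
        scores = _scores(est, x[test_idx])
        ev = evaluate_predictions(y[test_idx], pred, scores)
        folds.append(ev.per_fold.iloc[0])
        confusion += ev.confusion
    per_fold = pd.DataFrame(folds).reset_index(drop=True)
    means = per_fold.mean()
    return ClassifierEvaluation(per_fold, float(means.sensitivity),
                                float(means.specificity),
                                float(means.accuracy), float(means.auc),
                                confusion, best)


def classify_trees(fitted, trees) -> pd.DataFrame:
    """Label a collection of trees with a fitted classifier.

    Returns one row per tree (tree_id, predicted label, score); the frame's
    ``attrs["proportions"]`` holds the percentage breakdown by class.
    """
    trees = list(trees)
    if not trees:
        out = pd.DataFrame(columns=["tree_id", "predicted", "score"])
        out.attrs["proportions"] = {}
        return out
    table = statistics_table(trees)
    x = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    pred = fitted.predict(x)
    out = pd.DataFrame({"tree_id": table["tree_id"], "predicted": pred,
                        "score": _scores(fitted, x)})
    counts = out["predicted"].value_counts(normalize=True) * 100.0
    out.attrs["proportions"] = counts.to_dict()
    return out


def sensitivity_experiment(modes=("varied-size", "varied-parameters", "both"),
                           models=MODEL_NAMES, seed: int = 0,
                           n_unstructured: int = 250, n_structured: int = 250,
                           k_folds: int = 10,
                           design_kwargs: dict | None = None) -> pd.DataFrame:
    """Robustness of the classifiers to varied tree sizes and parameters.

    For each mode, 250 + 250 trees (configurable) are simulated with tree
    sizes and/or per-deme R0 drawn by Latin hypercube sampling, then every
    model is evaluated under stratified 10-fold cross-validation.  Returns a
    long report with one row per (mode, model) and the four mean metrics.
    """
    from .simulate import simulate_dataset, varied_design

    rows = []
    for mode_i, mode in enumerate(modes):
        design = varied_design(seed + 1000 * mode_i, mode,
                               n_unstructured, n_structured,
                               **(design_kwargs or {}))
        data = simulate_dataset(design)
        table = statistics_table(data.trees)
        x, y = build_feature_matrix(table)
        for model in models:
            ev = kfold_cross_validate(x, y, model, k_folds=k_folds, seed=seed)
            rows.append({"mode": mode, "model": model, "n_trees": len(y),
                         **ev.summary()})
    return pd.DataFrame(rows)
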