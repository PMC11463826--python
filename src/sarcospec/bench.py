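"""Nested grid-search benchmark of KNN / logistic regression / RBF-SVM.

The protocol: an 80:20 stratified train/test split, then for each model
family a nested grid search — five outer stratified folds, and within each
outer-fold training portion an exhaustive grid search scored by five inner
stratified folds.  Each outer fold yields a winning hyperparameter
combination and its score on that fold's held-out portion; the winner with
the best outer score is refit on the whole training set and evaluated once
on the untouched 20% test set.  PCA (95% variance rule) sits inside the
fitted pipeline, so it is refit on training data only in every fold —
the test set never leaks into any fitting step.

Sarcoma is the positive class throughout; specificity is the healthy
true-negative rate.  Alongside the benchmark live the ROC/AUC helper, the
learning-curve diagnostic and the inverse-power-law sample-size
extrapolation acc(n) = a - b * n^(-c).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA as _SKPCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.model_selection import learning_curve as _sk_learning_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

POSITIVE = "sarcoma"
NEGATIVE = "healthy"

MODEL_FAMILIES = ("knn", "logistic", "svm_rbf")


@dataclass(frozen=True)
class HyperparameterGrid:
    model_family: str
    params: Dict[str, list]

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.model_family!r}")
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise ValueError("every hyperparameter list must be nonempty")

    def combinations(self) -> List[dict]:
        names = list(self.params)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.params[n] for n in names))
        ]


def default_grid(family: str) -> HyperparameterGrid:
    """The benchmark's stock grids per model family.

    The SVM gamma entries 'auto' and 'scale' are 1/n_features and
    1/(n_features * Var(X)) respectively.
    """
    if family == "svm_rbf":
        return HyperparameterGrid(
            "svm_rbf",
            {"C": [0.5, 1, 5, 10, 30, 40], "gamma": [0.001, 0.005, 0.01, "auto", "scale"]},
        )
    if family == "logistic":
        return HyperparameterGrid(
            "logistic",
            {
                "C": [0.001, 0.01, 0.1, 1],
                "solver": ["newton-cg", "lbfgs", "sag", "saga"],
                "penalty": ["l1", "l2", None],
            },
        )
    if family == "knn":
        return HyperparameterGrid(
            "knn",
            {
                "n_neighbors": [5, 7, 10, 15, 20],
                "metric": ["manhattan", "euclidean", "minkowski"],
                "weights": ["distance", "uniform"],
            },
        )
    raise ValueError(f"unknown model family {family!r}")


@dataclass(frozen=True)
class CVPlan:
    test_fraction: float = 0.2
    outer_folds: int = 5
    inner_folds: int = 5
    scoring: str = "accuracy"
    seed: int = 20241009

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be at least 2")
        if self.scoring not in ("accuracy",):
            raise ValueError(f"unsupported scoring {self.scoring!r}")


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    specificity: float
    precision_pos: float
    precision_macro: float
    recall_pos: float
    recall_macro: float
    f1_pos: float
    f1_macro: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "precision_pos": self.precision_pos,
            "precision_macro": self.precision_macro,
            "recall_pos": self.recall_pos,
            "recall_macro": self.recall_macro,
            "f1_pos": self.f1_pos,
            "f1_macro": self.f1_macro,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


@dataclass
class FoldRecord:
    fold: int
    train_indices: np.ndarray
    val_indices: np.ndarray
    best_params: dict
    inner_mean_score: float
    outer_score: float


@dataclass
class SearchResult:
    family: str
    model: Pipeline
    best_params: dict
    fold_records: List[FoldRecord]
    skipped_combinations: List[dict] = field(default_factory=list)


def make_estimator(
    family: str,
    params: Optional[dict] = None,
    use_pca: bool = True,
    var_target: float = 0.95,
    seed: int = 0,
) -> Pipeline:
    """Pipeline of (optional) 95%-rule PCA followed by the classifier."""
    params = dict(params or {})
    if family == "svm_rbf":
        clf = SVC(kernel="rbf", random_state=seed, **params)
    elif family == "logistic":
        clf = LogisticRegression(max_iter=5000, random_state=seed, **params)
    elif family == "knn":
        clf = KNeighborsClassifier(**params)
    else:
        raise ValueError(f"unknown model family {family!r}")
    steps = []
    if use_pca:
        steps.append(("pca", _SKPCA(n_components=var_target, svd_solver="full")))
    steps.append(("clf", clf))
    return Pipeline(steps)


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores oriented so larger means more sarcoma-like."""
    final = model[-1] if isinstance(model, Pipeline) else model
    classes = list(final.classes_)
    pos = classes.index(POSITIVE)
    if hasattr(model, "decision_function"):
        scores = model.decision_function(X)
        # sklearn orients decision_function toward classes_[1]
        return scores if pos == 1 else -scores
    proba = model.predict_proba(X)
    return proba[:, pos]


def stratified_split(
    y: Sequence[str],
    plan: CVPlan,
    groups: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test index split.

    The test set takes round(f * n_c) members of each class c (round half
    up), so 393 sarcoma + 118 healthy at f=0.2 give a 79 + 24 test set.
    With ``groups`` (e.g. mouse ids), whole groups are assigned to one side
    — an honest-generalization mode, off by default.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(plan.seed)
    test_idx: List[int] = []
    if groups is None:
        for cls in classes:
            members = np.flatnonzero(y == cls)
            if members.size < plan.outer_folds:
                raise ValueError(f"class {cls!r} has fewer members than folds")
            n_test = int(np.floor(plan.test_fraction * members.size + 0.5))
            chosen = rng.permutation(members)[:n_test]
            test_idx.extend(chosen.tolist())
    else:
        groups = np.asarray(groups)
        for cls in classes:
            members = np.flatnonzero(y == cls)
            cls_groups = rng.permutation(np.unique(groups[members]))
            target = plan.test_fraction * members.size
            picked: List[int] = []
            for g in cls_groups:
                if len(picked) >= target:
                    break
                picked.extend(np.flatnonzero((y == cls) & (groups == g)).tolist())
            test_idx.extend(picked)
    test = np.array(sorted(test_idx), dtype=int)
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def _complexity_key(family: str, params: dict) -> tuple:
    """Tie-break preference: simpler models first.

    Smaller C (stronger regularization) for SVM/LR, stronger penalty for
    LR (l1 before l2 before none), larger k for KNN.
    """
    if family == "svm_rbf":
        return (params["C"],)
    if family == "logistic":
        penalty_rank = {"l1": 0, "l2": 1, None: 2}
        return (params["C"], penalty_rank.get(params.get("penalty"), 3))
    if family == "knn":
        return (-params["n_neighbors"],)
    return ()


def nested_grid_search(
    X: np.ndarray,
    y: Sequence[str],
    family: str,
    grid: Optional[HyperparameterGrid] = None,
    plan: CVPlan = CVPlan(),
    use_pca: bool = True,
) -> SearchResult:
    """Nested grid search: inner CV selects per-fold winners, outer CV
    compares them, and the best is refit on the full training data.

    Hyperparameter combinations a fitter rejects (e.g. an LR solver/penalty
    pair sklearn does not support) are skipped and recorded.  Ties are
    broken by highest mean score, then lowest complexity, then grid order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = grid or default_grid(family)
    if grid.model_family != family:
        raise ValueError("grid/family mismatch")
    combos = grid.combinations()
    outer = StratifiedKFold(plan.outer_folds, shuffle=True, random_state=plan.seed)
    skipped: List[dict] = []
    skipped_keys = set()
    records: List[FoldRecord] = []

    for fold, (tr, va) in enumerate(outer.split(X, y)):
        if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
            raise ValueError(f"outer fold {fold} is single-class")
        inner = StratifiedKFold(
            plan.inner_folds, shuffle=True, random_state=plan.seed + 1 + fold
        )
        best: Optional[Tuple[float, tuple, int, dict]] = None
        for gi, params in enumerate(combos):
            scores = []
            failed = False
            for itr, iva in inner.split(X[tr], y[tr]):
                est = make_estimator(family, params, use_pca=use_pca, seed=plan.seed)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est.fit(X[tr][itr], y[tr][itr])
                        pred = est.predict(X[tr][iva])
                except (ValueError, TypeError):
                    # illegal cell for this fitter (e.g. unsupported
                    # solver/penalty pair, k larger than the fold)
                    failed = True
                    break
                scores.append(float(np.mean(pred == y[tr][iva])))
            if failed:
                key = tuple(sorted(params.items(), key=lambda kv: kv[0]))
                if key not in skipped_keys:
                    skipped_keys.add(key)
                    skipped.append(params)
                continue
            mean_score = float(np.mean(scores))
            cand = (-mean_score, _complexity_key(family, params), gi, params)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            raise ValueError("every grid combination failed to fit")
        best_params = best[3]
        est = make_estimator(family, best_params, use_pca=use_pca, seed=plan.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
        outer_score = float(np.mean(est.predict(X[va]) == y[va]))
        records.append(
            FoldRecord(
                fold=fold,
                train_indices=tr,
                val_indices=va,
                best_params=best_params,
                inner_mean_score=-best[0],
                outer_score=outer_score,
            )
        )

    winner = min(
        records,
        key=lambda r: (-r.outer_score, _complexity_key(family, r.best_params), r.fold),
    )
    final = make_estimator(family, winner.best_params, use_pca=use_pca, seed=plan.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return SearchResult(
        family=family,
        model=final,
        best_params=winner.best_params,
        fold_records=records,
        skipped_combinations=skipped,
    )


def roc_with_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC sweep and trapezoid AUC; scores orient larger = more sarcoma-like.

    Returns (fpr, tpr, thresholds, auc).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, pos_label=POSITIVE)
    return fpr, tpr, thresholds, float(_sk_auc(fpr, tpr))


def evaluate_classifier(model, X_test: np.ndarray, y_test: Sequence[str]) -> MetricsReport:
    """All report metrics from one confusion matrix (sarcoma = positive)."""
    y_test = np.asarray(y_test)
    if np.unique(y_test).size < 2:
        raise ValueError("test set must contain both classes")
    pred = model.predict(np.asarray(X_test, dtype=float))
    tp = int(np.sum((pred == POSITIVE) & (y_test == POSITIVE)))
    fp = int(np.sum((pred == POSITIVE) & (y_test == NEGATIVE)))
    tn = int(np.sum((pred == NEGATIVE) & (y_test == NEGATIVE)))
    fn = int(np.sum((pred == NEGATIVE) & (y_test == POSITIVE)))

    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    precision_pos = safe(tp, tp + fp)
    recall_pos = safe(tp, tp + fn)
    precision_neg = safe(tn, tn + fn)
    recall_neg = safe(tn, tn + fp)

    def f1(p: float, r: float) -> float:
        return safe(2 * p * r, p + r)

    scores = decision_scores(model, np.asarray(X_test, dtype=float))
    *_, auc_value = roc_with_auc(scores, y_test)
    return MetricsReport(
        accuracy=safe(tp + tn, tp + tn + fp + fn),
        specificity=recall_neg,
        precision_pos=precision_pos,
        precision_macro=(precision_pos + precision_neg) / 2.0,
        recall_pos=recall_pos,
        recall_macro=(recall_pos + recall_neg) / 2.0,
        f1_pos=f1(precision_pos, recall_pos),
        f1_macro=(f1(precision_pos, recall_pos) + f1(precision_neg, recall_neg)) / 2.0,
        auc=auc_value,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


@dataclass
class LearningCurvePoint:
    fraction: float
    n_train: int
    train_mean: float
    train_sd: float
    val_mean: float
    val_sd: float


def learning_curve(
    X: np.ndarray,
    y: Sequence[str],
    family: str,
    params: Optional[dict] = None,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    plan: CVPlan = CVPlan(),
    use_pca: bool = True,
    subset_fraction: float = 0.9,
) -> List[LearningCurvePoint]:
    """Train/validation accuracy vs training-set size.

    A 90% stratified subset of the data feeds 5-fold CV; within each fold
    the training portion is subsampled to each fraction, and the mean and
    sd of the five train and validation scores are reported per fraction.
    """
    if any(not (0.0 < f <= 1.0) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    y = np.asarray(y)
    subset_plan = CVPlan(
        test_fraction=1.0 - subset_fraction,
        outer_folds=plan.outer_folds,
        inner_folds=plan.inner_folds,
        seed=plan.seed,
    )
    keep, _ = stratified_split(y, subset_plan)
    Xs, ys = np.asarray(X, dtype=float)[keep], y[keep]
    est = make_estimator(family, params, use_pca=use_pca, seed=plan.seed)
    cv = StratifiedKFold(plan.outer_folds, shuffle=True, random_state=plan.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sizes, train_scores, val_scores = _sk_learning_curve(
            est,
            Xs,
            ys,
            train_sizes=np.asarray(fractions),
            cv=cv,
            scoring="accuracy",
            shuffle=True,
            random_state=plan.seed,
            error_score=np.nan,
        )
    points = []
    for f, n, tr, va in zip(fractions, sizes, train_scores, val_scores):
        if np.all(np.isnan(tr)) or np.all(np.isnan(va)):
            warnings.warn(
                f"training fraction {f} is too small to fit both classes; skipped",
                stacklevel=2,
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            points.append(
                LearningCurvePoint(
                    fraction=float(f),
                    n_train=int(n),
                    train_mean=float(np.nanmean(tr)),
                    train_sd=float(np.nanstd(tr)),
                    val_mean=float(np.nanmean(va)),
                    val_sd=float(np.nanstd(va)),
                )
            )
    return points


@dataclass(frozen=True)
class SampleSizeEstimate:
    attainable: bool
    n_required: Optional[int]
    a: float
    b: float
    c: float


def estimate_sample_size(
    points: Sequence[Tuple[float, float]], target_accuracy: float = 0.90
) -> SampleSizeEstimate:
    """Inverse-power-law extrapolation of validation accuracy vs sample size.

    Fits acc(n) = a - b * n^(-c) by least squares (a in (0, 1], b, c > 0)
    and inverts it: the smallest n with acc(n) >= target is
    ceil((b / (a - target))^(1/c)).  When the fitted asymptote a falls
    below the target the estimate is flagged non-attainable.
    """
    points = list(points)
    if len(points) < 4:
        raise ValueError("need at least 4 (n, accuracy) points")
    n = np.array([p[0] for p in points], dtype=float)
    acc = np.array([p[1] for p in points], dtype=float)
    if np.any(n <= 0) or np.any((acc <= 0) | (acc >= 1)):
        raise ValueError("sample sizes must be positive and accuracies in (0, 1)")

    def model(n, a, b, c):
        return a - b * np.power(n, -c)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                n,
                acc,
                p0=(min(0.99, acc.max() + 0.02), 1.0, 0.5),
                bounds=([1e-9, 1e-12, 1e-9], [1.0, np.inf, np.inf]),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
    except RuntimeError:
        return SampleSizeEstimate(False, None, np.nan, np.nan, np.nan)
    a, b, c = (float(v) for v in popt)
    if a <= target_accuracy:
        return SampleSizeEstimate(False, None, a, b, c)
    n_star = (b / (a - target_accuracy)) ** (1.0 / c)
    return SampleSizeEstimate(True, int(np.ceil(n_star - 1e-9)), a, b, c)


def run_benchmark(
    X: np.ndarray,
    y: Sequence[str],
    families: Sequence[str] = MODEL_FAMILIES,
    plan: CVPlan = CVPlan(),
    use_pca: bool = True,
) -> dict:
    """End-to-end benchmark: split, nested search per family, test metrics.

    Returns {"split": ..., "models": {family: {"metrics", "best_params",
    "fold_records", "roc"}}} with every stochastic choice derived from
    plan.seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train_idx, test_idx = stratified_split(y, plan)
    result: dict = {
        "seed": plan.seed,
        "split": {"train_indices": train_idx, "test_indices": test_idx},
        "models": {},
    }
    for family in families:
        search = nested_grid_search(X[train_idx], y[train_idx], family, plan=plan, use_pca=use_pca)
        metrics = evaluate_classifier(search.model, X[test_idx], y[test_idx])
        scores = decision_scores(search.model, X[test_idx])
        fpr, tpr, thresholds, auc_value = roc_with_auc(scores, y[test_idx])
        result["models"][family] = {
            "metrics": metrics,
            "best_params": search.best_params,
            "fold_records": search.fold_records,
            "skipped_combinations": search.skipped_combinations,
            "roc": {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": auc_value},
        }
    return result
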