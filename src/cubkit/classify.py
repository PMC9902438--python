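"""Classification harness for codon-usage tables.

Splitting and cross-validation, a from-scratch Euclidean k-NN and
Gaussian naive Bayes, a hard-voting ensemble, the confusion-matrix
metric suite (accuracy, per-class / micro / macro precision, recall and
F1, and trapezoid one-vs-rest ROC AUC), PCA-reduced classification and
a K-Means cluster survey.  SVM, random forest, gradient boosting and
neural-network classifiers are thin seeded wrappers around established
implementations, shipped with tuned hyperparameter presets for the
five-kingdom and DNA-type tasks.

Conventions: for single-label multiclass evaluation micro-F1 equals
accuracy (an algebraic identity that is asserted in tests); metrics
with a zero denominator are reported as 0 with a warning; multiclass
AUC is the macro average of one-vs-rest trapezoid AUCs computed from
class score vectors (k-NN vote fractions, model probabilities or
decision values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ModelSpec",
    "ClusterSurvey",
    "PRESETS",
    "stratified_split",
    "kfold_cv",
    "knn_classify",
    "gaussian_nb",
    "hard_vote",
    "compute_metrics",
    "roc_auc",
    "pca_classify",
    "kmeans_survey",
    "train_model",
    "evaluate_split",
]

#: Tuned hyperparameters per task.  ``kingdom`` is the five-way
#: taxonomic task (archaea/bacteria/eukaryote/phage/virus), ``dnatype``
#: the organelle task (nuclear/mitochondrial/chloroplast).
PRESETS: dict[str, dict[str, dict]] = {
    "kingdom": {
        "knn": {"k": 1},
        "svm": {"C": 144.0, "gamma": 50.0, "kernel": "rbf"},
        "rf": {
            "n_estimators": 1200, "min_samples_split": 2, "min_samples_leaf": 1,
            "max_features": "sqrt", "max_depth": 100, "bootstrap": False,
        },
        "xgb": {"n_estimators": 300, "learning_rate": 0.3, "max_depth": 6},
        "ann": {
            "hidden_layer_sizes": (600, 600, 300, 150), "alpha": 6.1e-7,
            "early_stopping": True, "n_iter_no_change": 50, "max_iter": 1000,
        },
        "gnb": {},
    },
    "dnatype": {
        "knn": {"k": 3},
        "svm": {"C": 400.0, "gamma": 50.0, "kernel": "rbf"},
        "rf": {
            "n_estimators": 1088, "min_samples_split": 5, "min_samples_leaf": 1,
            "max_features": "sqrt", "max_depth": None, "bootstrap": False,
        },
        "xgb": {"n_estimators": 300, "learning_rate": 0.3, "max_depth": 6},
        "ann": {
            "hidden_layer_sizes": (700,) * 6 + (350, 175), "alpha": 6.3e-5,
            "early_stopping": True, "n_iter_no_change": 50, "max_iter": 1000,
        },
        "gnb": {},
    },
}

#: Final shipped hard-voting ensemble membership.
ENSEMBLE_MEMBERS = ("knn", "svm", "rf")


# ---------------------------------------------------------------------------
# splitting and cross-validation

def stratified_split(
    y: Sequence,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split preserving class proportions.

    Returns ``(train_idx, test_idx)``; disjoint, exhaustive and
    deterministic for a given seed.  A class with a single member
    cannot be stratified and is an error.
    """
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    singles = labels[counts < 2]
    if singles.size:
        raise ValueError(f"classes with a single member cannot be split: {singles.tolist()}")
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(train), np.sort(test)


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float


def kfold_cv(spec: "ModelSpec", X: np.ndarray, y: Sequence, k: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation accuracy of one model spec."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    smallest = np.unique(y, return_counts=True)[1].min()
    if k > smallest:
        raise ValueError(f"k={k} exceeds the smallest class count {smallest}")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    seen: set[int] = set()
    for train_idx, test_idx in folds.split(X, y):
        assert not seen & set(test_idx.tolist()), "cross-validation folds overlap"
        seen |= set(test_idx.tolist())
        model = train_model(spec, X[train_idx], y[train_idx])
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
    assert len(seen) == len(y), "cross-validation folds are not exhaustive"
    return CVResult(tuple(accs), float(np.mean(accs)))


# ---------------------------------------------------------------------------
# from-scratch classifiers

def knn_classify(
    train_X: np.ndarray,
    train_y: Sequence,
    query_X: np.ndarray,
    k: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euclidean k-nearest-neighbour classification.

    Each query takes the majority label among its ``k`` nearest training
    points; the vote fraction of class ``j`` is the share of the ``k``
    neighbours labeled ``j`` (used as a class score for ROC curves).
    Returns ``(labels, vote_fractions, classes)`` with ``vote_fractions``
    of shape (n_queries, n_classes) over ``classes``.  Vote ties break
    toward the class of the nearer neighbour.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=np.float64))
    query_X = np.atleast_2d(np.asarray(query_X, dtype=np.float64))
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= train_X.shape[0]:
        raise ValueError(f"k must be in 1..{train_X.shape[0]}")
    classes = np.unique(train_y)
    class_idx = {c: i for i, c in enumerate(classes)}
    dist = cdist(query_X, train_X, metric="euclidean")
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes = np.zeros((len(query_X), len(classes)))
    labels = np.empty(len(query_X), dtype=classes.dtype)
    for i, nbrs in enumerate(nearest):
        for j in nbrs:
            votes[i, class_idx[train_y[j]]] += 1
        best = votes[i].max()
        tied = {c for c, ci in class_idx.items() if votes[i, ci] == best}
        # nearer neighbour wins ties (deterministic: nbrs is distance-sorted)
        labels[i] = next(train_y[j] for j in nbrs if train_y[j] in tied)
    return labels, votes / k, classes


def gaussian_nb(
    train_X: np.ndarray,
    train_y: Sequence,
    query_X: np.ndarray,
    var_floor: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian naive Bayes: posterior ∝ prior x product of per-feature
    Gaussian likelihoods.

    Class priors are training frequencies; per-class, per-feature
    variances are floored at ``var_floor`` (degenerate constant
    features warn).  Returns ``(labels, posteriors, classes)`` with
    posteriors normalized to sum to 1 per query.

    Note the independence assumption is knowingly violated for codon
    frequencies (they sum to 1), which is why this model serves as a
    worst-case baseline.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=np.float64))
    query_X = np.atleast_2d(np.asarray(query_X, dtype=np.float64))
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ValueError("at least 2 classes are required")
    log_like = np.zeros((len(query_X), len(classes)))
    for ci, c in enumerate(classes):
        Xc = train_X[train_y == c]
        mean = Xc.mean(axis=0)
        var = Xc.var(axis=0)
        if (var < var_floor).any():
            warnings.warn(
                f"class {c!r} has near-constant features; variance floored at {var_floor}",
                stacklevel=2,
            )
        var = np.maximum(var, var_floor)
        prior = len(Xc) / len(train_X)
        ll = -0.5 * (np.log(2 * np.pi * var) + (query_X - mean) ** 2 / var).sum(axis=1)
        log_like[:, ci] = ll + np.log(prior)
    log_like -= log_like.max(axis=1, keepdims=True)
    post = np.exp(log_like)
    post /= post.sum(axis=1, keepdims=True)
    return classes[np.argmax(post, axis=1)], post, classes


def hard_vote(
    predictions: Sequence[Sequence],
    model_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Unweighted plurality vote across models' predicted labels.

    ``predictions`` is one label sequence per model, all the same
    length.  Ties are broken by the earliest model (in ``model_order``,
    which defaults to input order) whose prediction is among the tied
    labels.
    """
    if not predictions:
        raise ValueError("at least one model's predictions are required")
    arrays = [np.asarray(p) for p in predictions]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("prediction sequences have mismatched lengths")
    order = list(range(len(arrays)))
    if model_order is not None:
        if len(model_order) != len(arrays):
            raise ValueError("model_order length mismatch")
    out = []
    for i in range(n):
        row = [arrays[m][i] for m in order]
        counts: dict = {}
        for lab in row:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        tied = {lab for lab, c in counts.items() if c == best}
        out.append(next(lab for lab in row if lab in tied))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts matrix with rows = true class, columns = predicted class."""

    labels: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix must be square over the label set")
        if (m < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if labels is None:
            labels = np.unique(np.concatenate([y_true, y_pred]))
        index = {lab: i for i, lab in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            m[index[t], index[p]] += 1
        return cls(tuple(labels), m)

    def one_vs_rest(self, label) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class."""
        i = self.labels.index(label)
        m = self.matrix
        tp = int(m[i, i])
        fp = int(m[:, i].sum() - tp)
        fn = int(m[i, :].sum() - tp)
        tn = int(m.sum() - tp - fp - fn)
        return tp, fp, fn, tn

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} has zero denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / den


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    per_class_precision: Mapping
    per_class_recall: Mapping
    per_class_f1: Mapping
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc: float | None = None
    confusion: ConfusionMatrix | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                str(lab): {
                    "precision": self.per_class_precision[lab],
                    "recall": self.per_class_recall[lab],
                    "f1": self.per_class_f1[lab],
                }
                for lab in self.per_class_precision
            },
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.confusion is not None:
            d["labels"] = [str(lab) for lab in self.confusion.labels]
            d["confusion_matrix"] = self.confusion.matrix.tolist()
        return d


def compute_metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricsReport:
    """Accuracy and per-class / micro / macro precision, recall and F1.

    Accuracy is the diagonal mass over the total.  Per-class metrics use
    the one-vs-rest reduction of the matrix (precision TP/(TP+FP),
    recall TP/(TP+FN), F1 = 2TP/(2TP+FP+FN)); micro averages pool the
    per-class TP/FP/FN before dividing, macro averages the per-class
    ratios.  Zero denominators yield 0 with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = {}
    fp = {}
    fn = {}
    prec = {}
    rec = {}
    f1 = {}
    for lab in cm.labels:
        tp[lab], fp[lab], fn[lab], _ = cm.one_vs_rest(lab)
        prec[lab] = _safe_div(tp[lab], tp[lab] + fp[lab], f"precision[{lab}]")
        rec[lab] = _safe_div(tp[lab], tp[lab] + fn[lab], f"recall[{lab}]")
        f1[lab] = _safe_div(2 * tp[lab], 2 * tp[lab] + fp[lab] + fn[lab], f"F1[{lab}]")
    stp = sum(tp.values())
    micro_p = _safe_div(stp, stp + sum(fp.values()), "micro precision")
    micro_r = _safe_div(stp, stp + sum(fn.values()), "micro recall")
    micro_f1 = _safe_div(2 * micro_p * micro_r, micro_p + micro_r, "micro F1")
    macro_p = float(np.mean(list(prec.values())))
    macro_r = float(np.mean(list(rec.values())))
    macro_f1 = _safe_div(2 * macro_p * macro_r, macro_p + macro_r, "macro F1")
    accuracy = float(np.trace(cm.matrix) / cm.total)
    return MetricsReport(
        accuracy=accuracy,
        per_class_precision=prec,
        per_class_recall=rec,
        per_class_f1=f1,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f1,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f1,
        auc=auc,
        confusion=cm,
    )


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Trapezoid area under the ROC curve of one score vector.

    The ROC is traced by sweeping the decision threshold through the
    unique score values (ties move along a diagonal segment, which the
    trapezoid rule scores as half-correct).
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = positive[order].astype(np.float64)
    n_pos = pos.sum()
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    tp = np.cumsum(pos)
    fp = np.cumsum(1 - pos)
    # keep only the last index of each tied score block
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[keep] / n_pos]
    fpr = np.r_[0.0, fp[keep] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def roc_auc(scores: np.ndarray, y_true: Sequence, classes: Sequence) -> float:
    """Macro-averaged one-vs-rest trapezoid AUC.

    ``scores`` has shape (n_samples, n_classes) over ``classes`` (vote
    fractions, probabilities, or decision values); every class must be
    present in ``y_true``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    y_true = np.asarray(y_true)
    present = set(np.unique(y_true).tolist())
    if len(present) < 2:
        raise ValueError("AUC requires at least 2 classes in the truth")
    aucs = []
    for ci, c in enumerate(classes):
        if c not in present:
            raise ValueError(f"class {c!r} absent from the truth labels")
        aucs.append(_binary_auc(scores[:, ci], y_true == c))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# model wrappers

@dataclass(frozen=True)
class ModelSpec:
    """A classifier kind plus hyperparameters and a seed.

    ``kind`` is one of ``knn``, ``svm``, ``rf``, ``xgb``, ``ann``,
    ``gnb``, ``ensemble``.  ``preset`` pulls tuned hyperparameters for
    a task (``kingdom`` or ``dnatype``); explicit ``params`` override
    preset values.
    """

    kind: str
    params: Mapping = field(default_factory=dict)
    preset: str | None = None
    seed: int = 0

    def resolved_params(self) -> dict:
        base: dict = {}
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}")
            base.update(PRESETS[self.preset].get(self.kind, {}))
        base.update(self.params)
        return base


class _KNNModel:
    def __init__(self, k: int):
        self.k = k

    def fit(self, X, y):
        self._X, self._y = np.asarray(X, dtype=np.float64), np.asarray(y)
        self.classes_ = np.unique(self._y)
        return self

    def predict(self, X):
        labels, _, _ = knn_classify(self._X, self._y, X, self.k)
        return labels

    def predict_score(self, X):
        _, votes, _ = knn_classify(self._X, self._y, X, self.k)
        return votes


class _GNBModel:
    def __init__(self, var_floor: float = 1e-9):
        self.var_floor = var_floor

    def fit(self, X, y):
        self._X, self._y = np.asarray(X, dtype=np.float64), np.asarray(y)
        self.classes_ = np.unique(self._y)
        return self

    def predict(self, X):
        labels, _, _ = gaussian_nb(self._X, self._y, X, self.var_floor)
        return labels

    def predict_score(self, X):
        _, post, _ = gaussian_nb(self._X, self._y, X, self.var_floor)
        return post


class _SklearnModel:
    def __init__(self, estimator, encode_labels: bool = False):
        self.estimator = estimator
        self.encode_labels = encode_labels

    def fit(self, X, y):
        if self.encode_labels:
            self._enc = LabelEncoder().fit(y)
            self.estimator.fit(X, self._enc.transform(y))
            self.classes_ = self._enc.classes_
        else:
            self.estimator.fit(X, y)
            self.classes_ = self.estimator.classes_
        return self

    def predict(self, X):
        pred = self.estimator.predict(X)
        return self._enc.inverse_transform(pred.astype(int)) if self.encode_labels else pred

    def predict_score(self, X):
        if hasattr(self.estimator, "predict_proba"):
            try:
                return self.estimator.predict_proba(X)
            except AttributeError:
                pass
        scores = self.estimator.decision_function(X)
        if scores.ndim == 1:  # binary: expand to two columns
            scores = np.c_[-scores, scores]
        return scores


class _EnsembleModel:
    """Hard-voting ensemble over member model specs (labels only)."""

    def __init__(self, members: Sequence[ModelSpec]):
        self.member_specs = tuple(members)

    def fit(self, X, y):
        self.members_ = [train_model(spec, X, y) for spec in self.member_specs]
        self.classes_ = np.unique(np.asarray(y))
        return self

    def predict(self, X):
        return hard_vote([m.predict(X) for m in self.members_])

    def predict_score(self, X):
        # mean of members' one-hot votes: the fraction of models voting each class
        idx = {c: i for i, c in enumerate(self.classes_)}
        votes = np.zeros((len(X), len(self.classes_)))
        for m in self.members_:
            for i, lab in enumerate(m.predict(X)):
                votes[i, idx[lab]] += 1
        return votes / len(self.members_)


def train_model(spec: ModelSpec, X: np.ndarray, y: Sequence):
    """Fit the classifier described by ``spec``; returns an object with
    ``predict``, ``predict_score`` and ``classes_``."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    p = spec.resolved_params()
    if spec.kind == "knn":
        return _KNNModel(k=p.get("k", 1)).fit(X, y)
    if spec.kind == "gnb":
        return _GNBModel(var_floor=p.get("var_floor", 1e-9)).fit(X, y)
    if spec.kind == "svm":
        est = SVC(
            C=p.get("C", 1.0), gamma=p.get("gamma", "scale"),
            kernel=p.get("kernel", "rbf"), random_state=spec.seed,
        )
        return _SklearnModel(est).fit(X, y)
    if spec.kind == "rf":
        est = RandomForestClassifier(random_state=spec.seed, **{k: v for k, v in p.items()})
        return _SklearnModel(est).fit(X, y)
    if spec.kind == "xgb":
        from xgboost import XGBClassifier

        est = XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0, **p)
        return _SklearnModel(est, encode_labels=True).fit(X, y)
    if spec.kind == "ann":
        est = MLPClassifier(random_state=spec.seed, **p)
        return _SklearnModel(est).fit(X, y)
    if spec.kind == "ensemble":
        members = p.get("members", ENSEMBLE_MEMBERS)
        specs = [
            m if isinstance(m, ModelSpec)
            else ModelSpec(kind=m, preset=spec.preset, seed=spec.seed)
            for m in members
        ]
        return _EnsembleModel(specs).fit(X, y)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def evaluate_split(
    spec: ModelSpec,
    X: np.ndarray,
    y: Sequence,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> MetricsReport:
    """Stratified split, fit on train, full metric report on test."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    train_idx, test_idx = stratified_split(y, test_fraction=test_fraction, seed=seed)
    assert not set(train_idx) & set(test_idx), "train/test leak"
    model = train_model(spec, X[train_idx], y[train_idx])
    pred = model.predict(X[test_idx])
    cm = ConfusionMatrix.from_predictions(y[test_idx], pred, labels=np.unique(y))
    auc = None
    try:
        scores = model.predict_score(X[test_idx])
        auc = roc_auc(scores, y[test_idx], model.classes_)
    except (AttributeError, ValueError):
        pass
    return compute_metrics(cm, auc=auc)


# ---------------------------------------------------------------------------
# PCA classification and clustering

def pca_classify(
    X: np.ndarray,
    y: Sequence,
    n_components: int = 25,
    knn_k: int = 3,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> MetricsReport:
    """k-NN classification in a PCA-reduced feature space.

    Principal components are fit on the training split only; queries
    are projected before classification.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the feature dimension")
    train_idx, test_idx = stratified_split(y, test_fraction=test_fraction, seed=seed)
    pca = PCA(n_components=n_components, random_state=seed).fit(X[train_idx])
    Z_train, Z_test = pca.transform(X[train_idx]), pca.transform(X[test_idx])
    pred, votes, classes = knn_classify(Z_train, y[train_idx], Z_test, knn_k)
    cm = ConfusionMatrix.from_predictions(y[test_idx], pred, labels=np.unique(y))
    try:
        auc = roc_auc(votes, y[test_idx], classes)
    except ValueError:
        auc = None
    return compute_metrics(cm, auc=auc)


@dataclass(frozen=True)
class ClusterSurvey:
    """Per-k K-Means inertia (elbow curve) and mean silhouette score."""

    ks: tuple[int, ...]
    inertia: tuple[float, ...]
    silhouette: tuple[float, ...]

    def best_k_by_silhouette(self) -> int:
        return self.ks[int(np.argmax(self.silhouette))]


def kmeans_survey(
    X: np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
    n_init: int = 10,
) -> ClusterSurvey:
    """Seeded K-Means over a range of cluster counts (k >= 2)."""
    X = np.asarray(X, dtype=np.float64)
    ks, inertias, silhouettes = [], [], []
    for k in k_range:
        if not 2 <= k < len(X):
            raise ValueError(f"k={k} out of range for {len(X)} rows")
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(X)
        ks.append(int(k))
        inertias.append(float(km.inertia_))
        silhouettes.append(float(silhouette_score(X, km.labels_)))
    return ClusterSurvey(tuple(ks), tuple(inertias), tuple(silhouettes))
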