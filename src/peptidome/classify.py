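"""Forward-selection SVM signatures with cross-validation and validation.

The discriminant workflow: a stratified ~60/40 split into training and
independent validation subjects; greedy wrapper forward selection in which
every candidate feature is scored by the k-fold cross-validated accuracy
of a linear SVM on the training set (folds drawn once per run so all
candidates share them); the selected panel, capped at ``max_features``, is
refit on the full training set; performance on the held-out subjects is
summarized as a confusion matrix with sensitivity / specificity / PPV /
NPV and a ROC curve traced in decreasing-confidence order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ConfusionMatrix",
    "ValidationReport",
    "ClassifierModel",
    "split_train_validation",
    "forward_select_svm",
    "evaluate",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for a two-class decision (positive = case)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:  # % of true positives recovered
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:  # % of true negatives recovered
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:  # positive predictive value, %
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:  # negative predictive value, %
        return 100.0 * self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    def metrics(self, decimals: int = 2) -> dict:
        return {
            "sensitivity_pct": round(self.sensitivity, decimals),
            "specificity_pct": round(self.specificity, decimals),
            "ppv_pct": round(self.ppv, decimals),
            "npv_pct": round(self.npv, decimals),
        }


@dataclass
class ValidationReport:
    confusion: ConfusionMatrix
    roc_points: list  # (fpr, tpr) in decreasing-confidence order
    auc: float
    n_subjects: int

    def metrics(self, decimals: int = 2) -> dict:
        out = self.confusion.metrics(decimals)
        out["auc"] = round(self.auc, 3)
        out["n_subjects"] = self.n_subjects
        return out


@dataclass
class ClassifierModel:
    """Selected panel + trained linear decision rule + provenance."""

    selected_features: list
    positive_label: str
    coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    training_subjects: list
    cv_performance: list  # CV accuracy after each selection round
    svm_params: dict = field(default_factory=lambda: {"kernel": "linear", "C": 1.0})
    seed: int = 0

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from matrix: {missing}")
        Z = (X[self.selected_features].to_numpy(dtype=float) - self.scaler_mean) / self.scaler_scale
        return Z @ self.coef + self.intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.decision_values(X) > 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_features": list(self.selected_features),
                    "positive_label": self.positive_label,
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept,
                    "scaler_mean": self.scaler_mean.tolist(),
                    "scaler_scale": self.scaler_scale.tolist(),
                    "training_subjects": list(self.training_subjects),
                    "cv_performance": list(self.cv_performance),
                    "svm_params": self.svm_params,
                    "seed": self.seed,
                },
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("coef", "scaler_mean", "scaler_scale"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def split_train_validation(
    metadata: pd.DataFrame,
    train_fraction: float = 0.6,
    stratify_by: str = "group",
    seed: int = 0,
) -> tuple[list, list]:
    """Deterministic stratified split; per class, round(n * fraction) trains."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for _, ids in metadata.groupby(stratify_by, sort=True).groups.items():
        ids = list(ids)
        if len(ids) < 2:
            raise ValueError(f"class with {len(ids)} subject(s) cannot be split")
        order = rng.permutation(len(ids))
        n_train = int(round(len(ids) * train_fraction))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both sides non-empty
        train += [ids[i] for i in order[:n_train]]
        val += [ids[i] for i in order[n_train:]]
    return sorted(train), sorted(val)


def _feature_sort_key(label):
    try:
        return (0, float(label))
    except (TypeError, ValueError):
        return (1, str(label))


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds, C: float) -> float:
    correct = 0
    for tr, te in folds:
        mean, scale = _standardize_fit(X[tr])
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[tr] - mean) / scale, y[tr])
        correct += int((clf.predict((X[te] - mean) / scale) == y[te]).sum())
    return correct / y.size


def forward_select_svm(
    matrix: pd.DataFrame,
    labels: pd.Series,
    positive_label,
    k: int = 10,
    max_features: int = 20,
    C: float = 1.0,
    seed: int = 0,
) -> ClassifierModel:
    """Greedy wrapper selection scored by shared k-fold CV accuracy.

    Starting from the empty panel, each round scores every remaining
    candidate by the CV accuracy of a linear SVM (z-scored features) on
    the current panel plus that candidate, adds the best one, and stops
    when no candidate strictly improves the accuracy or the panel reaches
    ``max_features``.  Ties go to the lower nominal-m/z feature.  The final
    model is refit on the whole training set.
    """
    y = (labels == positive_label).to_numpy()
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"need >= k={k} subjects per class for stratified folding, "
            f"got {n_pos} positives / {n_neg} negatives"
        )
    Xall = matrix.to_numpy(dtype=float)
    features = sorted(matrix.columns, key=_feature_sort_key)
    col = {f: i for i, f in enumerate(matrix.columns)}
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(Xall, y))  # drawn once; all candidates share them

    selected: list = []
    cv_curve: list = []
    best_so_far = 0.0
    while len(selected) < max_features:
        best_feat, best_acc = None, best_so_far
        for f in features:
            if f in selected:
                continue
            cols = [col[g] for g in selected + [f]]
            acc = _cv_accuracy(Xall[:, cols], y, folds, C)
            if acc > best_acc:  # strict: ties keep the earlier (lower m/z)
                best_feat, best_acc = f, acc
        if best_feat is None:
            break
        selected.append(best_feat)
        best_so_far = best_acc
        cv_curve.append(best_acc)

    cols = [col[f] for f in selected]
    Xsel = Xall[:, cols]
    mean, scale = _standardize_fit(Xsel)
    clf = SVC(kernel="linear", C=C)
    clf.fit((Xsel - mean) / scale, y)
    return ClassifierModel(
        selected_features=selected,
        positive_label=str(positive_label),
        coef=np.asarray(clf.coef_).ravel(),
        intercept=float(clf.intercept_[0]),
        scaler_mean=mean,
        scaler_scale=scale,
        training_subjects=list(matrix.index),
        cv_performance=cv_curve,
        svm_params={"kernel": "linear", "C": C, "k_folds": k, "max_features": max_features},
        seed=seed,
    )


def cross_validated_report(
    matrix: pd.DataFrame,
    labels: pd.Series,
    features: list,
    positive_label,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> ValidationReport:
    """Pooled k-fold CV predictions on a fixed panel, as a ValidationReport.

    Used to report training-phase performance in the same confusion-matrix
    layout as the independent validation.
    """
    y = (labels.loc[matrix.index] == positive_label).to_numpy()
    X = matrix[list(features)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.zeros(y.size, dtype=bool)
    scores = np.zeros(y.size)
    for tr, te in skf.split(X, y):
        mean, scale = _standardize_fit(X[tr])
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[tr] - mean) / scale, y[tr])
        s = clf.decision_function((X[te] - mean) / scale)
        scores[te] = s
        pred[te] = s > 0
    cm = ConfusionMatrix(
        tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()), fn=int((~pred & y).sum()),
    )
    points, auc = roc_auc(scores, y)
    return ValidationReport(cm, points, auc, n_subjects=int(y.size))


def roc_auc(confidences, labels) -> tuple[list, float]:
    """ROC traced in decreasing-confidence order; AUC by trapezoid.

    ``labels`` are booleans (True = positive).  Tied confidences step
    diagonally in one move, which makes the trapezoidal AUC equal to the
    normalized Mann-Whitney U statistic.
    """
    conf = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-conf, kind="stable")
    conf, y = conf[order], y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < conf.size:
        j = i
        while j < conf.size and conf[j] == conf[i]:  # simultaneous tie step
            j += 1
        tp += int(y[i:j].sum())
        fp += int((~y[i:j]).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, auc


def evaluate(
    model: ClassifierModel, matrix: pd.DataFrame, labels: pd.Series
) -> ValidationReport:
    """Independent-set evaluation: confusion counts, metrics, ROC/AUC."""
    y = (labels.loc[matrix.index] == model.positive_label).to_numpy()
    scores = model.decision_values(matrix)
    pred = scores > 0
    cm = ConfusionMatrix(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )
    points, auc = roc_auc(scores, y)
    return ValidationReport(cm, points, auc, n_subjects=int(y.size))
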