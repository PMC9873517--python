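"""Connectome-based subject classification.

Features are the pairwise connection coefficients (strict upper triangle of
each subject's weighted connectivity matrix). Inside each leave-one-out
fold, features are standardized on the training subjects only, an
L1-penalized (LASSO) linear model at a fixed penalty screens the features,
and a linear support vector machine is trained on the surviving features to
score the held-out subject. Held-out decision scores pooled over folds give
the ROC and its AUC; held-out class predictions give accuracy, sensitivity
and specificity (the patient group is the positive class).

Feature selection and standardization live inside the fold to avoid
information leakage from the held-out subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .fc import ConnectivityMatrix

__all__ = ["FeatureMatrix", "ClassificationResult", "build_features",
           "lasso_select", "svm_loocv"]

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    x: np.ndarray                      # n_subjects x n_features
    feature_names: list[str]
    groups: np.ndarray                 # per-subject group labels

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.x.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.x.shape[1] != len(self.feature_names):
            raise ValueError("feature-name count mismatch")
        if self.x.shape[0] != self.groups.size:
            raise ValueError("group-label count mismatch")
        if np.any(~np.isfinite(self.x)):
            raise ValueError("features contain missing values")


@dataclass
class ClassificationResult:
    auc: float
    accuracy: float       # percent
    sensitivity: float    # percent
    specificity: float    # percent
    scores: np.ndarray    # pooled held-out decision scores
    predictions: np.ndarray
    truth: np.ndarray     # 1 = positive (patient) class
    selected_per_fold: list[np.ndarray] = field(default_factory=list)
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)


def build_features(
    cms: list[ConnectivityMatrix], groups
) -> FeatureMatrix:
    """Vectorize the strict upper triangle of each subject's matrix.

    Region-pair feature names are "labelA|labelB"; N regions yield
    N(N-1)/2 features per subject. All subjects must share region labels.
    """
    labels = cms[0].region_labels
    for cm in cms:
        if cm.region_labels != labels:
            raise ValueError("subjects have mismatched region labels")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    x = np.stack([cm.values[iu, ju] for cm in cms])
    names = [f"{labels[i]}|{labels[j]}" for i, j in zip(iu, ju)]
    return FeatureMatrix(x=x, feature_names=names, groups=np.asarray(groups))


def vector_to_matrix(vec: np.ndarray, labels: list[str]) -> np.ndarray:
    """Inverse of build_features for one subject (zero diagonal)."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    m = np.zeros((n, n))
    m[iu, ju] = vec
    return m + m.T


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def lasso_select(train_features: np.ndarray, train_labels: np.ndarray, lam: float = 0.05) -> np.ndarray:
    """Indices of features with nonzero LASSO coefficients.

    Fits an L1-penalized linear model of the 0/1 label on standardized
    features at penalty ``lam``. An empty selection is allowed (and logged
    by the caller).
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    x = np.asarray(train_features, dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    y = np.asarray(train_labels, dtype=float)
    model = Lasso(alpha=lam, max_iter=20_000)
    model.fit(xs, y)
    return np.flatnonzero(model.coef_ != 0)


def svm_loocv(
    features: FeatureMatrix,
    lam: float = 0.05,
    svm_c: float = 1.0,
    kernel: str = "linear",
    positive_label=None,
) -> ClassificationResult:
    """LASSO-screened linear-SVM classification with leave-one-out CV.

    One fold per subject: standardize on the training fold, select features
    with :func:`lasso_select` on the training fold, fit the SVM on the
    selected features and score the held-out subject. A fold whose
    selection is empty predicts the training majority class with a decision
    score equal to the (signed) training class-prior imbalance.
    """
    x, groups = features.x, features.groups
    n = x.shape[0]
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2:
        raise ValueError("need exactly two classes")
    if positive_label is None:
        positive_label = labels[1]
    y = (groups == positive_label).astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 subjects per class")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    selected: list[np.ndarray] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xtr, xte = _standardize(x[mask], x[i : i + 1])
        ytr = y[mask]
        sel = lasso_select(xtr, ytr, lam)
        selected.append(sel)
        if sel.size == 0:
            log.warning("fold %d: empty LASSO selection; predicting class prior", i)
            prior = ytr.mean()
            scores[i] = prior - 0.5
            preds[i] = int(prior >= 0.5)
            continue
        clf = SVC(kernel=kernel, C=svm_c)
        clf.fit(xtr[:, sel], ytr)
        scores[i] = float(clf.decision_function(xte[:, sel])[0])
        preds[i] = int(clf.predict(xte[:, sel])[0])
    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores)
    return ClassificationResult(
        auc=auc,
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        scores=scores,
        predictions=preds,
        truth=y,
        selected_per_fold=selected,
        roc=(fpr, tpr),
    )
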