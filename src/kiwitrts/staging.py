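"""Softening-stage classification from TRP difference spectra.

Pipeline: PCA on the (profiles x bins) matrix of day-0 difference spectra,
firmness-based three-class labels (class 1 = firmest), discriminative
selection of a few principal components, and a cross-validated support
vector machine.  Accuracy is reported as the pooled out-of-fold
trace/total of a single confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "PCAModel",
    "StagingReport",
    "fit_pca",
    "pca_scores",
    "assign_softening_classes",
    "class_thresholds",
    "select_components",
    "train_classify_svm",
]


@dataclass
class PCAModel:
    """Column-mean-centered principal component decomposition.

    ``loadings`` has one orthonormal row per component; scores of a row x
    are ``(x - mean_vector) @ loadings.T``.  Component signs are fixed so
    that each loading's largest-magnitude element is positive.
    """

    mean_vector: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


@dataclass
class StagingReport:
    """Cross-validated staging outcome: confusion matrix rows are predicted
    classes, columns are actual classes (class labels 1..n)."""

    class_thresholds: list
    selected_components: list
    confusion_matrix: np.ndarray
    fold_accuracies: list
    overall_accuracy: float
    folds: int = 5
    seed: int = 0
    extra: dict = field(default_factory=dict)


def fit_pca(matrix: np.ndarray, n_components: int | None = None) -> PCAModel:
    """PCA of a profiles-by-bins matrix: centered, no variance scaling."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    max_comp = min(X.shape)
    if n_components is not None and n_components > X.shape[0]:
        raise ValueError(
            f"requested {n_components} components from {X.shape[0]} rows"
        )
    model = PCA(n_components=n_components or max_comp, svd_solver="full")
    model.fit(X)
    loadings = model.components_.copy()
    # deterministic sign: largest-magnitude element of each loading positive
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(
        mean_vector=model.mean_.copy(),
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


def pca_scores(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Project rows onto the components: (X - mean) @ loadings.T."""
    X = np.asarray(matrix, dtype=float)
    return (X - model.mean_vector) @ model.loadings.T


def assign_softening_classes(firmness: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Rank-based equal-count classes; class 1 holds the firmest fruit.

    Ties are broken by stable input order.  All-equal firmness still yields
    deterministic labels but warns that the grouping is arbitrary.
    """
    f = np.asarray(firmness, dtype=float)
    if f.ndim != 1 or f.size < n_classes:
        raise ValueError(f"need at least {n_classes} samples")
    if np.all(f == f[0]):
        warnings.warn("all firmness values equal: class labels follow input order",
                      stacklevel=2)
    order = np.argsort(-f, kind="stable")
    labels = np.empty(f.size, dtype=int)
    for cls, chunk in enumerate(np.array_split(order, n_classes), start=1):
        labels[chunk] = cls
    return labels


def class_thresholds(firmness: np.ndarray, labels: np.ndarray) -> list:
    """Firmness cut values: the lowest firmness inside each class but the last."""
    f = np.asarray(firmness, dtype=float)
    cuts = []
    for cls in range(1, int(labels.max())):
        cuts.append(float(f[labels == cls].min()))
    return cuts


def select_components(
    pca: PCAModel,
    scores: np.ndarray,
    labels: np.ndarray,
    k: int = 3,
    n_candidates: int = 10,
    explicit: list | None = None,
) -> list:
    """Pick k discriminative components (0-based indices into the PCA).

    Default rule: among the first ``n_candidates`` components, rank by the
    ratio of between-class to within-class variance of the scores and keep
    the top ``k``.  An ``explicit`` index list short-circuits the rule and
    is honored verbatim.
    """
    if explicit is not None:
        return list(explicit)
    S = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_avail = min(n_candidates, S.shape[1])
    if k > n_avail:
        raise ValueError(f"k={k} exceeds available components {n_avail}")
    classes = np.unique(y)
    grand = S[:, :n_avail].mean(axis=0)
    between = np.zeros(n_avail)
    within = np.zeros(n_avail)
    for c in classes:
        block = S[y == c, :n_avail]
        between += block.shape[0] * (block.mean(axis=0) - grand) ** 2
        within += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(within <= 0):
        warnings.warn(
            "degenerate within-class variance: falling back to variance ordering",
            stacklevel=2,
        )
        ranked = np.argsort(-pca.explained_variance_ratio[:n_avail], kind="stable")
    else:
        ranked = np.argsort(-(between / within), kind="stable")
    return [int(i) for i in ranked[:k]]


def train_classify_svm(
    scores: np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    kernel: str = "linear",
    thresholds: list | None = None,
    selected_components: list | None = None,
) -> StagingReport:
    """Stratified k-fold SVM staging with pooled out-of-fold evaluation.

    Features are standardized inside each training fold.  Deterministic for
    a given seed.  The confusion matrix is indexed [predicted, actual].
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    counts = {c: int((y == c).sum()) for c in classes}
    for c, n in counts.items():
        if n < folds:
            raise ValueError(
                f"class {c} has only {n} samples; cannot stratify into "
                f"{folds} folds without losing it from training folds"
            )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n_classes = classes.size
    cm = np.zeros((n_classes, n_classes), dtype=int)
    fold_acc = []
    cls_index = {c: i for i, c in enumerate(classes)}
    for train_idx, test_idx in skf.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        clf = SVC(C=C, kernel=kernel)
        clf.fit(scaler.transform(X[train_idx]), y[train_idx])
        pred = clf.predict(scaler.transform(X[test_idx]))
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        for p, a in zip(pred, y[test_idx]):
            cm[cls_index[p], cls_index[a]] += 1

    overall = float(np.trace(cm) / cm.sum())
    return StagingReport(
        class_thresholds=list(thresholds) if thresholds is not None else [],
        selected_components=list(selected_components)
        if selected_components is not None
        else [],
        confusion_matrix=cm,
        fold_accuracies=fold_acc,
        overall_accuracy=overall,
        folds=folds,
        seed=seed,
    )
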