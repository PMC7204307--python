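"""Metastasis-stage classification from a gene signature.

The model restricts the normalized expression matrix to the signature
genes, standardizes each gene, projects samples onto the top two principal
components, and fits a Gaussian-kernel SVM on the 2-D scores.  Performance
is summarized by ROC/AUC, either by resubstitution or by stratified k-fold
cross-validation with all preprocessing learned inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .signatures import GeneSignature


class ClassifierError(ValueError):
    pass


@dataclass
class SignatureClassifier:
    """Fitted PCA+SVM classifier over a gene signature."""

    genes: Tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    pca: PCA
    svm: SVC
    seed: int
    threshold: float = 0.0


def _signature_matrix(
    expr: pd.DataFrame, genes: Sequence[str]
) -> Tuple[np.ndarray, Tuple[str, ...]]:
    present = [g for g in genes if g in expr.index]
    if len(present) < 2:
        raise ClassifierError("fewer than 2 usable signature genes in matrix")
    return expr.loc[present].to_numpy(dtype=float).T, tuple(present)


def _median_heuristic_gamma(x: np.ndarray) -> float:
    d = pdist(x)
    d = d[d > 0]
    if len(d) == 0:
        return 1.0
    med = float(np.median(d))
    return 1.0 / (2.0 * med * med)


def fit_pca_svm(
    expr: pd.DataFrame,
    signature: GeneSignature,
    labels: pd.Series,
    seed: int = 0,
    C: float = 1.0,
    gamma: Optional[float] = None,
) -> SignatureClassifier:
    """Standardize signature genes, project onto 2 PCs, fit an RBF SVM.

    ``labels`` is a binary per-sample series aligned with the matrix
    columns.  The kernel width defaults to the median heuristic on the
    training 2-D scores.  Deterministic given ``seed``.
    """
    y = np.asarray(labels.loc[expr.columns], dtype=int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ClassifierError("need exactly 2 classes in labels")
    if min(np.sum(y == c) for c in classes) < 4:
        raise ClassifierError("need at least 4 samples per class")

    x, present = _signature_matrix(expr, signature.genes)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    xs = (x - means) / sds

    pca = PCA(n_components=2, random_state=seed)
    scores2d = pca.fit_transform(xs)
    g = gamma if gamma is not None else _median_heuristic_gamma(scores2d)
    svm = SVC(kernel="rbf", C=C, gamma=g, random_state=seed)
    svm.fit(scores2d, y)
    return SignatureClassifier(present, means, sds, pca, svm, seed)


def predict_scores(model: SignatureClassifier, expr: pd.DataFrame) -> pd.Series:
    """Continuous decision values per sample; sign at the stored threshold
    gives the class.  Missing signature genes are imputed at the training
    mean."""
    rows = []
    n_missing = 0
    for i, g in enumerate(model.genes):
        if g in expr.index:
            rows.append(expr.loc[g].to_numpy(dtype=float))
        else:
            n_missing += 1
            rows.append(np.full(expr.shape[1], model.means[i]))
    if n_missing == len(model.genes):
        raise ClassifierError("all signature genes missing from matrix")
    x = np.asarray(rows).T
    xs = (x - model.means) / model.sds
    dec = model.svm.decision_function(model.pca.transform(xs))
    return pd.Series(dec, index=expr.columns, name="decision_value")


@dataclass(frozen=True)
class RocResult:
    """ROC points (FPR, TPR, ordered by threshold) and trapezoidal AUC."""

    points: pd.DataFrame
    auc: float
    scheme: str = "resubstitution"


def roc_auc(scores, labels, scheme: str = "resubstitution") -> RocResult:
    """ROC curve by threshold sweep; AUC by trapezoid (ties half-credit,
    equal to the Mann-Whitney rank statistic)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ClassifierError("labels must be binary 0/1")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ClassifierError("both classes must be present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # one ROC point per distinct threshold (last index of each tie block)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(points, auc, scheme)


def cross_validated_scores(
    expr: pd.DataFrame,
    signature: GeneSignature,
    labels: pd.Series,
    n_splits: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> pd.Series:
    """Out-of-fold decision values from stratified k-fold CV.

    Preprocessing (standardization, PCA, kernel width) is learned on each
    training fold only.
    """
    y = labels.loc[expr.columns]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    out = pd.Series(np.nan, index=expr.columns, name="decision_value")
    cols = np.asarray(expr.columns)
    for train_idx, test_idx in skf.split(cols, y.to_numpy()):
        train_cols, test_cols = cols[train_idx], cols[test_idx]
        model = fit_pca_svm(expr[train_cols], signature, y, seed=seed, C=C)
        out.loc[test_cols] = predict_scores(model, expr[test_cols])
    return out


def cross_validated_auc(
    expr: pd.DataFrame,
    signature: GeneSignature,
    labels: pd.Series,
    n_splits: int = 5,
    seed: int = 0,
) -> RocResult:
    """AUC of pooled out-of-fold decision values."""
    scores = cross_validated_scores(expr, signature, labels, n_splits, seed)
    y = labels.loc[expr.columns]
    # orient decision values so class 1 is the positive direction
    result = roc_auc(scores.to_numpy(), y.to_numpy(), scheme=f"{n_splits}-fold")
    return result
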