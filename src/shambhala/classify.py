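"""Transfer-learning tissue-type classifiers over harmonized profiles.

A classifier is trained on one harmonized dataset and validated on another
(typically another platform): first-nearest-neighbour (1nn) and 11-nearest-
neighbour (11nn) votes in the Euclidean space of per-gene log expression,
and a linear SVM over 20 principal components fitted on the training set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .datamodel import ExpressionMatrix

METHODS = ("knn1", "knn11", "svm_pca20")


@dataclasses.dataclass
class AccuracyReport:
    method: str
    per_class_accuracy: dict[str, float]
    total_accuracy: float
    n_train: dict[str, int]
    n_val: dict[str, int]
    predictions: list[str]


def _knn_predict(train: np.ndarray, train_labels: np.ndarray, val: np.ndarray, k: int) -> np.ndarray:
    """kNN with deterministic ties: distance ties go to the smallest training
    index (stable argsort); vote ties go to the nearest neighbour's class."""
    D = cdist(val, train, metric="euclidean")
    out = np.empty(len(val), dtype=object)
    for i in range(len(val)):
        order = np.argsort(D[i], kind="stable")[:k]
        neigh = train_labels[order]
        classes, counts = np.unique(neigh, return_counts=True)
        best = counts.max()
        tied = set(classes[counts == best])
        if len(tied) == 1:
            out[i] = tied.pop()
        else:
            out[i] = next(c for c in neigh if c in tied)  # nearest among tied classes
    return out


def pca_project(train: ExpressionMatrix, val: ExpressionMatrix, n_components: int = 20,
                pooled: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component features; loadings fitted on the training set only
    (``pooled=True`` fits on the concatenated set instead)."""
    if not train.gene_ids.equals(val.gene_ids):
        raise ValueError("train and val must share an identical gene list")
    Xt = train.values.T
    Xv = val.values.T
    if n_components > min(Xt.shape[0] - 1, Xt.shape[1]):
        raise ValueError(f"n_components={n_components} exceeds min(n_train-1, n_genes)")
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    if pooled:
        pca.fit(np.vstack([Xt, Xv]))
        return pca.transform(Xt), pca.transform(Xv)
    feat_t = pca.fit_transform(Xt)
    return feat_t, pca.transform(Xv)


def transfer_accuracy(train: ExpressionMatrix, train_labels: np.ndarray | list,
                      val: ExpressionMatrix, val_labels: np.ndarray | list,
                      method: str = "knn1", seed: int = 0) -> AccuracyReport:
    """Train on one dataset, report per-class and total accuracy on another."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if not train.gene_ids.equals(val.gene_ids):
        raise ValueError("train and val must share an identical gene list")
    y_train = np.asarray(train_labels)
    y_val = np.asarray(val_labels)
    if len(y_train) != train.n_samples or len(y_val) != val.n_samples:
        raise ValueError("one label per sample required")
    missing = sorted(set(y_val) - set(y_train))
    if missing:
        raise ValueError(f"validation class(es) absent from training: {missing}")
    if method == "knn1":
        pred = _knn_predict(train.values.T, y_train, val.values.T, k=1)
    elif method == "knn11":
        pred = _knn_predict(train.values.T, y_train, val.values.T, k=min(11, train.n_samples))
    else:
        if train.n_samples < 21:
            raise ValueError("svm_pca20 needs >= 21 training samples")
        feat_t, feat_v = pca_project(train, val, n_components=20)
        clf = SVC(kernel="linear", C=1.0, decision_function_shape="ovo", random_state=seed)
        clf.fit(feat_t, y_train)
        pred = clf.predict(feat_v)
    per_class = {}
    n_val = {}
    for cls in np.unique(y_val):
        mask = y_val == cls
        per_class[str(cls)] = float(np.mean(pred[mask] == cls))
        n_val[str(cls)] = int(mask.sum())
    total = float(np.mean(pred == y_val))
    n_train = {str(c): int((y_train == c).sum()) for c in np.unique(y_train)}
    return AccuracyReport(method=method, per_class_accuracy=per_class, total_accuracy=total,
                          n_train=n_train, n_val=n_val, predictions=[str(p) for p in pred])
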