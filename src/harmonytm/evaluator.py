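"""Task metrics, scanner-leakage metrics, and the representation audit.

Disease metrics are the standard binary set (accuracy at threshold 0.5,
AUROC, sensitivity, specificity, precision, F1).  Scanner metrics are
computed one-vs-rest per class and averaged with weights proportional to
class support, alongside an M x M confusion matrix whose rows are actual and
columns predicted scanner types.

The representation audit projects encoder features onto their first two
principal components and fits logistic-regression probes — on mode 1 alone,
mode 2 alone, and both — for the scanner labels and the disease labels.
Probes are fit on a seeded 80/20 stratified split and scored on the held-out
20%, avoiding the trivially optimistic in-sample separability estimate.
A full-feature logistic probe (all encoder features) is also reported as the
primary leakage measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "EvalReport",
    "binary_metrics",
    "multiclass_weighted_metrics",
    "feature_probe_accuracy",
    "pca_probe",
]


def binary_metrics(y, p, threshold: float = 0.5) -> dict:
    """Binary disease metrics from probabilities.

    AUROC is threshold-free and requires both classes; everything else is
    computed from the 0.5-threshold (configurable) hard decision.
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if len(y) != len(p):
        raise ValueError("length mismatch")
    if y.min() == y.max():
        raise ValueError("AUROC undefined: only one class present")
    yhat = (p >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return dict(
        accuracy=float((tp + tn) / len(y)),
        auroc=float(roc_auc_score(y, p)),
        sensitivity=float(sens),
        specificity=float(spec),
        precision=float(prec),
        f1=float(f1),
    )


def multiclass_weighted_metrics(y, P, n_classes: int | None = None):
    """Support-weighted one-vs-rest scanner metrics plus the confusion matrix.

    ``P`` may be an (N, M) probability/score matrix (argmax decision rule)
    or a vector of predicted class ids.  Returns ``(metrics, confusion)``
    with confusion rows = actual, columns = predicted.
    """
    y = np.asarray(y, dtype=int)
    P = np.asarray(P)
    yhat = P.argmax(axis=1) if P.ndim == 2 else P.astype(int)
    m = n_classes if n_classes is not None else (P.shape[1] if P.ndim == 2
                                                 else int(max(y.max(), yhat.max())) + 1)
    if y.min() < 0 or y.max() >= m:
        raise ValueError("label outside the scanner label space")
    conf = confusion_matrix(y, yhat, labels=np.arange(m))
    n = len(y)
    support = conf.sum(axis=1)
    weights = support / n
    sens = np.zeros(m)
    spec = np.zeros(m)
    prec = np.zeros(m)
    f1 = np.zeros(m)
    for k in range(m):
        tp = conf[k, k]
        fn = support[k] - tp
        fp = conf[:, k].sum() - tp
        tn = n - tp - fn - fp
        sens[k] = tp / (tp + fn) if tp + fn else 0.0
        spec[k] = tn / (tn + fp) if tn + fp else 0.0
        prec[k] = tp / (tp + fp) if tp + fp else 0.0
        f1[k] = (2 * prec[k] * sens[k] / (prec[k] + sens[k])
                 if prec[k] + sens[k] else 0.0)
    metrics = dict(
        accuracy=float(np.trace(conf) / n),
        sensitivity=float(np.sum(weights * sens)),
        specificity=float(np.sum(weights * spec)),
        precision=float(np.sum(weights * prec)),
        f1=float(np.sum(weights * f1)),
    )
    return metrics, conf


def _probe(train_x, train_y, test_x, test_y) -> float:
    clf = LogisticRegression(C=1.0, max_iter=2000)
    clf.fit(train_x, train_y)
    return float(clf.score(test_x, test_y))


def feature_probe_accuracy(features_train, labels_train, features_test,
                           labels_test) -> float:
    """Held-out accuracy of a ridge-regularised logistic probe on features."""
    if len(set(np.asarray(labels_train).tolist())) < 2:
        raise ValueError("probe needs at least two classes in training labels")
    return _probe(np.asarray(features_train), np.asarray(labels_train),
                  np.asarray(features_test), np.asarray(labels_test))


def pca_probe(features, labels_scanner, labels_disease, seed: int = 0,
              test_size: float = 0.2):
    """First two PCA modes of the features plus per-mode probe accuracies.

    Features are centred (and constant columns dropped) before the PCA.
    Returns ``(coords, probe_acc)`` where ``coords`` is the n x 2 score
    matrix and ``probe_acc`` maps ``(label_set, mode_key)`` to held-out
    logistic accuracy, with ``mode_key`` in {"mode1", "mode2", "both"}.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] <= 2 or X.shape[1] < 2:
        raise ValueError("need an n x F feature matrix with n > 2, F >= 2")
    keep = X.std(axis=0) > 0
    labels = {"scanner": np.asarray(labels_scanner),
              "disease": np.asarray(labels_disease)}
    if keep.sum() == 0:
        # fully collapsed representation: no variance to project, and the
        # best any probe can do is predict the majority class
        coords = np.zeros((len(X), 2))
        probe_acc = {}
        for name, lab in labels.items():
            majority = np.bincount(lab.astype(int)).max() / len(lab)
            for mode_key in ("mode1", "mode2", "both"):
                probe_acc[(name, mode_key)] = float(majority)
        return coords, probe_acc
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    rank = min(2, keep.sum())
    coords = PCA(n_components=rank, random_state=0).fit_transform(Xc)
    if rank < 2:  # degenerate features: mode 2 carries no variance
        coords = np.hstack([coords, np.zeros((len(coords), 1))])
    modes = {"mode1": coords[:, [0]], "mode2": coords[:, [1]], "both": coords}
    probe_acc = {}
    for name, lab in labels.items():
        strat = lab if np.min(np.bincount(lab.astype(int))) >= 2 else None
        idx_tr, idx_te = train_test_split(np.arange(len(lab)),
                                          test_size=test_size,
                                          random_state=seed, stratify=strat)
        for mode_key, Z in modes.items():
            probe_acc[(name, mode_key)] = _probe(Z[idx_tr], lab[idx_tr],
                                                 Z[idx_te], lab[idx_te])
    return coords, probe_acc


@dataclass
class EvalReport:
    """Bundle of everything one evaluation produces (JSON/CSV serialisable)."""

    disease_metrics: dict
    scanner_metrics: dict
    confusion: np.ndarray
    pca_coords: np.ndarray
    probe_acc: dict                      # (label_set, mode) -> accuracy
    scanner_probe_accuracy: float = None  # full-feature probe
    disease_probe_accuracy: float = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(
            disease_metrics=self.disease_metrics,
            scanner_metrics=self.scanner_metrics,
            confusion=np.asarray(self.confusion).tolist(),
            probe_acc={f"{a}/{b}": v for (a, b), v in self.probe_acc.items()},
            scanner_probe_accuracy=self.scanner_probe_accuracy,
            disease_probe_accuracy=self.disease_probe_accuracy,
            extras=self.extras,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        m = len(self.confusion)
        idx = [f"actual_{i}" for i in range(m)]
        cols = [f"predicted_{i}" for i in range(m)]
        return pd.DataFrame(self.confusion, index=idx, columns=cols)

    def pca_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pca_coords, columns=["mode1", "mode2"])
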