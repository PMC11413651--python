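"""Adversarial scanner-unlearning: losses and the three-step batch procedure.

Per batch (always drawn from a single center in traveling-model mode) three
sequential sub-updates are applied:

1. optimize encoder + disease head on the binary cross-entropy of the
   disease prediction;
2. optimize the scanner head on the categorical cross-entropy of the
   scanner prediction, with the encoder frozen;
3. optimize the encoder on the *confusion loss* — the cross-entropy between
   the scanner head's softmax output and the uniform distribution over the
   M scanner types — pushing the scanner head toward chance level and
   thereby scrubbing scanner information out of the feature representation.

The three losses plus their sum are returned for logging.  Batch size N is
whatever the visited center can supply (N <= 5 in the traveling schedule),
and no oversampling of scanner classes is performed: each update uses the
batch exactly as the center provides it.

Before harmonization the network is pre-trained in two phases: encoder +
disease head on the task alone, then the scanner head on frozen features.

All probabilities inside logarithms are clipped at ``EPS = 1e-7``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .model_zoo import (ModelBundle, forward_features, predict_disease,
                        predict_scanner)

EPS = 1e-7

__all__ = [
    "EPS",
    "Batch",
    "LossRecord",
    "loss_pd",
    "loss_scanner",
    "loss_confusion",
    "loss_total",
    "one_hot",
    "make_optimizers",
    "task_step",
    "disease_head_step",
    "scanner_step",
    "confusion_step",
    "harmonization_step",
    "pretrain",
]


@dataclass
class Batch:
    """N samples from a single center with both label sets."""

    volumes: np.ndarray      # (N, D, H, W)
    y_disease: np.ndarray    # (N,) in {0, 1}
    y_scanner: np.ndarray    # (N, M) one-hot
    center_id: str | None = None

    def __post_init__(self):
        n = len(self.volumes)
        if n < 1:
            raise ValueError("batch must contain at least one sample")
        if len(self.y_disease) != n or len(self.y_scanner) != n:
            raise ValueError("label arrays must match batch size")
        rowsum = np.asarray(self.y_scanner).sum(axis=1)
        if not np.allclose(rowsum, 1.0):
            raise ValueError("y_scanner rows must be one-hot")

    @property
    def n(self) -> int:
        return len(self.volumes)


@dataclass
class LossRecord:
    """The three per-batch losses and their sum (the logged total)."""

    l_pd: float
    l_sc: float
    l_conf: float
    l_total: float

    @classmethod
    def of(cls, l_pd: float, l_sc: float, l_conf: float) -> "LossRecord":
        return cls(l_pd, l_sc, l_conf, loss_total(l_pd, l_sc, l_conf))


def one_hot(ids: np.ndarray, m: int) -> np.ndarray:
    ids = np.asarray(ids, dtype=np.int64)
    if ids.min() < 0 or ids.max() >= m:
        raise ValueError("class id outside label space")
    out = np.zeros((len(ids), m))
    out[np.arange(len(ids)), ids] = 1.0
    return out


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def loss_pd(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binary cross-entropy of the disease prediction."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if len(y) == 0:
        raise ValueError("empty batch")
    if y.shape != p.shape:
        raise ValueError("label/prediction length mismatch")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def loss_scanner(Y: np.ndarray, P: np.ndarray) -> float:
    """Mean categorical cross-entropy of the scanner prediction."""
    Y = np.asarray(Y, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if Y.shape != P.shape:
        raise ValueError("one-hot and prediction shapes must match")
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("expected a nonempty N x M batch")
    return float(-np.mean(np.sum(Y * np.log(np.clip(P, EPS, 1.0)), axis=1)))


def loss_confusion(P: np.ndarray) -> float:
    """Cross-entropy of the scanner softmax against the uniform distribution.

    Equal to ``ln M`` exactly when every row is uniform, strictly larger
    otherwise; driving it down pushes the scanner head to chance level.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] == 0:
        raise ValueError("expected a nonempty N x M matrix")
    n, m = P.shape
    return float(-np.sum(np.log(np.clip(P, EPS, 1.0))) / (n * m))


def loss_total(l_pd: float, l_sc: float, l_conf: float) -> float:
    """Sum of the three losses (logged diagnostic)."""
    return float(l_pd) + float(l_sc) + float(l_conf)


# --------------------------------------------------------------------------
# per-batch updates
# --------------------------------------------------------------------------

def make_optimizers(lr_task: float, lr_scanner: float | None = None,
                    lr_confusion: float | None = None) -> dict:
    """Three independent Adam states for the three sub-updates."""
    return {
        "task": nn.Adam(lr=lr_task),
        "scanner": nn.Adam(lr=lr_task if lr_scanner is None else lr_scanner),
        "confusion": nn.Adam(lr=lr_task if lr_confusion is None else lr_confusion),
    }


def task_step(bundle: ModelBundle, volumes, y, optimizer: nn.Adam,
              inference_stats: bool = False) -> float:
    """Update encoder + disease head on the disease objective.

    ``inference_stats=True`` keeps batch-norm statistics frozen (and
    dropout off) while still updating the weights — used during the
    adversarial phase so all three sub-updates act on one consistent,
    stationary representation.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    feats = forward_features(bundle, volumes, train=not inference_stats)
    p = predict_disease(bundle, feats)
    value = loss_pd(y, p)
    dlogit = ((np.clip(p, EPS, 1 - EPS) - y) / n)[:, None]
    dfeat = bundle.disease_head.backward(dlogit)
    bundle.encoder.backward(dfeat.astype(feats.dtype))
    params = {**bundle.encoder_params(), **bundle.disease_params()}
    grads = {**bundle.encoder_grads(), **bundle.disease_grads()}
    if optimizer.step(params, grads):
        bundle.encoder.commit_bn()
    return value


def disease_head_step(bundle: ModelBundle, volumes, y,
                      optimizer: nn.Adam) -> float:
    """Update the disease head only, on frozen (eval-mode) encoder features.

    The head-only analogue of :func:`scanner_step`: used to bring the
    disease head to convergence on a fixed representation before it is
    evaluated, so that threshold-based metrics reflect the representation
    rather than whichever centers the traveling model visited last.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    feats = forward_features(bundle, volumes, train=False)
    p = predict_disease(bundle, feats)
    value = loss_pd(y, p)
    dlogit = ((np.clip(p, EPS, 1 - EPS) - y) / n)[:, None]
    bundle.disease_head.backward(dlogit)
    optimizer.step(bundle.disease_params(), bundle.disease_grads())
    return value


def scanner_step(bundle: ModelBundle, volumes, y_scanner: np.ndarray,
                 optimizer: nn.Adam) -> float:
    """Update the scanner head on frozen (eval-mode) encoder features."""
    Y = np.asarray(y_scanner, dtype=np.float64)
    n = Y.shape[0]
    feats = forward_features(bundle, volumes, train=False)
    P = predict_scanner(bundle, feats)
    value = loss_scanner(Y, P)
    dlogit = (P - Y) / n
    bundle.scanner_head.backward(dlogit)
    optimizer.step(bundle.scanner_params(), bundle.scanner_grads())
    return value


def confusion_step(bundle: ModelBundle, volumes, optimizer: nn.Adam,
                   inference_stats: bool = True) -> float:
    """Update the encoder only, pushing the scanner softmax toward uniform.

    By default the forward pass uses inference-time statistics (running
    batch norm, no dropout): with single-center batches of at most five
    samples, per-batch statistics differ so much from the running ones that
    unlearning on batch-normalised features would leave the evaluation-time
    representation — the one any probe or downstream user sees — largely
    un-harmonized.  The adversary (step 2) is trained on the same
    inference-time features, keeping the game consistent.
    """
    feats = forward_features(bundle, volumes, train=not inference_stats)
    P = predict_scanner(bundle, feats)
    value = loss_confusion(P)
    n, m = P.shape
    dlogit = (P - 1.0 / m) / n
    dfeat = bundle.scanner_head.backward(dlogit)  # head grads are discarded
    bundle.encoder.backward(dfeat.astype(feats.dtype))
    if optimizer.step(bundle.encoder_params(), bundle.encoder_grads()):
        bundle.encoder.commit_bn()
    return value


def harmonization_step(batch: Batch, bundle: ModelBundle, optimizers: dict,
                       combined: bool = False,
                       inference_stats: bool = False) -> LossRecord:
    """One harmonization pass over a single-center batch.

    With ``combined=False`` (default) the three sub-updates run sequentially
    with their own optimizers; parameter groups outside each sub-update are
    untouched bit-for-bit.  With ``combined=True`` the encoder receives one
    update driven by the summed disease + confusion gradient (the total-loss
    reading) after the scanner-head update.

    ``inference_stats=True`` runs the encoder forwards of steps 1 and 3 on
    frozen (running) batch-norm statistics instead of per-batch ones.  That
    aligns the unlearning with the inference-time representation and scrubs
    residual probe-decodable scanner information harder, but the amplified
    gradients through low-variance normalisation layers can destabilise the
    disease task on small cohorts; the default keeps the classic training
    forward.
    """
    if batch.n == 0:
        raise ValueError("empty batch")
    if not combined:
        l1 = task_step(bundle, batch.volumes, batch.y_disease,
                       optimizers["task"], inference_stats=inference_stats)
        l2 = scanner_step(bundle, batch.volumes, batch.y_scanner,
                          optimizers["scanner"])
        l3 = confusion_step(bundle, batch.volumes, optimizers["confusion"],
                            inference_stats=inference_stats)
        return LossRecord.of(l1, l2, l3)

    # combined encoder update: one forward, summed feature gradient
    y = np.asarray(batch.y_disease, dtype=np.float64)
    n = batch.n
    feats = forward_features(bundle, batch.volumes, train=not inference_stats)
    p = predict_disease(bundle, feats)
    P = predict_scanner(bundle, feats)
    l1 = loss_pd(y, p)
    l3 = loss_confusion(P)
    dlog_d = ((np.clip(p, EPS, 1 - EPS) - y) / n)[:, None]
    dfeat = bundle.disease_head.backward(dlog_d)
    m = P.shape[1]
    dfeat = dfeat + bundle.scanner_head.backward((P - 1.0 / m) / n)
    bundle.encoder.backward(dfeat.astype(feats.dtype))
    params = {**bundle.encoder_params(), **bundle.disease_params()}
    grads = {**bundle.encoder_grads(), **bundle.disease_grads()}
    if optimizers["task"].step(params, grads):
        bundle.encoder.commit_bn()
    l2 = scanner_step(bundle, batch.volumes, batch.y_scanner, optimizers["scanner"])
    return LossRecord.of(l1, l2, l3)


# --------------------------------------------------------------------------
# two-phase pre-training
# --------------------------------------------------------------------------

def pretrain(shards, bundle: ModelBundle, tm_config,
             phase_a_cycles: int | None = None,
             phase_b_cycles: int | None = None,
             patience: int | None = None):
    """Pre-train with the traveling schedule: task first, then scanner head.

    Phase A updates encoder + disease head only; phase B freezes the encoder
    (bit-identical before/after) and trains the scanner head on its features,
    also following the traveling schedule.  "Until convergence" is realised
    as a fixed cycle budget with optional early stopping when the mean cycle
    loss stops improving for ``patience`` cycles.

    Returns ``(bundle, history)`` with one history row per (phase, cycle,
    center) visit.
    """
    from .tm_trainer import run_tm  # local import: tm_trainer uses the steps above

    if len(shards) == 0:
        raise ValueError("empty cohort")
    bundle, hist_a = run_tm(shards, bundle, tm_config, mode="task_only",
                            n_cycles=phase_a_cycles, patience=patience)
    hist_a = hist_a.assign(phase="task_pretrain")
    bundle, hist_b = run_tm(shards, bundle, tm_config, mode="scanner_only",
                            n_cycles=phase_b_cycles, patience=patience)
    hist_b = hist_b.assign(phase="scanner_pretrain")
    import pandas as pd

    return bundle, pd.concat([hist_a, hist_b], ignore_index=True)
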