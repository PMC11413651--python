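"""Centralized baseline: same architecture and losses, pooled data.

The pooled cohort is shuffled every epoch into batches of five (a shorter
final batch takes the remainder), so — unlike the traveling model — a batch
may mix samples from several centers and scanners.  The harmonization
adaptations (batch-size-aware loss normalisation and no scanner
oversampling) are kept identical; the code path for all loss computations
and per-batch updates is literally shared with the traveling-model trainer.
The initial learning rate defaults to 1e-3, ten times the traveling-model
rate, matching how the two regimes are conventionally tuned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonizer import (Batch, disease_head_step, harmonization_step,
                         make_optimizers, one_hot, scanner_step, task_step)
from .model_zoo import ModelBundle
from .synth_cohort import pooled_samples
from .tm_trainer import _colmean

__all__ = ["CentralConfig", "run_centralized"]


@dataclass(frozen=True)
class CentralConfig:
    """Centralized-training hyperparameters.

    The epoch budget should be chosen so the gradient-step count roughly
    matches the traveling-model budget it is compared against (one pooled
    epoch of batches of five is about one traveling cycle).
    """

    n_epochs: int = 30
    batch_size: int = 5
    lr_initial: float = 1e-3
    lr_decay: float = 0.95
    lr_scanner_scale: float = 30.0
    lr_scanner_pretrain_scale: float = 10.0
    lr_confusion_scale: float = 3.0
    seed: int = 0
    combined_encoder_update: bool = False


def run_centralized(shards, bundle: ModelBundle, config: CentralConfig,
                    mode: str = "task_only", optimizers: dict | None = None,
                    n_epochs: int | None = None):
    """Train on the pooled cohort; returns ``(bundle, history)``.

    ``mode`` accepts the same three values as the traveling loop.  History
    has one row per epoch with mean batch losses and the number of batches
    that mixed two or more centers.
    """
    shards = list(shards)
    if len(shards) == 0 or sum(len(s) for s in shards) == 0:
        raise ValueError("empty pool")
    if mode not in ("task_only", "harmonize", "scanner_only", "disease_only"):
        raise ValueError(f"unknown mode {mode!r}")
    vols, y, sc, centers = pooled_samples(shards)
    m = bundle.label_space.M
    n = len(y)
    if optimizers is None:
        optimizers = make_optimizers(config.lr_initial)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 31]))
    rows = []
    total = config.n_epochs if n_epochs is None else int(n_epochs)
    scanner_scale = (config.lr_scanner_pretrain_scale
                     if mode == "scanner_only" else config.lr_scanner_scale)
    task_scale = (config.lr_scanner_pretrain_scale
                  if mode == "disease_only" else 1.0)
    for epoch in range(total):
        lr = config.lr_initial * config.lr_decay ** epoch
        optimizers["task"].lr = lr * task_scale
        optimizers["scanner"].lr = lr * scanner_scale
        optimizers["confusion"].lr = lr * config.lr_confusion_scale
        order = rng.permutation(n)
        losses, n_mixed = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = Batch(volumes=vols[idx], y_disease=y[idx],
                          y_scanner=one_hot(sc[idx], m))
            if len(set(centers[idx])) > 1:
                n_mixed += 1
            if mode == "task_only":
                l1 = task_step(bundle, batch.volumes, batch.y_disease,
                               optimizers["task"])
                losses.append((l1, np.nan, np.nan, np.nan))
            elif mode == "disease_only":
                l1 = disease_head_step(bundle, batch.volumes,
                                       batch.y_disease, optimizers["task"])
                losses.append((l1, np.nan, np.nan, np.nan))
            elif mode == "scanner_only":
                l2 = scanner_step(bundle, batch.volumes, batch.y_scanner,
                                  optimizers["scanner"])
                losses.append((np.nan, l2, np.nan, np.nan))
            else:
                rec = harmonization_step(batch, bundle, optimizers,
                                         combined=config.combined_encoder_update)
                losses.append((rec.l_pd, rec.l_sc, rec.l_conf, rec.l_total))
        arr = np.asarray(losses, dtype=float)
        rows.append(dict(epoch=epoch, n_batches=len(arr), n_mixed_batches=n_mixed,
                         l_pd=_colmean(arr, 0), l_sc=_colmean(arr, 1),
                         l_conf=_colmean(arr, 2), l_total=_colmean(arr, 3)))
    return bundle, pd.DataFrame(rows)
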