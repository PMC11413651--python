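"""The traveling-model loop.

One model is trained sequentially: each cycle draws a fresh random
permutation of the centers (cycle-to-cycle variability playing the role of
batch shuffling), visits each center exactly once, and runs a single epoch
over that center's local data in batches of at most five samples — smaller
centers simply contribute one smaller batch.  Every batch therefore
originates from a single center, the structural property that makes the
traveling model comparatively resistant to cross-center shortcut learning.

The Adam optimizer state travels with the model between centers by default
(the model object is what travels); the learning rate decays exponentially
per cycle from its initial value (default 1e-4, decay 0.95/cycle — the
decay rate is a package default, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonizer import (Batch, disease_head_step, harmonization_step,
                         make_optimizers, one_hot, scanner_step, task_step)
from .model_zoo import ModelBundle

__all__ = [
    "TravelSchedule",
    "TMConfig",
    "make_schedule",
    "batch_plan",
    "lr_at",
    "run_tm",
]


@dataclass(frozen=True)
class TravelSchedule:
    """Center visiting order for one cycle."""

    cycle_index: int
    center_order: tuple
    seed: int


@dataclass(frozen=True)
class TMConfig:
    """Traveling-model training hyperparameters."""

    n_cycles: int = 30
    max_batch: int = 5
    lr_initial: float = 1e-4
    lr_decay: float = 0.95
    # the adversary head is a single dense layer trained online on tiny
    # batches; during the adversarial cycles it needs a much larger rate
    # than the encoder to stay competitive, while its convergence
    # pre-training (phase B) tolerates only a moderate boost
    lr_scanner_scale: float = 30.0
    lr_scanner_pretrain_scale: float = 10.0
    lr_confusion_scale: float = 3.0
    seed: int = 0
    reset_optimizers_per_center: bool = False
    combined_encoder_update: bool = False

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.max_batch < 1:
            raise ValueError("max_batch must be >= 1")


def make_schedule(center_ids, cycle_index: int, seed: int) -> TravelSchedule:
    """Deterministic permutation of the centers for one cycle."""
    center_ids = list(center_ids)
    if len(center_ids) == 0:
        raise ValueError("no centers to schedule")
    if len(set(center_ids)) != len(center_ids):
        raise ValueError("duplicate center ids")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed),
                                                        int(cycle_index), 101]))
    order = tuple(center_ids[i] for i in rng.permutation(len(center_ids)))
    return TravelSchedule(cycle_index=int(cycle_index), center_order=order,
                          seed=int(seed))


def batch_plan(shard_size: int, max_batch: int = 5) -> list:
    """Batch sizes for one local epoch: full batches plus one remainder."""
    if shard_size < 1:
        raise ValueError("shard_size must be >= 1")
    if max_batch < 1:
        raise ValueError("max_batch must be >= 1")
    q, r = divmod(int(shard_size), int(max_batch))
    return [max_batch] * q + ([r] if r else [])


def lr_at(cycle_index: int, config: TMConfig) -> float:
    """Exponentially decayed learning rate for a given cycle."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if config.lr_decay <= 0:
        raise ValueError("lr_decay must be positive")
    return config.lr_initial * config.lr_decay ** cycle_index


def _center_batches(shard, cycle: int, center_idx: int, config: TMConfig, m: int):
    """Seeded within-center shuffle, then the batch plan."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed), int(cycle), int(center_idx), 13]))
    order = rng.permutation(len(shard))
    start = 0
    for size in batch_plan(len(shard), config.max_batch):
        idx = order[start:start + size]
        start += size
        yield Batch(volumes=shard.volumes[idx],
                    y_disease=shard.disease_labels[idx],
                    y_scanner=one_hot(shard.scanner_labels[idx], m),
                    center_id=shard.center_id)


def _colmean(arr: np.ndarray, col: int) -> float:
    if len(arr) == 0:
        return float("nan")
    vals = arr[:, col]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def run_tm(shards, bundle: ModelBundle, tm_config: TMConfig,
           mode: str = "task_only", optimizers: dict | None = None,
           n_cycles: int | None = None, patience: int | None = None,
           callback=None):
    """Run the traveling-model loop.

    Parameters
    ----------
    mode
        ``task_only`` applies the disease objective per batch;
        ``harmonize`` applies the three-step adversarial procedure;
        ``scanner_only`` trains the scanner head on the frozen encoder
        (used for pre-training phase B).
    optimizers
        Three named Adam states; fresh ones are created when omitted.
        State travels with the model across centers and cycles unless
        ``tm_config.reset_optimizers_per_center`` is set.
    n_cycles
        Override of ``tm_config.n_cycles`` (e.g. separate pre-training and
        harmonization budgets sharing one config).
    patience
        Stop early when the mean cycle loss has not improved for this many
        cycles.

    Returns ``(bundle, history)`` where history has one row per
    (cycle, center) visit with the mean batch losses of that visit.
    """
    shards = list(shards)
    if len(shards) == 0:
        raise ValueError("empty cohort")
    if mode not in ("task_only", "harmonize", "scanner_only", "disease_only"):
        raise ValueError(f"unknown mode {mode!r}")
    m = bundle.label_space.M
    total_cycles = tm_config.n_cycles if n_cycles is None else int(n_cycles)
    if optimizers is None:
        optimizers = make_optimizers(tm_config.lr_initial)
    center_ids = [s.center_id for s in shards]
    by_id = dict(zip(center_ids, shards))
    rows = []
    best, since_best = np.inf, 0
    scanner_scale = (tm_config.lr_scanner_pretrain_scale
                     if mode == "scanner_only"
                     else tm_config.lr_scanner_scale)
    # head-only convergence passes get the same moderate boost as phase B
    task_scale = (tm_config.lr_scanner_pretrain_scale
                  if mode == "disease_only" else 1.0)
    for cycle in range(total_cycles):
        lr = lr_at(cycle, tm_config)
        optimizers["task"].lr = lr * task_scale
        optimizers["scanner"].lr = lr * scanner_scale
        optimizers["confusion"].lr = lr * tm_config.lr_confusion_scale
        schedule = make_schedule(center_ids, cycle, tm_config.seed)
        cycle_losses = []
        for center_id in schedule.center_order:
            if tm_config.reset_optimizers_per_center:
                optimizers = make_optimizers(
                    lr, lr * scanner_scale,
                    lr * tm_config.lr_confusion_scale)
            shard = by_id[center_id]
            center_idx = center_ids.index(center_id)
            batch_losses = []
            for batch in _center_batches(shard, cycle, center_idx, tm_config, m):
                if mode == "task_only":
                    l1 = task_step(bundle, batch.volumes, batch.y_disease,
                                   optimizers["task"])
                    rec = (l1, np.nan, np.nan, np.nan)
                elif mode == "disease_only":
                    l1 = disease_head_step(bundle, batch.volumes,
                                           batch.y_disease, optimizers["task"])
                    rec = (l1, np.nan, np.nan, np.nan)
                elif mode == "scanner_only":
                    l2 = scanner_step(bundle, batch.volumes, batch.y_scanner,
                                      optimizers["scanner"])
                    rec = (np.nan, l2, np.nan, np.nan)
                else:
                    lr_rec = harmonization_step(
                        batch, bundle, optimizers,
                        combined=tm_config.combined_encoder_update)
                    rec = (lr_rec.l_pd, lr_rec.l_sc, lr_rec.l_conf,
                           lr_rec.l_total)
                batch_losses.append(rec)
            arr = np.asarray(batch_losses, dtype=float)
            rows.append(dict(cycle=cycle, center=center_id,
                             n_samples=len(shard), n_batches=len(arr),
                             l_pd=_colmean(arr, 0), l_sc=_colmean(arr, 1),
                             l_conf=_colmean(arr, 2), l_total=_colmean(arr, 3)))
            cycle_losses.append(arr)
            if callback is not None:
                callback(cycle, center_id, bundle)
        if patience is not None:
            allb = np.concatenate(cycle_losses)
            track = {"task_only": 0, "disease_only": 0, "scanner_only": 1,
                     "harmonize": 3}[mode]
            mean_loss = np.nanmean(allb[:, track])
            if mean_loss < best - 1e-6:
                best, since_best = mean_loss, 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
    return bundle, pd.DataFrame(rows)
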