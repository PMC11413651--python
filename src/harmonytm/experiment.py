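"""Experiment orchestration: the before/after x centralized/traveling 2x2.

One experiment generates (or loads) a multi-center cohort, splits it once
into train/test — stratified by center and class where possible, with
single-sample strata kept in training — and then evaluates four models on
the common test split:

* traveling model, before harmonization (two-phase pre-training only);
* traveling model, after the adversarial harmonization cycles;
* centralized baseline, before; and after.

"Before" means the task-pretrained encoder with the scanner head fitted on
its frozen features (the leakage of the un-harmonized representation);
"after" is the same model following the three-step adversarial cycles.
All randomness funnels through one seed hierarchy (cohort / split / init /
training), so a rerun with the same config reproduces every report.
"""

from __future__ import annotations


import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .central_trainer import CentralConfig, run_centralized
from .evaluator import (EvalReport, binary_metrics, feature_probe_accuracy,
                        multiclass_weighted_metrics, pca_probe)
from .harmonizer import pretrain
from .model_zoo import (EncoderConfig, ModelBundle, ScannerLabelSpace,
                        build_bundle, forward_features, predict_disease,
                        predict_scanner)
from .synth_cohort import (CenterShard, CohortSpec, desk_cohort_spec,
                           generate_cohort, load_cohort_nifti)
from .tm_trainer import TMConfig, run_tm

__all__ = [
    "ExperimentConfig",
    "EvalSet",
    "split_cohort",
    "encode",
    "evaluate_bundle",
    "run_experiment",
    "desk_experiment_config",
]


@dataclass
class EvalSet:
    """Pooled held-out samples shared by all four evaluation arms."""

    volumes: np.ndarray
    y_disease: np.ndarray
    y_scanner: np.ndarray
    centers: np.ndarray

    def __len__(self):
        return len(self.volumes)


def split_cohort(shards, test_frac: float = 0.2, seed: int = 0):
    """Per-(center, class) stratified split; singleton strata go to training.

    Returns ``(train_shards, test_set)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    train_shards, te_parts = [], []
    for shard in shards:
        test_mask = np.zeros(len(shard), dtype=bool)
        for cls in np.unique(shard.disease_labels):
            idx = np.flatnonzero(shard.disease_labels == cls)
            n_te = int(round(len(idx) * test_frac))
            if len(idx) < 2 or n_te == 0:
                continue
            chosen = rng.permutation(idx)[:n_te]
            test_mask[chosen] = True
        tr = ~test_mask
        if tr.any():
            train_shards.append(CenterShard(
                center_id=shard.center_id, volumes=shard.volumes[tr],
                disease_labels=shard.disease_labels[tr],
                scanner_labels=shard.scanner_labels[tr]))
        if test_mask.any():
            te_parts.append((shard.volumes[test_mask],
                             shard.disease_labels[test_mask],
                             shard.scanner_labels[test_mask],
                             np.full(test_mask.sum(), shard.center_id)))
    if not te_parts:
        raise ValueError("test split is empty; lower test_frac or enlarge cohort")
    test_set = EvalSet(
        volumes=np.concatenate([p[0] for p in te_parts]),
        y_disease=np.concatenate([p[1] for p in te_parts]),
        y_scanner=np.concatenate([p[2] for p in te_parts]),
        centers=np.concatenate([p[3] for p in te_parts]),
    )
    return train_shards, test_set


def encode(bundle: ModelBundle, volumes, chunk: int = 16) -> np.ndarray:
    """Eval-mode features in memory-bounded chunks."""
    parts = [forward_features(bundle, volumes[i:i + chunk], train=False)
             for i in range(0, len(volumes), chunk)]
    return np.concatenate(parts)


def evaluate_bundle(bundle: ModelBundle, train_shards, test_set: EvalSet,
                    probe_seed: int = 0) -> EvalReport:
    """Full evaluation of one model on the common test split.

    Scanner leakage is measured two ways: by the bundle's own scanner head
    on the test set, and by an independent logistic probe fitted on training
    features and scored on test features.  The PCA audit pools train + test
    features; its probes are themselves scored on an internal held-out part.
    """
    from .synth_cohort import pooled_samples

    tr_vols, tr_y, tr_sc, _ = pooled_samples(train_shards)
    f_train = encode(bundle, tr_vols)
    f_test = encode(bundle, test_set.volumes)

    p = predict_disease(bundle, f_test)
    disease = binary_metrics(test_set.y_disease, p)
    P = predict_scanner(bundle, f_test)
    scanner, conf = multiclass_weighted_metrics(test_set.y_scanner, P,
                                                n_classes=bundle.label_space.M)

    scanner_probe = feature_probe_accuracy(f_train, tr_sc, f_test,
                                           test_set.y_scanner)
    disease_probe = feature_probe_accuracy(f_train, tr_y, f_test,
                                           test_set.y_disease)

    f_all = np.concatenate([f_train, f_test])
    coords, probe_acc = pca_probe(
        f_all,
        np.concatenate([tr_sc, test_set.y_scanner]),
        np.concatenate([tr_y, test_set.y_disease]),
        seed=probe_seed)

    return EvalReport(disease_metrics=disease, scanner_metrics=scanner,
                      confusion=conf, pca_coords=coords, probe_acc=probe_acc,
                      scanner_probe_accuracy=scanner_probe,
                      disease_probe_accuracy=disease_probe,
                      extras=dict(n_train=len(tr_y), n_test=len(test_set)))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one 2x2 experiment."""

    cohort_spec: CohortSpec | None = None
    manifest_path: str | None = None
    encoder_widths: tuple = (4, 8, 16, 32, 32, 16)
    normalize: str = "zscore"  # per-volume input standardisation
    dropout_rate: float = 0.2
    tm: TMConfig = field(default_factory=TMConfig)
    central: CentralConfig = field(default_factory=CentralConfig)
    pretrain_task_cycles: int = 10
    pretrain_scanner_cycles: int = 4
    harmonize_cycles: int = 8
    # disease-head-only convergence passes (frozen encoder) before each
    # evaluation, so threshold metrics reflect the representation rather
    # than the bias drift of the last centers visited
    head_refit_cycles: int = 2
    test_frac: float = 0.2
    harmonize: bool = True
    arms: tuple = ("tm", "centralized")
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.cohort_spec is None) == (self.manifest_path is None):
            raise ValueError("exactly one of cohort_spec / manifest_path")


def desk_experiment_config(seed: int, out_dir: str | None = None,
                           arms=("tm", "centralized")) -> ExperimentConfig:
    """Desk-scale study configuration on the 16-center / 4-scanner cohort."""
    return ExperimentConfig(
        cohort_spec=desk_cohort_spec(seed),
        tm=TMConfig(lr_initial=2e-3, lr_decay=0.95, seed=seed),
        central=CentralConfig(lr_initial=2e-3, lr_decay=0.95, seed=seed),
        arms=tuple(arms),
        out_dir=out_dir,
        seed=seed,
    )


def _load_shards(config: ExperimentConfig):
    if config.cohort_spec is not None:
        shards = generate_cohort(config.cohort_spec)
        space = config.cohort_spec.label_space
    else:
        shards = load_cohort_nifti(config.manifest_path)
        m = int(max(s.scanner_labels.max() for s in shards)) + 1
        space = ScannerLabelSpace.of_size(max(m, 2))
    return shards, space


def run_experiment(config: ExperimentConfig, progress=None) -> dict:
    """Run the requested arms; returns reports plus training histories.

    The result maps ``"<arm>/<stage>"`` (e.g. ``"tm/after"``) to
    :class:`EvalReport`; histories land under ``"history/<arm>"``.  When
    ``config.out_dir`` is set, all reports (JSON), confusion matrices and
    PCA coordinates (CSV), and histories (CSV) are written there.
    """
    def log(msg):
        if progress is not None:
            progress(msg)

    shards, space = _load_shards(config)
    volume_shape = shards[0].volumes.shape[1:]
    train_shards, test_set = split_cohort(shards, config.test_frac, config.seed)
    enc_cfg = EncoderConfig(input_shape=tuple(volume_shape),
                            channel_widths=tuple(config.encoder_widths),
                            dropout_rate=config.dropout_rate,
                            normalize=config.normalize)
    results = {}

    for arm in config.arms:
        bundle = build_bundle(enc_cfg, space, seed=config.seed)
        if arm == "tm":
            log("tm: two-phase pre-training")
            bundle, hist_pre = pretrain(
                train_shards, bundle, config.tm,
                phase_a_cycles=config.pretrain_task_cycles,
                phase_b_cycles=config.pretrain_scanner_cycles)
            bundle, _ = run_tm(train_shards, bundle, config.tm,
                               mode="disease_only",
                               n_cycles=config.head_refit_cycles)
            results["tm/before"] = evaluate_bundle(bundle, train_shards,
                                                   test_set, config.seed)
            hists = [hist_pre]
            if config.harmonize:
                log("tm: harmonization cycles")
                bundle, hist_h = run_tm(train_shards, bundle, config.tm,
                                        mode="harmonize",
                                        n_cycles=config.harmonize_cycles)
                hists.append(hist_h.assign(phase="harmonize"))
                bundle, _ = run_tm(train_shards, bundle, config.tm,
                                   mode="disease_only",
                                   n_cycles=config.head_refit_cycles)
                results["tm/after"] = evaluate_bundle(bundle, train_shards,
                                                      test_set, config.seed)
            results["history/tm"] = pd.concat(hists, ignore_index=True)
        elif arm == "centralized":
            log("centralized: two-phase pre-training")
            bundle, h1 = run_centralized(train_shards, bundle, config.central,
                                         mode="task_only",
                                         n_epochs=config.pretrain_task_cycles)
            bundle, h2 = run_centralized(train_shards, bundle, config.central,
                                         mode="scanner_only",
                                         n_epochs=config.pretrain_scanner_cycles)
            bundle, _ = run_centralized(train_shards, bundle, config.central,
                                        mode="disease_only",
                                        n_epochs=config.head_refit_cycles)
            results["centralized/before"] = evaluate_bundle(
                bundle, train_shards, test_set, config.seed)
            hists = [h1.assign(phase="task_pretrain"),
                     h2.assign(phase="scanner_pretrain")]
            if config.harmonize:
                log("centralized: harmonization epochs")
                bundle, h3 = run_centralized(train_shards, bundle,
                                             config.central, mode="harmonize",
                                             n_epochs=config.harmonize_cycles)
                hists.append(h3.assign(phase="harmonize"))
                bundle, _ = run_centralized(train_shards, bundle,
                                            config.central,
                                            mode="disease_only",
                                            n_epochs=config.head_refit_cycles)
                results["centralized/after"] = evaluate_bundle(
                    bundle, train_shards, test_set, config.seed)
            results["history/centralized"] = pd.concat(hists, ignore_index=True)
        else:
            raise ValueError(f"unknown arm {arm!r}")

    if config.out_dir is not None:
        _write_artifacts(results, config.out_dir)
    return results


def _write_artifacts(results: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for key, value in results.items():
        slug = key.replace("/", "_")
        if isinstance(value, EvalReport):
            value.to_json(os.path.join(out_dir, f"report_{slug}.json"))
            value.confusion_frame().to_csv(
                os.path.join(out_dir, f"confusion_{slug}.csv"))
            value.pca_frame().to_csv(
                os.path.join(out_dir, f"pca_{slug}.csv"), index=False)
        elif isinstance(value, pd.DataFrame):
            value.to_csv(os.path.join(out_dir, f"{slug}.csv"), index=False)
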