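"""Freeze contracts and adversarial dynamics of the three-step procedure."""

import numpy as np
import pytest

from harmonytm.harmonizer import (Batch, confusion_step, harmonization_step,
                                  make_optimizers, one_hot, pretrain,
                                  scanner_step, task_step)
from harmonytm.synth_cohort import generate_cohort
from harmonytm.tm_trainer import TMConfig

from conftest import TOY_SHAPE, toy_cohort_spec


def _toy_batch(rng, n=4, m=3):
    return Batch(volumes=rng.normal(size=(n,) + TOY_SHAPE).astype(np.float32),
                 y_disease=rng.integers(0, 2, size=n),
                 y_scanner=one_hot(rng.integers(0, m, size=n), m))


def test_batch_validation():
    with pytest.raises(ValueError):
        Batch(volumes=np.zeros((0, 2, 2, 2)), y_disease=np.zeros(0),
              y_scanner=np.zeros((0, 3)))
    with pytest.raises(ValueError):
        Batch(volumes=np.zeros((2, 2, 2, 2)), y_disease=np.zeros(2),
              y_scanner=np.full((2, 3), 0.5))  # rows not one-hot


def test_zero_learning_rate_leaves_bundle_bit_identical(toy_bundle, rng):
    batch = _toy_batch(rng)
    before = toy_bundle.snapshot()
    opts = make_optimizers(0.0)
    harmonization_step(batch, toy_bundle, opts)
    after = toy_bundle.state_dict()
    for key in before:
        assert np.array_equal(before[key], after[key]), key


def test_scanner_step_never_touches_encoder(toy_bundle, rng):
    batch = _toy_batch(rng)
    opts = make_optimizers(1e-2)
    for _ in range(5):
        enc_before = {k: v.copy() for k, v in toy_bundle.encoder_params().items()}
        buf_before = {k: v.copy() for k, v in toy_bundle.encoder.buffers().items()}
        scanner_step(toy_bundle, batch.volumes, batch.y_scanner, opts["scanner"])
        for k, v in toy_bundle.encoder_params().items():
            assert np.array_equal(v, enc_before[k]), k
        for k, v in toy_bundle.encoder.buffers().items():
            assert np.array_equal(v, buf_before[k]), k


def test_confusion_step_never_touches_scanner_head(toy_bundle, rng):
    batch = _toy_batch(rng)
    opts = make_optimizers(1e-2)
    for _ in range(5):
        head_before = {k: v.copy() for k, v in toy_bundle.scanner_params().items()}
        confusion_step(toy_bundle, batch.volumes, opts["confusion"])
        for k, v in toy_bundle.scanner_params().items():
            assert np.array_equal(v, head_before[k]), k


def test_task_step_never_touches_scanner_head(toy_bundle, rng):
    batch = _toy_batch(rng)
    opts = make_optimizers(1e-2)
    head_before = {k: v.copy() for k, v in toy_bundle.scanner_params().items()}
    task_step(toy_bundle, batch.volumes, batch.y_disease, opts["task"])
    for k, v in toy_bundle.scanner_params().items():
        assert np.array_equal(v, head_before[k]), k


def test_harmonization_step_returns_consistent_record(toy_bundle, rng):
    batch = _toy_batch(rng)
    rec = harmonization_step(batch, toy_bundle, make_optimizers(1e-3))
    assert rec.l_total == pytest.approx(rec.l_pd + rec.l_sc + rec.l_conf,
                                        abs=1e-9)
    assert rec.l_conf >= np.log(3) - 1e-9


def test_repeated_confusion_steps_approach_ln_m(toy_bundle, rng):
    """Iterating the adversarial encoder update on a fixed batch drives the
    scanner softmax to uniform: the confusion loss approaches its ln M bound."""
    batch = _toy_batch(rng, n=5)
    opts = make_optimizers(1e-2)
    value = np.inf
    for _ in range(200):
        value = confusion_step(toy_bundle, batch.volumes, opts["confusion"])
    assert value - np.log(3) < 0.05


def test_combined_update_mode_runs_and_matches_freeze_contracts(toy_bundle, rng):
    batch = _toy_batch(rng)
    opts = make_optimizers(1e-3)
    head_before = {k: v.copy() for k, v in toy_bundle.scanner_params().items()}
    rec = harmonization_step(batch, toy_bundle, opts, combined=True)
    assert rec.l_total > 0
    # the scanner head is updated only by its own sub-step, which runs last;
    # the encoder update must not have moved it
    changed = any(not np.array_equal(v, head_before[k])
                  for k, v in toy_bundle.scanner_params().items())
    assert changed  # by its own optimizer, not by the encoder update


def test_pretrain_phase_contracts(toy_bundle):
    """Phase A leaves the scanner head untouched; phase B leaves every
    encoder byte untouched."""
    shards = generate_cohort(toy_cohort_spec(seed=1))
    head_init = {k: v.copy() for k, v in toy_bundle.scanner_params().items()}

    cfg = TMConfig(lr_initial=1e-3, seed=0)
    from harmonytm.tm_trainer import run_tm

    bundle, _ = run_tm(shards, toy_bundle, cfg, mode="task_only", n_cycles=2)
    for k, v in bundle.scanner_params().items():
        assert np.array_equal(v, head_init[k]), k

    enc_after_a = {k: v.copy() for k, v in bundle.encoder_params().items()}
    buf_after_a = {k: v.copy() for k, v in bundle.encoder.buffers().items()}
    bundle, _ = run_tm(shards, bundle, cfg, mode="scanner_only", n_cycles=2)
    for k, v in bundle.encoder_params().items():
        assert np.array_equal(v, enc_after_a[k]), k
    for k, v in bundle.encoder.buffers().items():
        assert np.array_equal(v, buf_after_a[k]), k


def test_pretrain_loss_decreases_on_separable_cohort():
    """On an easily separable toy cohort the phase-A training loss falls."""
    from harmonytm.model_zoo import EncoderConfig, ScannerLabelSpace, build_bundle
    from conftest import TOY_WIDTHS

    for seed in (0, 1, 2):
        spec = toy_cohort_spec(seed=seed, disease_delta=0.6,
                               confound_strength=0.0)
        shards = generate_cohort(spec)
        cfg = EncoderConfig(TOY_SHAPE, TOY_WIDTHS)
        bundle = build_bundle(cfg, ScannerLabelSpace.of_size(3), seed=seed)
        bundle, hist = pretrain(shards, bundle,
                                TMConfig(lr_initial=1e-2, seed=seed),
                                phase_a_cycles=12, phase_b_cycles=1)
        task = hist[hist.phase == "task_pretrain"].groupby("cycle").l_pd.mean()
        assert task.iloc[-3:].mean() < task.iloc[:3].mean()


def test_disease_head_refit_touches_only_the_disease_head(toy_bundle):
    """The head-only convergence pass leaves encoder and scanner head
    bit-identical."""
    from harmonytm.tm_trainer import run_tm

    shards = generate_cohort(toy_cohort_spec(seed=4))
    enc = {k: v.copy() for k, v in toy_bundle.encoder_params().items()}
    buf = {k: v.copy() for k, v in toy_bundle.encoder.buffers().items()}
    head = {k: v.copy() for k, v in toy_bundle.scanner_params().items()}
    dis = {k: v.copy() for k, v in toy_bundle.disease_params().items()}
    bundle, _ = run_tm(shards, toy_bundle, TMConfig(lr_initial=1e-3, seed=0),
                       mode="disease_only", n_cycles=2)
    for k, v in bundle.encoder_params().items():
        assert np.array_equal(v, enc[k]), k
    for k, v in bundle.encoder.buffers().items():
        assert np.array_equal(v, buf[k]), k
    for k, v in bundle.scanner_params().items():
        assert np.array_equal(v, head[k]), k
    assert any(not np.array_equal(v, dis[k])
               for k, v in bundle.disease_params().items())


def test_pretrain_rejects_empty_cohort(toy_bundle):
    with pytest.raises(ValueError):
        pretrain([], toy_bundle, TMConfig(seed=0))
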