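"""Generator contracts: determinism, effect injection, manifests, probes."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from harmonytm.model_zoo import ScannerLabelSpace
from harmonytm.synth_cohort import (CohortSpec, ScannerParams,
                                    default_scanner_pool, generate_cohort,
                                    inject_disease_effect,
                                    inject_scanner_effect,
                                    mask_contrast_oracle_accuracy,
                                    pooled_samples, read_manifest,
                                    write_manifest)

from conftest import toy_cohort_spec


# --------------------------------------------------------------------------
# generate_cohort
# --------------------------------------------------------------------------

def test_shard_sizes_follow_spec(toy_spec):
    shards = generate_cohort(toy_spec)
    assert [len(s) for s in shards] == [6, 10, 4]


def test_same_seed_is_bit_identical():
    a = generate_cohort(toy_cohort_spec(seed=5))
    b = generate_cohort(toy_cohort_spec(seed=5))
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.volumes, sb.volumes)
        assert np.array_equal(sa.disease_labels, sb.disease_labels)
        assert np.array_equal(sa.scanner_labels, sb.scanner_labels)


def test_different_seeds_differ():
    a = generate_cohort(toy_cohort_spec(seed=5))
    b = generate_cohort(toy_cohort_spec(seed=6))
    assert not np.array_equal(a[0].volumes, b[0].volumes)


def test_prevalence_extremes_yield_single_class_centers():
    spec = toy_cohort_spec(prevalences=(0.0, 1.0, 0.5))
    shards = generate_cohort(spec)
    assert shards[0].disease_labels.sum() == 0
    assert shards[1].disease_labels.sum() == len(shards[1])


def test_scanner_labels_respect_center_map(toy_spec):
    for c, shard in enumerate(generate_cohort(toy_spec)):
        assert set(shard.scanner_labels) <= set(toy_spec.center_scanner_map[c])


def test_inconsistent_spec_is_rejected():
    with pytest.raises(ValueError):
        toy_cohort_spec(sizes=(6, 10))  # wrong length
    with pytest.raises(ValueError):
        CohortSpec(n_centers=2, scanner_pool=default_scanner_pool(2),
                   center_sizes=[3, 3], center_scanner_map={0: [0], 1: []},
                   prevalence_per_center=[0.5, 0.5])
    with pytest.raises(ValueError):
        CohortSpec(n_centers=2, scanner_pool=[ScannerParams()],
                   center_sizes=[3, 3], center_scanner_map={0: [0], 1: [0]},
                   prevalence_per_center=[0.5, 0.5])


# --------------------------------------------------------------------------
# effect injection
# --------------------------------------------------------------------------

def test_scanner_effect_zero_strength_is_identity(rng):
    v = rng.normal(size=(6, 6, 6)).astype(np.float32)
    params = ScannerParams(gain=1.7, offset=0.4, smooth_sigma=1.0, noise_sd=0.3)
    out = inject_scanner_effect(v, params, 0.0, rng)
    assert np.array_equal(out, v)


def test_scanner_effect_pure_gain_scales_mean(rng):
    v = np.abs(rng.normal(size=(6, 6, 6))).astype(np.float64)
    out = inject_scanner_effect(v, ScannerParams(gain=2.0), 1.0, rng)
    assert out.mean() == pytest.approx(2.0 * v.mean(), rel=1e-6)


def test_scanner_effect_pure_offset_shifts_mean(rng):
    v = rng.normal(size=(6, 6, 6)).astype(np.float64)
    out = inject_scanner_effect(v, ScannerParams(offset=0.5), 1.0, rng)
    assert out.mean() == pytest.approx(v.mean() + 0.5, abs=1e-9)


def test_scanner_effect_rejects_bad_input(rng):
    v = np.full((4, 4, 4), np.nan)
    with pytest.raises(ValueError):
        inject_scanner_effect(v, ScannerParams(), 1.0, rng)
    with pytest.raises(ValueError):
        ScannerParams(gain=-1.0)
    with pytest.raises(ValueError):
        ScannerParams(offset=np.inf)


def test_disease_effect_shifts_only_the_mask(rng):
    v = rng.normal(size=(5, 5, 5)).astype(np.float32)
    mask = np.zeros_like(v, dtype=bool)
    mask.ravel()[:10] = True
    out = inject_disease_effect(v, mask, 1.0)
    assert np.allclose(out[mask], v[mask] + 1.0)
    assert np.array_equal(out[~mask], v[~mask])
    assert out[mask].mean() - v[mask].mean() == pytest.approx(1.0, abs=1e-6)
    assert np.array_equal(inject_disease_effect(v, mask, 0.0), v)


def test_disease_effect_shape_mismatch(rng):
    with pytest.raises(ValueError):
        inject_disease_effect(rng.normal(size=(4, 4, 4)),
                              np.ones((3, 3, 3), dtype=bool), 1.0)


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------

def test_manifest_round_trip(tmp_path, toy_shards):
    path = tmp_path / "manifest.csv"
    written = write_manifest(path, toy_shards)
    read = read_manifest(path, ScannerLabelSpace.of_size(3))
    assert written.astype(str).equals(read.astype(str))


def test_empty_shard_list_gives_header_only(tmp_path):
    path = tmp_path / "manifest.csv"
    write_manifest(path, [])
    frame = read_manifest(path)
    assert len(frame) == 0
    assert list(frame.columns) == ["sample_id", "center_id", "scanner_id",
                                   "disease_label", "volume_path"]


def test_unknown_scanner_id_is_rejected(tmp_path, toy_shards):
    path = tmp_path / "manifest.csv"
    write_manifest(path, toy_shards)
    with pytest.raises(ValueError):
        read_manifest(path, ScannerLabelSpace.of_size(2))  # pool too small


def test_missing_columns_are_rejected(tmp_path):
    path = tmp_path / "broken.csv"
    path.write_text("sample_id,center_id\nx,y\n")
    with pytest.raises(ValueError):
        read_manifest(path)


# --------------------------------------------------------------------------
# statistical structure
# --------------------------------------------------------------------------

def _voxel_probe_accuracy(spec, stride=2):
    """4-fold CV accuracy of a ridge-regularised probe on raw voxels."""
    from sklearn.model_selection import cross_val_score

    shards = generate_cohort(spec)
    vols, _, sc, _ = pooled_samples(shards)
    X = vols[:, ::stride, ::stride, ::stride].reshape(len(vols), -1)
    clf = LogisticRegression(C=0.01, max_iter=500)
    return cross_val_score(clf, X, sc, cv=4).mean()


def _probe_spec(seed, strength):
    return toy_cohort_spec(seed=seed, n_centers=8, sizes=(25,) * 8, m=4,
                           confound_strength=strength, disease_delta=0.0,
                           prevalences=(0.5,) * 8)


def test_no_confound_means_chance_level_scanner_probe():
    """With zero scanner effect and zero disease effect, flattened voxels
    carry no scanner information: probe accuracy sits at chance (1/M)."""
    spec = _probe_spec(seed=0, strength=0.0)
    acc = _voxel_probe_accuracy(spec)
    assert abs(acc - 0.25) <= 0.05


def test_scanner_probe_accuracy_is_monotone_in_confound_strength():
    """Raising confound_strength can only make scanners easier to decode."""
    for seed in (0, 1, 2):
        accs = [_voxel_probe_accuracy(_probe_spec(seed, s))
                for s in (0.0, 0.5, 1.0)]
        assert accs[1] >= accs[0] - 0.02
        assert accs[2] >= accs[1] - 0.02


def test_disease_detectable_by_mask_contrast_oracle():
    """A masked shift well above the noise floor is read off by the direct
    mask-contrast threshold at >90% accuracy."""
    spec = toy_cohort_spec(seed=2, n_centers=4, sizes=(30,) * 4, m=3,
                           confound_strength=0.5, disease_delta=0.2,
                           prevalences=(0.5,) * 4)
    assert spec.disease_delta > 3 * spec.noise_sd
    shards = generate_cohort(spec)
    acc = mask_contrast_oracle_accuracy(shards, spec.resolved_mask())
    assert acc > 0.9
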