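"""Shared fixtures: tiny cohorts and toy models that run in milliseconds."""

import numpy as np
import pytest

from harmonytm.model_zoo import (EncoderConfig, ScannerLabelSpace,
                                 build_bundle)
from harmonytm.synth_cohort import (CohortSpec, default_scanner_pool,
                                    generate_cohort)

TOY_SHAPE = (8, 8, 8)
TOY_WIDTHS = (2, 2, 2, 2, 2, 4)


def toy_cohort_spec(seed=0, n_centers=3, sizes=(6, 10, 4), m=3,
                    confound_strength=1.0, disease_delta=0.4,
                    prevalences=(0.5, 0.5, 0.5)):
    """A millisecond-scale cohort: 8^3 volumes, three centers."""
    return CohortSpec(
        n_centers=n_centers,
        scanner_pool=default_scanner_pool(m),
        center_sizes=list(sizes),
        center_scanner_map={c: [c % m] for c in range(n_centers)},
        prevalence_per_center=list(prevalences),
        volume_shape=TOY_SHAPE,
        disease_delta=disease_delta,
        confound_strength=confound_strength,
        noise_sd=0.05,
        seed=seed,
    )


@pytest.fixture
def toy_spec():
    return toy_cohort_spec()


@pytest.fixture
def toy_shards(toy_spec):
    return generate_cohort(toy_spec)


@pytest.fixture
def toy_bundle():
    cfg = EncoderConfig(input_shape=TOY_SHAPE, channel_widths=TOY_WIDTHS)
    return build_bundle(cfg, ScannerLabelSpace.of_size(3), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
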