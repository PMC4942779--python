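"""Shared fixtures: small, fast synthetic inputs built at test time."""
from __future__ import annotations

import numpy as np
import pytest

from ibdquant import CohortSpec, generate_cohort
from ibdquant.features import extract_feature_table
from ibdquant.preprocess import preprocess_sample
from ibdquant.synthetic import NoiseSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def small_spec(**overrides) -> CohortSpec:
    """A quick cohort spec: single 128x128 tile per sample."""
    defaults = dict(n_samples=4, seed=0, tile_grid=(1, 1),
                    tile_shape_px=(128, 128),
                    noise=NoiseSpec(poisson_scale=200.0, gaussian_sd=0.005))
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(small_spec())


def cohort_feature_table(spec: CohortSpec):
    """Generate -> preprocess -> extract, returning (table, labels dict)."""
    cohort = generate_cohort(spec)
    pre = [preprocess_sample(s, r) for s, r, _ in cohort]
    table, _qc = extract_feature_table(pre)
    labels = {s.sample_id: lab for s, _, lab in cohort}
    return table, labels
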