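"""Shared pytest fixtures; the generators and oracles live in helpers.py."""

import warnings

import numpy as np
import pytest

from helpers import (  # noqa: F401  (re-exported for the test modules)
    NEUN,
    oracle_active_rows,
    oracle_tukey,
    random_dataset,
    random_filters,
    random_simple_polygon,
    rasterise_labels,
)

warnings.filterwarnings("ignore", message=".*excluded.*")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def ad_dataset():
    from cardlink.fixtures import FixtureConfig, generate_clinical_dataset

    return generate_clinical_dataset(FixtureConfig(n_ad=8, n_control=4, seed=42, missing_rate=0.02))

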