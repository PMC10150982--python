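"""Shared fixtures: one reduced-scale synthetic corpus with trained models.

The corpus (two syllables, ~6,000 renditions each over 30 days at 200/day)
is expensive enough to build and fit that the density/maturity models are
trained once per session and reused by the evaluation-oriented tests.
"""

import numpy as np
import pandas as pd
import pytest

import songdev
from songdev import entropy as en


@pytest.fixture(scope="session")
def defaults_params() -> songdev.GroundTruthParams:
    return songdev.GroundTruthParams(
        n_birds=1, syllables_per_bird=2, k=6,
        renditions_per_day=200, age_range=(60.0, 90.0), seed=7,
    )


@pytest.fixture(scope="session")
def defaults_dataset(defaults_params) -> pd.DataFrame:
    return songdev.generate_dataset(defaults_params)


@pytest.fixture(scope="session")
def defaults_splits(defaults_dataset):
    return {
        key: songdev.split_dataset(sub, 0.2, seed=7)
        for key, sub in defaults_dataset.groupby(["bird_id", "syllable_id"])
    }


@pytest.fixture(scope="session")
def trained_dev_models(defaults_splits):
    return {
        key: songdev.train_dev_model(train, architecture="narrow64", seed=7,
                                     max_epochs=150, patience=12)
        for key, (train, _ev) in defaults_splits.items()
    }


@pytest.fixture(scope="session")
def trained_age_models(defaults_splits):
    return {
        key: songdev.train_age_net(train, "pyramid", l2_weight=1e-4, seed=7)
        for key, (train, _ev) in defaults_splits.items()
    }


@pytest.fixture(scope="session")
def defaults_query_times(defaults_params, defaults_splits):
    # support filter scaled to the corpus singing rate (~7 renditions per
    # half-hour window at 200/day; see docs/methods.md)
    return {
        key: en.sample_query_times(train, defaults_params.day_window, min_count=5)
        for key, (train, _ev) in defaults_splits.items()
    }


def random_spd(rng: np.random.Generator, k: int) -> np.ndarray:
    """Well-conditioned random SPD matrix for clamp/entropy tests."""
    a = rng.normal(size=(k, k))
    q, _ = np.linalg.qr(a)
    lam = rng.uniform(0.2, 5.0, size=k)
    return (q * lam) @ q.T
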