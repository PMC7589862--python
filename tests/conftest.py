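import numpy as np
import pandas as pd
import pytest

from berrywalk import SyntheticConfig, generate_dataset
from berrywalk.features import assemble_features


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by cheap tests."""
    obs, weather_df, gt = generate_dataset(SyntheticConfig(n_obs=120), seed=11)
    return obs, weather_df, gt


@pytest.fixture(scope="session")
def small_features(small_dataset):
    obs, weather_df, _ = small_dataset
    return assemble_features(obs, weather_df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_composition_values(rng, d):
    """Strictly positive part vectors with realistic spread."""
    return np.exp(rng.normal(0.0, 1.0, size=d))


def random_sbp(rng, labels):
    """A random valid sequential binary partition over the labels."""
    from berrywalk.compositions import BalancePartition

    contrasts = []
    groups = [list(range(len(labels)))]
    while groups:
        group = groups.pop(rng.integers(len(groups)))
        if len(group) < 2:
            continue
        perm = rng.permutation(group)
        cut = int(rng.integers(1, len(group)))
        num, den = list(perm[:cut]), list(perm[cut:])
        contrasts.append(([labels[i] for i in num], [labels[i] for i in den]))
        groups.extend(g for g in (num, den) if len(g) > 1)
    return BalancePartition.from_contrasts(labels, contrasts)
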