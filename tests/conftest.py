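import numpy as np
import pytest

from polyrank import (
    HashedEnvironmentFingerprinter,
    RunConfig,
    fingerprint_polymers,
    study_datasets,
    run_unified_ranking,
)


@pytest.fixture(scope="session")
def fixtures():
    """The three packaged study datasets (24 + 7 + 8 polymers)."""
    return study_datasets()


@pytest.fixture(scope="session")
def fixture_polymers(fixtures):
    return [p for ds in fixtures.values() for p in ds.polymers]


@pytest.fixture(scope="session")
def fixture_fps(fixture_polymers):
    return fingerprint_polymers(fixture_polymers, HashedEnvironmentFingerprinter())


@pytest.fixture(scope="session")
def fixture_run(fixtures):
    """Full pipeline run (CV over the default C grid + refit) on the study data.

    Session-scoped: the cross-validated grid search is the expensive step and
    several tests inspect the same trained model.
    """
    return run_unified_ranking(RunConfig(seed=0), datasets=list(fixtures.values()))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_linear_instance(seed: int, n_items: int = 10, dim: int = 12):
    """Items with a known linear latent score and all induced preference pairs."""
    gen = np.random.default_rng(seed)
    X = gen.normal(size=(n_items, dim))
    w = gen.normal(size=dim)
    s = X @ w
    diffs, labels = [], []
    for i in range(n_items):
        for j in range(i + 1, n_items):
            diffs.append(X[i] - X[j])
            labels.append(1 if s[i] > s[j] else -1)
    return X, w, s, np.array(diffs), np.array(labels)
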