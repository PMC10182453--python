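"""Shared fixtures: a small synthetic world and its derived artifacts."""

from __future__ import annotations

import numpy as np
import pytest

import rdsentinel as rd
from rdsentinel.simulate import WorldConfig, generate_panel, generate_world


@pytest.fixture(scope="session")
def world():
    """Mid-size labeled world reused by feature/intent/pipeline tests."""
    return generate_world(WorldConfig(n_users=2500, seed=11))


@pytest.fixture(scope="session")
def sessions(world):
    return world.build_sessions()


@pytest.fixture(scope="session")
def oracle_labels(world, sessions):
    return world.oracle_intents(sessions)


@pytest.fixture(scope="session")
def featurizer(world, sessions, oracle_labels):
    return rd.SessionFeaturizer().fit(sessions, oracle_labels)


@pytest.fixture(scope="session")
def session_feats(featurizer, sessions):
    return featurizer.transform(sessions)


@pytest.fixture(scope="session")
def noisy_panel():
    """Count-rich panel with 5% observation noise and default news bursts."""
    panel, coeffs = generate_panel(WorldConfig(n_users=20000, noise_frac=0.05, seed=101))
    return panel, coeffs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
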