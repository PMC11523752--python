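"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from cmconn import SessionSpec, generate_session, preprocess_session


def small_spec(**overrides) -> SessionSpec:
    """A fast-to-generate session spec; overrides are applied on top."""
    base = dict(
        n_subjects=1,
        n_trials_per_surface=3,
        surfaces=("Sandpaper", "Suede", "Silk"),
        seed=1234,
    )
    base.update(overrides)
    return SessionSpec(**base)


@pytest.fixture(scope="session")
def coupled_epochs():
    """Preprocessed single-subject session with default per-surface coupling."""
    spec = small_spec(n_trials_per_surface=4)
    trials, _ = generate_session(spec)
    return preprocess_session(trials)


@pytest.fixture(scope="session")
def uncoupled_epochs():
    """Preprocessed trials with zero coupling everywhere (independence null)."""
    spec = small_spec(
        n_trials_per_surface=4,
        coupling_gain_per_surface={"Sandpaper": 0.0, "Suede": 0.0, "Silk": 0.0},
        subject_kappa_jitter=0.0,
        seed=99,
    )
    trials, _ = generate_session(spec)
    return preprocess_session(trials)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
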