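"""Shared fixtures: small interaction sets and a paper-scale ensemble table.

Everything is generated programmatically; the heavier shared artifacts
(stable-community enumerations, the synthetic-invader trial table) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from glvcom.assembly import enumerate_stable_communities
from glvcom.config import ModelConfig
from glvcom.ensemble import ensemble_survey, sample_invaders
from glvcom.interactions import InteractionSet
from glvcom.synthetic import sample_world, world_interactions


def make_iset(B, rates=None, caps=None, A=None, species=None) -> InteractionSet:
    """Hand-built InteractionSet with zero SDs for targeted tests."""
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    A = np.zeros((n, n)) if A is None else np.asarray(A, dtype=float)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_d = np.where(off, np.log1p(B), 0.0)
        eps_r = np.where(off, np.log1p(A), 0.0)
    return InteractionSet(
        species=species or [f"sp{i+1:02d}" for i in range(n)],
        A=A, B=B, A_sd=np.zeros((n, n)), B_sd=np.zeros((n, n)),
        eps_density=eps_d, eps_rate=eps_r, valid=np.ones((n, n), bool),
        mono_rates=np.full(n, 0.8) if rates is None else np.asarray(rates, float),
        mono_capacities=np.ones(n) if caps is None else np.asarray(caps, float),
        mono_rate_sd=np.zeros(n), mono_capacity_sd=np.zeros(n))


@pytest.fixture(scope="session")
def model_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def pool_world():
    """A 7-species negative-dominated world used for ensemble-level checks."""
    return sample_world(7, seed=11)


@pytest.fixture(scope="session")
def pool_iset(pool_world):
    return world_interactions(pool_world)


@pytest.fixture(scope="session")
def pool_stable(pool_iset, model_config):
    return enumerate_stable_communities(pool_iset, model_config)


@pytest.fixture(scope="session")
def ensemble_table(pool_iset, pool_stable, model_config):
    """Synthetic-invader trials over all stable communities of the pool.

    Sized to give >= 1000 trials while staying fast enough for the default
    test run.
    """
    stable = pool_stable.stable_states
    n_invaders = max(1, int(np.ceil(1000 / len(stable))) + 2)
    invaders = sample_invaders(pool_iset, n_invaders, seed=23)
    return ensemble_survey(invaders, stable, pool_iset, model_config)
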