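"""Shared fixtures: tiny simulator configurations, synthetic
trajectories, and stub surrogate models for oracle-style tests."""

from __future__ import annotations

import numpy as np
import pytest

from sepsiscast import abm
from sepsiscast.abm import InjuryParams, SimConfig, Trajectory
from sepsiscast.surrogates import NetSpec, SurrogateModel
from sepsiscast.windows import NormStats


@pytest.fixture(scope="session")
def toy_config():
    """7x7 agent-free grid: dynamics reduce to pure cell-level rules."""
    return SimConfig(width=7, height=7, n_phagocytes=0, n_regulators=0)


@pytest.fixture(scope="session")
def desk_config():
    return abm.DESK_CONFIG


@pytest.fixture(scope="session")
def mid_params():
    return InjuryParams(injury_size=5, virulence=0.2, toxigenesis=0.15,
                        env_toxicity=0.005, host_resilience=0.1)


@pytest.fixture(scope="session")
def small_cohort(desk_config):
    """A small mixed-outcome cohort for structural checks."""
    return abm.simulate_cohort(40, 1234, desk_config, max_steps=300)


def synthetic_trajectory(T, pid=0, seed=0, grid=(33, 33)):
    """Deterministic synthetic trajectory whose entries encode their own
    (step, channel) coordinates, so window alignment can be verified by
    direct indexing."""
    t = np.arange(T, dtype=float)
    cyto = (pid * 10_000 + t[:, None] * 100
            + np.arange(abm.N_CYTOKINES)[None, :])
    deficit = pid * 1000 + t
    return Trajectory(cytokines=cyto, oxygen_deficit=deficit,
                      outcome="censored",
                      params=InjuryParams(1, 0.1, 0.1, 0.0, 0.1),
                      seed=seed, grid_shape=grid)


@pytest.fixture
def coord_trajectories():
    return [synthetic_trajectory(T, pid=i)
            for i, T in enumerate((30, 6, 5, 60))]


def identity_stats(deficit_max=1089.0):
    """Norm stats with mean 0 / std 1: standardized == original units."""
    return NormStats(cyto_mean=np.zeros(abm.N_CYTOKINES),
                     cyto_std=np.ones(abm.N_CYTOKINES),
                     deficit_mean=0.0, deficit_std=1.0,
                     deficit_max=deficit_max)


class _StubNet:
    """Duck-typed Sequential: applies a plain function of the input."""

    def __init__(self, fn):
        self.fn = fn

    def forward(self, x, rng=None):
        out = np.asarray(self.fn(np.asarray(x, dtype=float)), dtype=float)
        return out.reshape(len(x), 1)


def stub_model(fn, stats=None, kind="mlp_predictor", channel=None):
    """Wrap a function (standardized in → standardized out) as a model."""
    spec = NetSpec(kind=kind, layer_sizes=(), dropout_rate=0.0,
                   dropout_permanent=False, loss="MSE",
                   input_shape=(), output_shape=(1,))
    return SurrogateModel(spec=spec, net=_StubNet(fn), is_stub=True,
                          channel=channel,
                          norm_stats=stats or identity_stats())


def last_value_stubs(stats=None):
    """11 stubs that each repeat the last observed value of their channel."""
    return [stub_model(lambda x, c=c: x[:, -1, c], stats, channel=c)
            for c in range(abm.N_CYTOKINES)]


def increment_stubs(delta=1.0, stats=None):
    """11 stubs that add ``delta`` to the last value of their channel."""
    return [stub_model(lambda x, c=c: x[:, -1, c] + delta, stats, channel=c)
            for c in range(abm.N_CYTOKINES)]
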