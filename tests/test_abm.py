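"""Simulator unit and property tests: terminal states, determinism,
bounds, checkpointing, and branching replicates."""

import numpy as np
import pytest

from sepsiscast.abm import (InjuryParams, ParameterError, SimConfig,
                            checkpoint, death_threshold, initial_state,
                            reseed_replicates, restore, simulate_patient,
                            step)


class TestTerminalStates:
    def test_no_perturbation_is_healthy_fixed_point(self, desk_config):
        traj = simulate_patient(
            InjuryParams(0, 0.5, 0.5, 0.0, 0.1), seed=3, max_steps=50,
            config=desk_config)
        assert traj.outcome == "healed"
        assert len(traj) == 2            # initial state + one checked step
        assert np.all(traj.oxygen_deficit == 0.0)

    def test_pure_healing_dynamics(self, toy_config):
        cfg = SimConfig(width=21, height=21, n_phagocytes=0,
                        n_regulators=0)
        traj = simulate_patient(
            InjuryParams(4, 0.0, 0.0, 0.0, 0.25), seed=5, max_steps=500,
            config=cfg)
        assert traj.outcome == "healed"
        assert np.all(np.diff(traj.oxygen_deficit) <= 0)
        assert traj.oxygen_deficit[-1] == 0.0

    def test_death_is_declared_and_absorbing(self, toy_config):
        # overwhelming toxicity on a tiny grid kills quickly
        traj = simulate_patient(
            InjuryParams(3, 0.9, 1.0, 0.9, 0.0), seed=1, max_steps=200,
            config=toy_config)
        assert traj.outcome == "dead"
        thr = death_threshold(toy_config)
        assert traj.oxygen_deficit[-1] > thr
        assert np.all(traj.oxygen_deficit[:-1] <= thr)

    def test_censored_when_cap_reached(self, desk_config, mid_params):
        traj = simulate_patient(mid_params, seed=11, max_steps=10,
                                config=desk_config)
        if traj.outcome == "censored":
            assert len(traj) == 11


@pytest.mark.parametrize("field,value", [
    ("injury_size", -1.0), ("injury_size", 1e6),
    ("virulence", 1.5), ("toxigenesis", -0.1),
    ("env_toxicity", 2.0), ("host_resilience", -0.5),
])
def test_invalid_params_name_offending_field(field, value, mid_params):
    bad = {**mid_params.__dict__, field: value}
    with pytest.raises(ParameterError, match=field):
        simulate_patient(InjuryParams(**bad), seed=0, max_steps=5)


def test_max_steps_below_one_rejected(mid_params, desk_config):
    with pytest.raises(ValueError, match="max_steps"):
        simulate_patient(mid_params, seed=0, max_steps=0,
                         config=desk_config)


@pytest.mark.parametrize("w,h,expected", [
    (101, 101, 8160),   # floor(0.8 * 10201): the full-scale deficit top
    (10, 10, 80),
    (1, 1, 0),
    (33, 33, 871),
])
def test_death_threshold_is_80pct_of_grid(w, h, expected):
    assert death_threshold(SimConfig(width=w, height=h)) == expected


def test_fixed_seed_gives_bit_identical_trajectories(mid_params,
                                                     desk_config):
    a = simulate_patient(mid_params, seed=7, max_steps=150,
                         config=desk_config)
    b = simulate_patient(mid_params, seed=7, max_steps=150,
                         config=desk_config)
    assert np.array_equal(a.cytokines, b.cytokines)
    assert np.array_equal(a.oxygen_deficit, b.oxygen_deficit)
    assert a.outcome == b.outcome
    c = simulate_patient(mid_params, seed=8, max_steps=150,
                         config=desk_config)
    assert not np.array_equal(a.cytokines, c.cytokines)


def test_recorded_outputs_respect_physical_bounds(small_cohort,
                                                  desk_config):
    top = desk_config.width * desk_config.height
    for traj in small_cohort:
        assert np.all(traj.oxygen_deficit >= 0)
        assert np.all(traj.oxygen_deficit <= top)
        assert np.all(traj.cytokines >= 0)
        assert np.all(np.isfinite(traj.cytokines))


def test_heteroscedastic_one_step_noise(small_cohort):
    from sepsiscast.experiments import deficit_change_variance_terciles
    lo, _, hi = deficit_change_variance_terciles(small_cohort)
    assert hi > lo


class TestCheckpointRestore:
    def test_round_trip_then_steps_is_bit_identical(self, mid_params,
                                                    desk_config):
        state = initial_state(mid_params, 21, desk_config)
        for _ in range(20):
            step(state, mid_params, desk_config)
        blob = checkpoint(state)
        resumed = restore(blob)
        for _ in range(10):
            step(state, mid_params, desk_config)
            step(resumed, mid_params, desk_config)
        assert np.array_equal(state.grid_damage, resumed.grid_damage)
        assert np.array_equal(state.grid_infection,
                              resumed.grid_infection)
        assert np.array_equal(state.cytokine_fields,
                              resumed.cytokine_fields)
        assert np.array_equal(state.phagocyte_pos, resumed.phagocyte_pos)
        assert state.t == resumed.t

    def test_round_trip_zero_steps_identity(self, mid_params,
                                            desk_config):
        state = initial_state(mid_params, 4, desk_config)
        resumed = restore(checkpoint(state))
        assert np.array_equal(state.grid_damage, resumed.grid_damage)
        assert resumed.t == state.t

    def test_reseeded_restore_diverges(self, mid_params, desk_config):
        state = initial_state(mid_params, 21, desk_config)
        for _ in range(30):
            step(state, mid_params, desk_config)
        blob = checkpoint(state)
        a, b = restore(blob), restore(blob, new_seed=999)
        for _ in range(10):
            step(a, mid_params, desk_config)
            step(b, mid_params, desk_config)
        assert not np.array_equal(a.cytokine_fields, b.cytokine_fields)

    def test_corrupted_blob_raises(self):
        with pytest.raises(ValueError, match="deserialize"):
            restore(b"not a checkpoint")


@pytest.fixture(scope="module")
def parent(mid_params, desk_config):
    return simulate_patient(mid_params, seed=31, max_steps=200,
                            config=desk_config, keep_checkpoints=True)


class TestReseedReplicates:
    def test_prefix_shared_exactly(self, parent, mid_params, desk_config):
        bt = 30
        reps = reseed_replicates(parent, bt, seeds=[5, 6],
                                 config=desk_config, max_steps=120)
        for r in reps:
            assert r.branch_time == bt
            assert np.array_equal(r.cytokines[:bt + 1],
                                  parent.cytokines[:bt + 1])
            assert np.array_equal(r.oxygen_deficit[bt - 1],
                                  parent.oxygen_deficit[bt - 1])

    def test_none_seed_reproduces_parent(self, parent, mid_params,
                                         desk_config):
        bt = 30
        (rep,) = reseed_replicates(parent, bt, seeds=[None],
                                   config=desk_config, max_steps=200)
        n = min(len(rep), len(parent))
        assert np.array_equal(rep.cytokines[:n], parent.cytokines[:n])
        assert rep.outcome == parent.outcome

    def test_fresh_seeds_diverge_after_branch(self, parent, mid_params,
                                              desk_config):
        bt = 30
        reps = reseed_replicates(parent, bt, seeds=[5, 6],
                                 config=desk_config, max_steps=120)
        assert not np.array_equal(reps[0].cytokines[bt + 1:bt + 20],
                                  reps[1].cytokines[bt + 1:bt + 20])

    def test_branch_beyond_span_rejected(self, parent, desk_config):
        with pytest.raises(IndexError, match="branch_t"):
            reseed_replicates(parent, len(parent) + 5, seeds=[1],
                              config=desk_config)

    def test_missing_checkpoint_names_time(self, parent, desk_config):
        with pytest.raises(KeyError, match="35"):
            reseed_replicates(parent, 35, seeds=[1], config=desk_config)
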