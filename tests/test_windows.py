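"""Windowing, early-phase exclusion, patient-level splitting, and
standardization round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sepsiscast.windows import exclude_early, make_windows, split
from conftest import synthetic_trajectory


class TestWindowCounts:
    @pytest.mark.parametrize("T,expected", [(6, 1), (5, 0), (7, 2)])
    def test_short_trajectory_counts(self, T, expected):
        ws = make_windows([synthetic_trajectory(T)], shuffle_seed=0)
        assert len(ws) == expected

    def test_many_equal_trajectories(self):
        trajs = [synthetic_trajectory(105, pid=i) for i in range(100)]
        ws = make_windows(trajs, shuffle_seed=1)
        assert len(ws) == 100 * (105 - 5)

    def test_empty_input_gives_empty_set(self):
        ws = make_windows([], shuffle_seed=0)
        assert len(ws) == 0


def test_window_label_alignment_matches_direct_indexing(
        coord_trajectories):
    ws = make_windows(coord_trajectories, shuffle_seed=3)
    trajs = coord_trajectories
    rng = np.random.default_rng(0)
    for i in rng.choice(len(ws), size=25, replace=True):
        pid, t0 = int(ws.patient_ids[i]), int(ws.t_index[i])
        traj = trajs[pid]
        assert np.array_equal(ws.inputs[i], traj.cytokines[t0:t0 + 5])
        assert np.array_equal(ws.labels_next_profile[i],
                              traj.cytokines[t0 + 5])
        assert np.array_equal(ws.deficits[i],
                              traj.oxygen_deficit[t0:t0 + 6])
        assert ws.labels_deficit[i] == traj.oxygen_deficit[t0 + 4]
        assert ws.labels_next_deficit[i] == traj.oxygen_deficit[t0 + 5]


def test_shuffle_is_a_seeded_permutation(coord_trajectories):
    a = make_windows(coord_trajectories, shuffle_seed=7)
    b = make_windows(coord_trajectories, shuffle_seed=7)
    c = make_windows(coord_trajectories, shuffle_seed=8)
    assert np.array_equal(a.t_index, b.t_index)
    assert not np.array_equal(a.t_index, c.t_index)
    key_a = sorted(zip(a.patient_ids.tolist(), a.t_index.tolist()))
    key_c = sorted(zip(c.patient_ids.tolist(), c.t_index.tolist()))
    assert key_a == key_c


class TestExcludeEarly:
    def test_cutoff_zero_is_identity(self, coord_trajectories):
        out = exclude_early(coord_trajectories, 0)
        for before, after in zip(coord_trajectories, out):
            assert np.array_equal(before.cytokines, after.cytokines)

    def test_cutoff_at_length_removes_all_windows(self):
        traj = synthetic_trajectory(50)
        out = exclude_early([traj], 50)
        assert len(out[0]) == 0
        assert len(make_windows(out, shuffle_seed=0)) == 0

    def test_240_cutoff_on_340_step_trajectory_gives_95_windows(self):
        traj = synthetic_trajectory(340)
        out = exclude_early([traj], 240)
        assert len(out[0]) == 100
        ws = make_windows(out, shuffle_seed=0)
        assert len(ws) == 95

    def test_records_renumbered_consistently(self):
        traj = synthetic_trajectory(30)
        out = exclude_early([traj], 10)[0]
        assert np.array_equal(out.cytokines, traj.cytokines[10:])

    def test_negative_cutoff_rejected(self, coord_trajectories):
        with pytest.raises(ValueError, match="cutoff"):
            exclude_early(coord_trajectories, -1)


class TestSplit:
    def test_two_patients_half_split(self):
        trajs = [synthetic_trajectory(20, pid=i) for i in range(2)]
        ws = make_windows(trajs, shuffle_seed=0)
        tr, va = split(ws, 0.5, seed=0)
        assert len(set(tr.patient_ids)) == 1
        assert len(set(va.patient_ids)) == 1
        assert set(tr.patient_ids).isdisjoint(set(va.patient_ids))

    def test_same_seed_identical_split(self):
        trajs = [synthetic_trajectory(15, pid=i) for i in range(6)]
        ws = make_windows(trajs, shuffle_seed=0)
        a, _ = split(ws, 0.7, seed=5)
        b, _ = split(ws, 0.7, seed=5)
        assert np.array_equal(a.t_index, b.t_index)

    def test_fraction_respected_within_one_patient(self):
        trajs = [synthetic_trajectory(25, pid=i) for i in range(100)]
        ws = make_windows(trajs, shuffle_seed=0)
        tr, va = split(ws, 0.9, seed=1)
        per_patient = 25 - 5
        assert abs(len(tr) - 0.9 * len(ws)) <= per_patient
        assert len(tr) + len(va) == len(ws)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_domain(self, bad):
        ws = make_windows([synthetic_trajectory(20, pid=i)
                           for i in range(3)], shuffle_seed=0)
        with pytest.raises(ValueError, match="fraction"):
            split(ws, bad, seed=0)


class TestStandardization:
    def test_training_portion_standardizes_to_unit_moments(self):
        rng = np.random.default_rng(0)
        trajs = []
        for i in range(8):
            t = synthetic_trajectory(40, pid=i)
            t.cytokines = rng.gamma(2.0, 50.0, size=t.cytokines.shape)
            trajs.append(t)
        ws = make_windows(trajs, shuffle_seed=0)
        tr, _ = split(ws, 0.75, seed=0)
        z = tr.norm_stats.standardize_cyto(
            tr.inputs.reshape(-1, 11))
        assert np.all(np.abs(z.mean(axis=0)) < 1e-6)
        assert np.all(np.abs(z.std(axis=0) - 1.0) < 1e-6)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_standardize_invert_is_identity(self, seed):
        from conftest import identity_stats
        rng = np.random.default_rng(seed)
        stats = identity_stats()
        stats = type(stats)(
            cyto_mean=rng.normal(0, 100, 11),
            cyto_std=rng.uniform(0.5, 200, 11),
            deficit_mean=float(rng.normal(0, 500)),
            deficit_std=float(rng.uniform(1, 300)),
            deficit_max=1089.0)
        x = rng.gamma(2.0, 40.0, size=(17, 11))
        back = stats.destandardize_cyto(stats.standardize_cyto(x))
        assert np.allclose(back, x, rtol=1e-9)
        d = rng.uniform(0, 1089, size=9)
        backd = stats.destandardize_deficit(stats.standardize_deficit(d))
        assert np.allclose(backd, d, rtol=1e-9)
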