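"""Supervised windowing of simulated trajectories.

Turns per-patient time series into shuffled training pairs: five
consecutive 11-dimensional cytokine profiles as input, the next profile
as label, plus the aligned oxygen-deficit block needed by the health
regressor (deficit at the last input step) and by the deficit-only
forecaster (five past deficits → next deficit).

Standardization is per-channel z-scoring; the statistics are computed
from the training portion only and travel with the WindowSet so the
forecasting layer can invert them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .abm import N_CYTOKINES, Trajectory

__all__ = ["WindowSet", "NormStats", "make_windows", "exclude_early",
           "split", "WINDOW_LEN"]

#: number of consecutive profiles in one input window
WINDOW_LEN = 5


@dataclass(frozen=True)
class NormStats:
    """Per-channel standardization statistics (z-score)."""

    cyto_mean: np.ndarray      # (11,)
    cyto_std: np.ndarray       # (11,)
    deficit_mean: float
    deficit_std: float
    deficit_max: float         # W*H of the generating grid (clip bound)

    def standardize_cyto(self, x):
        return (x - self.cyto_mean) / self.cyto_std

    def destandardize_cyto(self, z):
        return z * self.cyto_std + self.cyto_mean

    def standardize_deficit(self, d):
        return (d - self.deficit_mean) / self.deficit_std

    def destandardize_deficit(self, z):
        return z * self.deficit_std + self.deficit_mean

    def allclose(self, other, rtol=1e-12) -> bool:
        return (np.allclose(self.cyto_mean, other.cyto_mean, rtol=rtol)
                and np.allclose(self.cyto_std, other.cyto_std, rtol=rtol)
                and np.isclose(self.deficit_mean, other.deficit_mean,
                               rtol=rtol)
                and np.isclose(self.deficit_std, other.deficit_std,
                               rtol=rtol))

    def to_dict(self):
        return {
            "cyto_mean": self.cyto_mean.tolist(),
            "cyto_std": self.cyto_std.tolist(),
            "deficit_mean": self.deficit_mean,
            "deficit_std": self.deficit_std,
            "deficit_max": self.deficit_max,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(cyto_mean=np.asarray(d["cyto_mean"], dtype=float),
                   cyto_std=np.asarray(d["cyto_std"], dtype=float),
                   deficit_mean=float(d["deficit_mean"]),
                   deficit_std=float(d["deficit_std"]),
                   deficit_max=float(d["deficit_max"]))


@dataclass
class WindowSet:
    """Shuffled supervised window/label pairs from a trajectory corpus.

    ``deficits`` covers the six steps ``t .. t+5`` of each window, so both
    regressor labels (column 4, the last input step) and the deficit-only
    forecaster's pairs (columns 0..4 → column 5) come from one block.
    """

    inputs: np.ndarray                # (N, 5, 11), original units
    labels_next_profile: np.ndarray   # (N, 11)
    deficits: np.ndarray              # (N, 6)
    patient_ids: np.ndarray           # (N,)
    t_index: np.ndarray               # (N,) step of first window element
    norm_stats: NormStats | None = None
    shuffle_seed: int | None = None

    def __len__(self):
        return len(self.inputs)

    @property
    def labels_deficit(self):
        """Oxygen deficit aligned to the last input step (regressor label)."""
        return self.deficits[:, WINDOW_LEN - 1]

    @property
    def deficit_inputs(self):
        """Five past deficit values (deficit-only forecaster input)."""
        return self.deficits[:, :WINDOW_LEN]

    @property
    def labels_next_deficit(self):
        """Next-step deficit (deficit-only forecaster label)."""
        return self.deficits[:, WINDOW_LEN]


def _compute_norm_stats(inputs, deficits, deficit_max) -> NormStats:
    flat = inputs.reshape(-1, N_CYTOKINES)
    std = flat.std(axis=0)
    dstd = deficits[:, :WINDOW_LEN].std()
    return NormStats(
        cyto_mean=flat.mean(axis=0),
        cyto_std=np.where(std > 0, std, 1.0),
        deficit_mean=float(deficits[:, :WINDOW_LEN].mean()),
        deficit_std=float(dstd if dstd > 0 else 1.0),
        deficit_max=float(deficit_max),
    )


def make_windows(trajectories: list[Trajectory],
                 shuffle_seed: int) -> WindowSet:
    """Build the shuffled WindowSet for a corpus.

    A trajectory of length T contributes exactly ``T - 5`` windows (none
    if T < 6); no window crosses a terminal step because recording stops
    there. Shuffling is a seeded permutation of the pooled windows.
    ``norm_stats`` are computed over all windows present — call
    :func:`split` afterwards to recompute them from the training portion.
    """
    ins, labels, defs, pids, tidx = [], [], [], [], []
    deficit_max = 101 * 101
    for pid, traj in enumerate(trajectories):
        deficit_max = traj.grid_shape[0] * traj.grid_shape[1]
        T = len(traj)
        if T < WINDOW_LEN + 1:
            continue
        n = T - WINDOW_LEN
        c = traj.cytokines
        d = traj.oxygen_deficit
        win = np.lib.stride_tricks.sliding_window_view(
            c, (WINDOW_LEN, N_CYTOKINES)).reshape(-1, WINDOW_LEN,
                                                  N_CYTOKINES)[:n]
        dwin = np.lib.stride_tricks.sliding_window_view(
            d, WINDOW_LEN + 1)[:n]
        ins.append(win.copy())
        labels.append(c[WINDOW_LEN:WINDOW_LEN + n].copy())
        defs.append(dwin.copy())
        pids.append(np.full(n, pid))
        tidx.append(np.arange(n))
    if not ins:
        empty = WindowSet(
            inputs=np.zeros((0, WINDOW_LEN, N_CYTOKINES)),
            labels_next_profile=np.zeros((0, N_CYTOKINES)),
            deficits=np.zeros((0, WINDOW_LEN + 1)),
            patient_ids=np.zeros(0, dtype=int),
            t_index=np.zeros(0, dtype=int),
            shuffle_seed=shuffle_seed,
        )
        return empty
    inputs = np.concatenate(ins)
    rng = np.random.default_rng(shuffle_seed)
    perm = rng.permutation(len(inputs))
    ws = WindowSet(
        inputs=inputs[perm],
        labels_next_profile=np.concatenate(labels)[perm],
        deficits=np.concatenate(defs)[perm],
        patient_ids=np.concatenate(pids)[perm],
        t_index=np.concatenate(tidx)[perm],
        shuffle_seed=shuffle_seed,
    )
    ws.norm_stats = _compute_norm_stats(ws.inputs, ws.deficits, deficit_max)
    return ws


def exclude_early(trajectories: list[Trajectory],
                  cutoff_steps: int) -> list[Trajectory]:
    """Drop all records before ``cutoff_steps`` from every trajectory.

    The first post-injury day is dominated by the stochastic shock of the
    homogeneous insult; excluding it (default cutoff 240 steps ≈ 1 day at
    6 min/step) yields better-behaved training data. Remaining records
    are renumbered from zero; trajectories left shorter than 6 records
    simply contribute no windows downstream.
    """
    if cutoff_steps < 0:
        raise ValueError(f"cutoff_steps must be >= 0: {cutoff_steps}")
    if cutoff_steps == 0:
        return list(trajectories)
    out = []
    for traj in trajectories:
        out.append(replace(
            traj,
            cytokines=traj.cytokines[cutoff_steps:],
            oxygen_deficit=traj.oxygen_deficit[cutoff_steps:],
            checkpoints={},
        ))
    return out


def split(windowset: WindowSet, fraction: float,
          seed: int) -> tuple[WindowSet, WindowSet]:
    """Patient-level train/validation split.

    Splitting by patient id (never by window) prevents leakage between
    overlapping windows of the same trajectory. Standardization stats are
    recomputed from the training portion and attached to both halves.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1): {fraction}")
    patients = np.unique(windowset.patient_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(patients)
    n_train = int(round(fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_set = set(order[:n_train].tolist())
    mask = np.fromiter((p in train_set for p in windowset.patient_ids),
                       dtype=bool, count=len(windowset))

    def _take(m):
        return WindowSet(
            inputs=windowset.inputs[m],
            labels_next_profile=windowset.labels_next_profile[m],
            deficits=windowset.deficits[m],
            patient_ids=windowset.patient_ids[m],
            t_index=windowset.t_index[m],
            shuffle_seed=windowset.shuffle_seed,
        )

    train, val = _take(mask), _take(~mask)
    deficit_max = (windowset.norm_stats.deficit_max
                   if windowset.norm_stats is not None else 101 * 101)
    stats = _compute_norm_stats(train.inputs, train.deficits, deficit_max)
    train.norm_stats = stats
    val.norm_stats = stats
    return train, val
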