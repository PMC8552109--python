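"""On-disk formats: trajectory CSV + JSON sidecars, HDF5 batch stores,
YAML configuration, and the config hash embedded in every artifact.

Floating-point values are serialized at full double precision (``%.17g``
in CSV, native float64 in HDF5), so every write → read round-trip is
bit-exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .abm import (CYTOKINE_NAMES, InjuryParams, SimConfig, Trajectory)
from .windows import NormStats, WindowSet

__all__ = ["config_hash", "load_config", "sim_config_from_dict",
           "save_trajectory_csv", "load_trajectory_csv",
           "save_cohort_h5", "load_cohort_h5",
           "save_windows_h5", "load_windows_h5",
           "save_cone_h5", "load_cone_h5"]

_CSV_HEADER = "t," + ",".join(CYTOKINE_NAMES) + ",oxygen_deficit"


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping or dataclass."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path) -> dict:
    """Load a YAML run configuration (sections: grid, injury, agents,
    cytokines, run); missing sections fall back to defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return cfg


def sim_config_from_dict(cfg: dict) -> SimConfig:
    """Build a :class:`SimConfig` from the YAML sections."""
    grid = cfg.get("grid", {})
    agents = cfg.get("agents", {})
    cyto = cfg.get("cytokines", {})
    run = cfg.get("run", {})
    return SimConfig(
        width=int(grid.get("width", 101)),
        height=int(grid.get("height", 101)),
        n_phagocytes=int(agents.get("n_phagocytes", 30)),
        n_regulators=int(agents.get("n_regulators", 20)),
        phagocyte_bias=float(agents.get("phagocyte_bias", 0.8)),
        bystander_damage=float(agents.get("bystander_damage", 0.05)),
        env_damage=float(cfg.get("injury", {}).get("env_damage", 0.2)),
        anti_potency=float(cyto.get("anti_potency", 0.5)),
        heal_boost=float(cyto.get("heal_boost", 1.0)),
        decay=float(cyto.get("decay", 0.9)),
        diffusion=float(cyto.get("diffusion", 0.1)),
        checkpoint_stride=int(run.get("checkpoint_stride", 10)),
        max_steps=int(run.get("max_steps", 10_000)),
    )


def save_trajectory_csv(traj: Trajectory, path, cfg_hash: str = "") -> None:
    """Write ``t,c01..c11,oxygen_deficit`` CSV plus a JSON sidecar."""
    path = Path(path)
    data = np.column_stack([np.arange(len(traj)), traj.cytokines,
                            traj.oxygen_deficit])
    np.savetxt(path, data, delimiter=",", header=_CSV_HEADER, comments="",
               fmt=["%d"] + ["%.17g"] * 12)
    meta = {
        "params": dataclasses.asdict(traj.params),
        "seed": traj.seed,
        "outcome": traj.outcome,
        "branch_time": traj.branch_time,
        "grid_shape": list(traj.grid_shape),
        "config_hash": cfg_hash,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_trajectory_csv(path) -> Trajectory:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Trajectory(
        cytokines=data[:, 1:12],
        oxygen_deficit=data[:, 12],
        outcome=meta["outcome"],
        params=InjuryParams(**meta["params"]),
        seed=meta["seed"],
        branch_time=meta["branch_time"],
        grid_shape=tuple(meta["grid_shape"]),
    )


def save_cohort_h5(trajectories: list[Trajectory], path,
                   cfg_hash: str = "") -> None:
    """One HDF5 file, one group per patient."""
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = cfg_hash
        fh.attrs["n_patients"] = len(trajectories)
        for i, traj in enumerate(trajectories):
            g = fh.create_group(f"patient_{i:05d}")
            g.create_dataset("cytokines", data=traj.cytokines)
            g.create_dataset("oxygen_deficit", data=traj.oxygen_deficit)
            g.attrs["outcome"] = traj.outcome
            g.attrs["seed"] = traj.seed
            g.attrs["params"] = json.dumps(dataclasses.asdict(traj.params))
            g.attrs["grid_shape"] = traj.grid_shape
            if traj.branch_time is not None:
                g.attrs["branch_time"] = traj.branch_time


def load_cohort_h5(path) -> list[Trajectory]:
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(k for k in fh if k.startswith("patient_")):
            g = fh[name]
            out.append(Trajectory(
                cytokines=g["cytokines"][...],
                oxygen_deficit=g["oxygen_deficit"][...],
                outcome=str(g.attrs["outcome"]),
                params=InjuryParams(**json.loads(g.attrs["params"])),
                seed=int(g.attrs["seed"]),
                branch_time=(int(g.attrs["branch_time"])
                             if "branch_time" in g.attrs else None),
                grid_shape=tuple(int(x) for x in g.attrs["grid_shape"]),
            ))
    return out


def save_windows_h5(ws: WindowSet, path, cfg_hash: str = "") -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = cfg_hash
        if ws.shuffle_seed is not None:
            fh.attrs["shuffle_seed"] = ws.shuffle_seed
        fh.create_dataset("inputs", data=ws.inputs)
        fh.create_dataset("labels_next_profile", data=ws.labels_next_profile)
        fh.create_dataset("deficits", data=ws.deficits)
        fh.create_dataset("patient_ids", data=ws.patient_ids)
        fh.create_dataset("t_index", data=ws.t_index)
        if ws.norm_stats is not None:
            fh.attrs["norm_stats"] = json.dumps(ws.norm_stats.to_dict())


def load_windows_h5(path) -> WindowSet:
    with h5py.File(path, "r") as fh:
        stats = (NormStats.from_dict(json.loads(fh.attrs["norm_stats"]))
                 if "norm_stats" in fh.attrs else None)
        return WindowSet(
            inputs=fh["inputs"][...],
            labels_next_profile=fh["labels_next_profile"][...],
            deficits=fh["deficits"][...],
            patient_ids=fh["patient_ids"][...],
            t_index=fh["t_index"][...],
            norm_stats=stats,
            shuffle_seed=(int(fh.attrs["shuffle_seed"])
                          if "shuffle_seed" in fh.attrs else None),
        )


def save_cone_h5(cone, path, cfg_hash: str = "") -> None:
    from .forecast import ForecastCone  # noqa: F401  (type reference)
    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = cfg_hash
        fh.attrs["start_t"] = cone.start_t
        fh.attrs["horizon"] = cone.horizon
        fh.create_dataset("ensemble", data=cone.ensemble)
        fh.create_dataset("lower", data=cone.lower)
        fh.create_dataset("upper", data=cone.upper)
        fh.create_dataset("member_seeds", data=np.asarray(cone.member_seeds))
        if cone.p05 is not None:
            fh.create_dataset("p05", data=cone.p05)
            fh.create_dataset("p95", data=cone.p95)


def load_cone_h5(path):
    from .forecast import ForecastCone
    with h5py.File(path, "r") as fh:
        return ForecastCone(
            start_t=int(fh.attrs["start_t"]),
            horizon=int(fh.attrs["horizon"]),
            ensemble=fh["ensemble"][...],
            lower=fh["lower"][...],
            upper=fh["upper"][...],
            member_seeds=[int(s) for s in fh["member_seeds"][...]],
            p05=fh["p05"][...] if "p05" in fh else None,
            p95=fh["p95"][...] if "p95" in fh else None,
        )
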