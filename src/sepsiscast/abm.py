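"""Stochastic agent-based model of acute inflammation ("IIRABM-lite").

A deliberately minimal ABM of the endothelial-blood interface: a toroidal
grid of tissue cells carrying damage and infection, eleven diffusing
cytokine fields, and two mobile immune-agent populations (pro-inflammatory
phagocytes and anti-inflammatory regulators). A simulated patient is
defined by five injury/host parameters; the run ends at complete healing,
at death (aggregate damage above 80% of the grid), or at the step cap.

The simulator is the sole data source for the surrogate networks. Its
structural properties — activity-dependent (heteroscedastic) per-step
noise from many independent Bernoulli events, a non-unique map from the
11-dimensional cytokine profile to the aggregate oxygen deficit, and
absorbing healed/dead terminal states — are what the downstream models
must cope with, not any particular quantitative output.

Update order within one step (all random events drawn from the patient's
counter-based generator):

1. infection spreads from each infected cell to each uninfected von
   Neumann neighbour independently with probability ``virulence``;
2. cells infected at step start add ``toxigenesis`` to local damage and
   secrete pro-inflammatory cytokines; damaged tissue leaks two
   tissue-derived signals;
3. every cell takes a fixed damage increment with probability
   ``env_toxicity``;
4. phagocytes walk up the c01 (TNFα) gradient, clear infection where they
   stand, inflict small bystander damage, and secrete pro-inflammatory
   cytokines scaled down by the local anti-inflammatory factor;
5. regulators random-walk and secrete anti-inflammatory cytokines;
6. cells infected at step start resolve spontaneously with probability
   ``host_resilience`` × (local anti-inflammatory healing boost); damaged,
   uninfected cells heal fully with the same probability;
7. every cytokine field diffuses to the 4-neighbourhood and decays.

Spread and resolution both act on the snapshot of infection taken at step
start, so on a toy grid with a single infected cell the one-step
infected-count distribution is exactly Bernoulli(1 - q) + Binomial(4, p)
with p = virulence and q = host_resilience — the enumerable thought
experiment that motivates the activity-scaled noise.
"""

from __future__ import annotations

import pickle
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DESK_CONFIG",
    "TIME_STEP_MINUTES",
    "STEPS_PER_DAY",
    "InjuryParams",
    "SimConfig",
    "SimState",
    "Trajectory",
    "death_threshold",
    "initial_state",
    "step",
    "simulate_patient",
    "simulate_cohort",
    "checkpoint",
    "restore",
    "reseed_replicates",
    "CYTOKINE_NAMES",
    "N_CYTOKINES",
]

N_CYTOKINES = 11
CYTOKINE_NAMES = tuple(f"c{i:02d}" for i in range(1, 12))

#: one simulation step represents 6 minutes, so 240 steps ≈ 1 day; the
#: first post-injury day is the default early-phase exclusion window
TIME_STEP_MINUTES = 6
STEPS_PER_DAY = 24 * 60 // TIME_STEP_MINUTES

# channel roles: c01..c06 pro-inflammatory (c01 = TNFα, the chemotactic
# driver), c07..c09 anti-inflammatory, c10..c11 tissue-derived signals
PRO = slice(0, 6)
ANTI = slice(6, 9)
TISSUE = slice(9, 11)

# per-channel secretion weights by source (arbitrary concentration units);
# distinct mixes keep the 11 channels from being collinear
_INFECTION_SECRETION = np.array(
    [1.0, 0.8, 0.6, 0.5, 0.4, 0.3, 0, 0, 0, 0, 0], dtype=float)
_PHAGOCYTE_SECRETION = np.array(
    [0.6, 0.3, 0.5, 0.2, 0.4, 0.1, 0, 0, 0, 0, 0], dtype=float)
_REGULATOR_SECRETION = np.array(
    [0, 0, 0, 0, 0, 0, 1.0, 0.7, 0.5, 0, 0], dtype=float)
_DAMAGE_SECRETION = np.array(
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0.5, 0.3], dtype=float)


class ParameterError(ValueError):
    """An injury parameter is outside its admissible domain."""


@dataclass(frozen=True)
class InjuryParams:
    """The five scalar parameters defining a simulated patient's insult.

    injury_size
        Radius (grid cells) of the initially injured/infected disc.
    virulence
        Per-neighbour, per-step infection-spread probability.
    toxigenesis
        Per-step damage increment inflicted by an infected cell.
    env_toxicity
        Per-step probability that any cell takes background damage.
    host_resilience
        Per-step spontaneous healing / infection-resolution probability.
    """

    injury_size: float
    virulence: float
    toxigenesis: float
    env_toxicity: float
    host_resilience: float

    def validate(self, grid_shape=(101, 101)) -> None:
        half = min(grid_shape) / 2
        if not 0 <= self.injury_size <= half:
            raise ParameterError(
                f"injury_size must be in [0, {half}]: {self.injury_size}")
        for name in ("virulence", "toxigenesis", "env_toxicity",
                     "host_resilience"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]: {v}")


@dataclass(frozen=True)
class SimConfig:
    """Fixed simulator configuration (everything that is not the injury)."""

    width: int = 101
    height: int = 101
    n_phagocytes: int = 30
    n_regulators: int = 20
    phagocyte_bias: float = 0.8      # prob. of moving up the c01 gradient
    bystander_damage: float = 0.05   # damage a phagocyte inflicts in place
    env_damage: float = 0.2          # damage increment of a toxicity event
    anti_potency: float = 0.5        # anti-cytokine suppression strength
    heal_boost: float = 1.0          # anti-cytokine healing amplification
    decay: float = 0.9               # per-step cytokine retention factor
    diffusion: float = 0.1           # per-step 4-neighbourhood exchange rate
    checkpoint_stride: int = 10
    max_steps: int = 10_000

    @property
    def grid_shape(self):
        return (self.width, self.height)


def death_threshold(config: SimConfig) -> int:
    """Oxygen-deficit value above which the patient dies.

    Death is triggered when aggregate damage exceeds 80% of the grid, so
    the threshold is ``floor(0.8 * W * H)`` damaged-cell equivalents —
    8160 on the default 101×101 grid.
    """
    return int(np.floor(0.8 * config.width * config.height))


@dataclass
class SimState:
    """Full mutable simulator state; serializable via :func:`checkpoint`."""

    grid_damage: np.ndarray
    grid_infection: np.ndarray
    cytokine_fields: np.ndarray        # (11, W, H)
    phagocyte_pos: np.ndarray          # (P, 2) int
    regulator_pos: np.ndarray          # (R, 2) int
    t: int
    rng: np.random.Generator

    def oxygen_deficit(self) -> float:
        return float(self.grid_damage.sum())

    def cytokine_sums(self) -> np.ndarray:
        return self.cytokine_fields.sum(axis=(1, 2))


@dataclass
class Trajectory:
    """Recorded macro/micro time series of one simulated patient.

    ``cytokines`` holds whole-grid sums of each of the 11 fields per step
    (row 0 is the post-injury initial state); ``oxygen_deficit`` is the
    matching aggregate damage. Terminal states are absorbing: recording
    stops at the first healed/dead step.
    """

    cytokines: np.ndarray            # (T, 11)
    oxygen_deficit: np.ndarray       # (T,)
    outcome: str                     # healed | dead | censored
    params: InjuryParams
    seed: int
    branch_time: int | None = None
    grid_shape: tuple = (101, 101)
    checkpoints: dict = field(default_factory=dict, repr=False)

    def __len__(self):
        return len(self.oxygen_deficit)


def _make_rng(seed: int) -> np.random.Generator:
    # counter-based generator: reseeding or state capture is exact
    return np.random.Generator(np.random.Philox(seed))


def initial_state(params: InjuryParams, seed: int,
                  config: SimConfig) -> SimState:
    """Post-injury state: a homogeneous damaged+infected central disc."""
    params.validate(config.grid_shape)
    w, h = config.width, config.height
    damage = np.zeros((w, h))
    infection = np.zeros((w, h))
    if params.injury_size > 0:
        x, y = np.ogrid[:w, :h]
        disc = (x - w // 2) ** 2 + (y - h // 2) ** 2 \
            <= params.injury_size ** 2
        damage[disc] = 1.0
        infection[disc] = 1.0
    rng = _make_rng(seed)
    phag = np.column_stack([rng.integers(0, w, config.n_phagocytes),
                            rng.integers(0, h, config.n_phagocytes)]) \
        if config.n_phagocytes else np.zeros((0, 2), dtype=np.int64)
    reg = np.column_stack([rng.integers(0, w, config.n_regulators),
                           rng.integers(0, h, config.n_regulators)]) \
        if config.n_regulators else np.zeros((0, 2), dtype=np.int64)
    return SimState(
        grid_damage=damage,
        grid_infection=infection,
        cytokine_fields=np.zeros((N_CYTOKINES, w, h)),
        phagocyte_pos=phag.astype(np.int64),
        regulator_pos=reg.astype(np.int64),
        t=0,
        rng=rng,
    )


def _neighbor_sum(a: np.ndarray) -> np.ndarray:
    """Sum of the 4 toroidal von Neumann neighbours of every cell."""
    return (np.roll(a, 1, 0) + np.roll(a, -1, 0)
            + np.roll(a, 1, 1) + np.roll(a, -1, 1))


def _move_agents(pos, field_vals, bias, rng, shape):
    """Biased random walk: each agent steps to its best-of-4 neighbour
    (by ``field_vals``) with probability ``bias``, else uniformly."""
    if len(pos) == 0:
        return pos
    w, h = shape
    offsets = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])
    cand = (pos[:, None, :] + offsets[None, :, :]) % [w, h]   # (n, 4, 2)
    vals = field_vals[cand[..., 0], cand[..., 1]]             # (n, 4)
    best = vals.argmax(axis=1)
    rand = rng.integers(0, 4, size=len(pos))
    take_best = rng.random(len(pos)) < bias
    choice = np.where(take_best, best, rand)
    return cand[np.arange(len(pos)), choice]


def step(state: SimState, params: InjuryParams, config: SimConfig) -> None:
    """Advance the simulation by one step, in place."""
    rng = state.rng
    D = state.grid_damage
    I = state.grid_infection
    C = state.cytokine_fields
    shape = D.shape

    infected0 = I > 0                       # snapshot at step start
    # local anti-inflammatory factor from the previous step's fields
    anti_local = C[ANTI].sum(axis=0)
    suppression = 1.0 / (1.0 + config.anti_potency * anti_local)

    # 1. infection spread (independent Bernoulli per infected neighbour)
    n_inf_nb = _neighbor_sum(infected0.astype(float))
    p_spread = 1.0 - (1.0 - params.virulence) ** n_inf_nb
    newly = (~infected0) & (rng.random(shape) < p_spread)

    # 2. toxigenic damage and secretion from snapshot-infected cells
    if params.toxigenesis:
        np.clip(D + params.toxigenesis * infected0, 0.0, 1.0, out=D)
    C += _INFECTION_SECRETION[:, None, None] * infected0[None, :, :]
    C += _DAMAGE_SECRETION[:, None, None] * D[None, :, :]

    # 3. environmental toxicity
    if params.env_toxicity:
        hit = rng.random(shape) < params.env_toxicity
        np.clip(D + config.env_damage * hit, 0.0, 1.0, out=D)

    # 4. phagocytes: chemotax up c01, clear infection, bystander damage,
    #    suppressed pro-inflammatory secretion
    cleared = np.zeros(shape, dtype=bool)
    if len(state.phagocyte_pos):
        state.phagocyte_pos = _move_agents(
            state.phagocyte_pos, C[0], config.phagocyte_bias, rng, shape)
        px, py = state.phagocyte_pos[:, 0], state.phagocyte_pos[:, 1]
        cleared[px, py] = True
        # bystander damage and secretion only where there is something to
        # fight — an uninjured grid must remain a healthy fixed point
        engaged = (infected0 | newly)[px, py]
        np.add.at(D, (px[engaged], py[engaged]), config.bystander_damage)
        np.clip(D, 0.0, 1.0, out=D)
        sup_at = suppression[px, py] * engaged
        occ = np.zeros(shape)
        np.add.at(occ, (px, py), sup_at)
        C += _PHAGOCYTE_SECRETION[:, None, None] * occ[None, :, :]

    # 5. regulators: random walk, anti-inflammatory secretion
    if len(state.regulator_pos):
        state.regulator_pos = _move_agents(
            state.regulator_pos, D, 0.5, rng, shape)
        rx, ry = state.regulator_pos[:, 0], state.regulator_pos[:, 1]
        engaged_r = ((D > 0) | infected0 | newly)[rx, ry]
        occ = np.zeros(shape)
        np.add.at(occ, (rx[engaged_r], ry[engaged_r]), 1.0)
        C += _REGULATOR_SECRETION[:, None, None] * occ[None, :, :]

    # 6. healing: snapshot-infected cells resolve, damaged uninfected
    #    cells heal fully, both with prob resilience * (1 + boost * anti)
    p_heal = np.clip(
        params.host_resilience * (1.0 + config.heal_boost * anti_local),
        0.0, 1.0)
    heal_draw = rng.random(shape) < p_heal
    resolved = infected0 & heal_draw
    I_new = (infected0 & ~resolved) | newly
    I_new &= ~cleared
    state.grid_infection = I_new.astype(float)
    healed_cells = (~infected0) & ~newly & (D > 0) & heal_draw
    D[healed_cells] = 0.0

    # 7. cytokine diffusion and decay
    r = config.diffusion
    C *= (1.0 - r)
    C += (r / 4.0) * (np.roll(C, 1, 1) + np.roll(C, -1, 1)
                      + np.roll(C, 1, 2) + np.roll(C, -1, 2))
    C *= config.decay
    state.t += 1


def checkpoint(state: SimState) -> bytes:
    """Serialize the full state (including generator state) to a blob."""
    payload = {
        "grid_damage": state.grid_damage,
        "grid_infection": state.grid_infection,
        "cytokine_fields": state.cytokine_fields,
        "phagocyte_pos": state.phagocyte_pos,
        "regulator_pos": state.regulator_pos,
        "t": state.t,
        "rng_state": state.rng.bit_generator.state,
    }
    return zlib.compress(pickle.dumps(payload, protocol=4))


def restore(blob: bytes, new_seed: int | None = None) -> SimState:
    """Rebuild a state from :func:`checkpoint` output.

    ``new_seed`` replaces only the random-generator state (the reseeding
    used for branching replicates); by default the saved state is kept so
    that stepping continues bit-identically.
    """
    try:
        payload = pickle.loads(zlib.decompress(blob))
        rng = np.random.Generator(np.random.Philox())
        rng.bit_generator.state = payload["rng_state"]
    except Exception as exc:
        raise ValueError(f"cannot deserialize checkpoint blob: {exc}") from exc
    if new_seed is not None:
        rng = _make_rng(new_seed)
    return SimState(
        grid_damage=payload["grid_damage"].copy(),
        grid_infection=payload["grid_infection"].copy(),
        cytokine_fields=payload["cytokine_fields"].copy(),
        phagocyte_pos=payload["phagocyte_pos"].copy(),
        regulator_pos=payload["regulator_pos"].copy(),
        t=payload["t"],
        rng=rng,
    )


def _record(state: SimState):
    return state.cytokine_sums(), state.oxygen_deficit()


def _run(state: SimState, params: InjuryParams, config: SimConfig,
         max_steps: int, keep_checkpoints: bool,
         cyto_rows: list, deficit_rows: list, checkpoints: dict) -> str:
    """Step until terminal state or cap; returns the outcome label."""
    thr = death_threshold(config)
    while state.t < max_steps:
        step(state, params, config)
        c, d = _record(state)
        cyto_rows.append(c)
        deficit_rows.append(d)
        if keep_checkpoints and state.t % config.checkpoint_stride == 0:
            checkpoints[state.t] = checkpoint(state)
        if d > thr:
            return "dead"
        if d == 0.0 and state.grid_infection.sum() == 0.0:
            return "healed"
    return "censored"


def simulate_patient(params: InjuryParams, seed: int,
                     max_steps: int | None = None,
                     config: SimConfig = SimConfig(),
                     keep_checkpoints: bool = False) -> Trajectory:
    """Simulate one patient from injury to terminal state or step cap.

    Deterministic: identical ``(params, seed, max_steps, config)`` give
    bit-identical trajectories. Set ``keep_checkpoints`` to record a
    serialized state every ``config.checkpoint_stride`` steps (required
    for :func:`reseed_replicates`); off by default to bound memory.
    """
    max_steps = config.max_steps if max_steps is None else max_steps
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1: {max_steps}")
    params.validate(config.grid_shape)
    state = initial_state(params, seed, config)
    c0, d0 = _record(state)
    cyto_rows, deficit_rows = [c0], [d0]
    checkpoints = {}
    if keep_checkpoints:
        checkpoints[0] = checkpoint(state)
    outcome = _run(state, params, config, max_steps, keep_checkpoints,
                   cyto_rows, deficit_rows, checkpoints)
    return Trajectory(
        cytokines=np.array(cyto_rows),
        oxygen_deficit=np.array(deficit_rows),
        outcome=outcome,
        params=params,
        seed=int(seed),
        grid_shape=config.grid_shape,
        checkpoints=checkpoints,
    )


#: default per-patient sampling ranges for cohort generation, chosen so a
#: mid-range insult yields a mixed healed/dead/censored outcome spread
DEFAULT_PARAM_RANGES = {
    "injury_size_frac": (0.05, 0.2),     # fraction of min grid dimension
    "virulence": (0.03, 0.25),
    "toxigenesis": (0.02, 0.2),
    "env_toxicity": (0.0, 0.01),
    "host_resilience": (0.05, 0.3),
}


def sample_params(rng: np.random.Generator, config: SimConfig,
                  ranges: dict | None = None) -> InjuryParams:
    """Draw one patient's injury parameters uniformly from ``ranges``."""
    r = dict(DEFAULT_PARAM_RANGES, **(ranges or {}))
    lo, hi = r["injury_size_frac"]
    size = rng.uniform(lo, hi) * min(config.grid_shape)
    draw = {k: rng.uniform(*r[k]) for k in
            ("virulence", "toxigenesis", "env_toxicity", "host_resilience")}
    return InjuryParams(injury_size=size, **draw)


def simulate_cohort(n_patients: int, seed: int,
                    config: SimConfig = SimConfig(),
                    max_steps: int | None = None,
                    ranges: dict | None = None,
                    keep_checkpoints: bool = False) -> list[Trajectory]:
    """Simulate ``n_patients`` with per-patient parameters and seeds.

    Parameters and per-patient seeds are all derived from the single root
    ``seed``, so the whole cohort is reproducible from one integer.
    """
    root = _make_rng(seed)
    seeds = root.integers(0, 2 ** 31, size=n_patients)
    out = []
    for i in range(n_patients):
        params = sample_params(root, config, ranges)
        out.append(simulate_patient(params, int(seeds[i]), max_steps,
                                    config, keep_checkpoints))
    return out


def reseed_replicates(traj: Trajectory, branch_t: int, seeds: list,
                      params: InjuryParams | None = None,
                      config: SimConfig = SimConfig(),
                      max_steps: int | None = None) -> list[Trajectory]:
    """Branch stochastic replicates from a checkpointed trajectory.

    Each replicate copies the parent's recorded values up to and including
    ``branch_t`` and then evolves independently from the checkpointed
    state. A seed of ``None`` keeps the checkpointed generator state (the
    replicate then reproduces the parent exactly); integers reseed the
    generator for an independent continuation.
    """
    if not 0 <= branch_t < len(traj):
        raise IndexError(
            f"branch_t {branch_t} outside trajectory span [0, {len(traj)})")
    if branch_t not in traj.checkpoints:
        raise KeyError(f"no checkpoint recorded at step {branch_t}")
    params = params or traj.params
    max_steps = config.max_steps if max_steps is None else max_steps
    blob = traj.checkpoints[branch_t]
    replicates = []
    for s in seeds:
        state = restore(blob, new_seed=None if s is None else int(s))
        cyto_rows = [row for row in traj.cytokines[:branch_t + 1]]
        deficit_rows = list(traj.oxygen_deficit[:branch_t + 1])
        outcome = _run(state, params, config, max_steps, False,
                       cyto_rows, deficit_rows, {})
        replicates.append(Trajectory(
            cytokines=np.array(cyto_rows),
            oxygen_deficit=np.array(deficit_rows),
            outcome=outcome,
            params=params,
            seed=traj.seed if s is None else int(s),
            branch_time=branch_t,
            grid_shape=config.grid_shape,
        ))
    return replicates


#: desk-scale simulator configuration used by the figure-level experiment
#: scripts: a 33×33 torus keeps a 200-patient cohort tractable on one CPU
#: while preserving the model's stochastic structure (death threshold
#: floor(0.8*33*33) = 871)
DESK_CONFIG = SimConfig(width=33, height=33, n_phagocytes=12,
                        n_regulators=8, max_steps=600)
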