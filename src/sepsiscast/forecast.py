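"""Recursive rollout, horizon accuracy, and Monte-Carlo forecast cones.

The forecasting workflow mirrors the two-stage surrogate design: eleven
per-cytokine networks advance the 11-dimensional microstate one step at a
time — each predicted profile is appended to the sliding five-point
window, so after five steps the window is entirely synthetic — and the
health regressor maps every predicted profile to the scalar oxygen
deficit. Repeating the rollout with the permanent dropout layer active
yields an ensemble whose pointwise min/max envelope is the forecast cone;
re-anchoring the window on the latest true observations at every step
gives the rolling forecast.

All public entry points take and return original (de-standardized)
units; standardization uses the models' shared training statistics and
predicted concentrations are clipped at zero before re-entering the
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .abm import N_CYTOKINES, Trajectory
from .surrogates import (ConfigurationError, SurrogateModel, predict,
                         predict_stochastic)
from .windows import WINDOW_LEN, NormStats

__all__ = ["ForecastCone", "HorizonReport", "DEFAULT_HORIZONS",
           "rollout", "rollout_deficit", "horizon_mse", "regress_health",
           "make_cone", "rolling_forecast"]

logger = logging.getLogger(__name__)

#: forecast depths at which rollout accuracy is scored
DEFAULT_HORIZONS = (1, 2, 3, 4, 5, 10, 25, 50, 100)

#: default rollout length (steps predicted past the last observation)
DEFAULT_HORIZON = 100


@dataclass
class ForecastCone:
    """Ensemble of predicted health trajectories with pointwise envelope."""

    start_t: int
    horizon: int
    ensemble: np.ndarray            # (M, horizon) oxygen-deficit paths
    lower: np.ndarray               # pointwise min over members
    upper: np.ndarray               # pointwise max over members
    member_seeds: list
    cytokine_ensemble: np.ndarray | None = None   # (M, horizon, 11)
    p05: np.ndarray | None = None
    p95: np.ndarray | None = None

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass
class HorizonReport:
    """Average MSE across the 11 cytokines at each forecast depth."""

    horizons: tuple
    mse_per_horizon: np.ndarray
    n_windows: int = 0
    n_skipped: int = 0


def _shared_stats(models: list[SurrogateModel]) -> NormStats:
    stats = models[0].norm_stats
    if stats is None:
        raise ConfigurationError("models carry no norm_stats")
    for m in models[1:]:
        if m.norm_stats is None or not stats.allclose(m.norm_stats):
            raise ConfigurationError(
                "cytokine models have mismatched norm_stats")
    return stats


def _call(model, X, rng):
    if rng is None:
        return predict(model, X)
    return predict_stochastic(model, X, rng)


def _rollout_std(models, window_std, horizon, rng, stats):
    """Recursive rollout in standardized space for a batch of windows.

    ``window_std``: (M, 5, 11). Returns (M, horizon, 11) standardized
    predictions; each predicted profile is clipped at zero concentration
    (in original units) before re-entering the sliding window.
    """
    M = window_std.shape[0]
    out = np.empty((M, horizon, N_CYTOKINES))
    win = window_std.copy()
    zero_std = stats.standardize_cyto(np.zeros(N_CYTOKINES))
    for h in range(horizon):
        nxt = np.empty((M, N_CYTOKINES))
        for ch, model in enumerate(models):
            nxt[:, ch] = _call(model, win, rng)
        np.maximum(nxt, zero_std, out=nxt)    # clip at 0 concentration
        out[:, h, :] = nxt
        win = np.concatenate([win[:, 1:, :], nxt[:, None, :]], axis=1)
    return out


def rollout(cytokine_models: list[SurrogateModel], window: np.ndarray,
            horizon: int = DEFAULT_HORIZON, stochastic: bool = False,
            seed=None) -> np.ndarray:
    """Recursively predict ``horizon`` future 11-d profiles.

    ``window`` is the last five observed profiles, shape (5, 11), in
    original units; the result is (horizon, 11) in original units. With
    ``stochastic`` the permanent dropout layers stay active, masks drawn
    from ``seed``.
    """
    if len(cytokine_models) != N_CYTOKINES:
        raise ConfigurationError(
            f"need {N_CYTOKINES} cytokine models, got {len(cytokine_models)}")
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0: {horizon}")
    window = np.asarray(window, dtype=float)
    if window.shape != (WINDOW_LEN, N_CYTOKINES):
        raise ValueError(f"window must be (5, 11); got {window.shape}")
    stats = _shared_stats(cytokine_models)
    if horizon == 0:
        return np.zeros((0, N_CYTOKINES))
    rng = None
    if stochastic:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
    win_std = stats.standardize_cyto(window)[None, :, :]
    out_std = _rollout_std(cytokine_models, win_std, horizon, rng, stats)
    return stats.destandardize_cyto(out_std[0])


def rollout_deficit(model: SurrogateModel, deficit_window: np.ndarray,
                    horizon: int = DEFAULT_HORIZON, stochastic: bool = False,
                    seed=None) -> np.ndarray:
    """Recursive deficit-only rollout (Markov-chain treatment).

    ``deficit_window`` is the last five oxygen-deficit values in original
    units; returns ``horizon`` future values clipped to [0, grid size].
    """
    stats = model.norm_stats
    if stats is None:
        raise ConfigurationError("model carries no norm_stats")
    win = stats.standardize_deficit(
        np.asarray(deficit_window, dtype=float))[None, :]
    rng = None
    if stochastic:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
    out = np.empty(horizon)
    lo = stats.standardize_deficit(0.0)
    hi = stats.standardize_deficit(stats.deficit_max)
    for h in range(horizon):
        nxt = np.clip(_call(model, win, rng), lo, hi)
        out[h] = nxt[0]
        win = np.concatenate([win[:, 1:], nxt[:, None]], axis=1)
    return stats.destandardize_deficit(out)


def regress_health(regressor: SurrogateModel,
                   profiles: np.ndarray) -> np.ndarray:
    """Map K cytokine profiles (original units) to oxygen deficits.

    Standardization is handled internally; outputs are clipped to the
    physical range [0, W*H].
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != N_CYTOKINES:
        raise ValueError(
            f"profiles must be (K, {N_CYTOKINES}); got {profiles.shape}")
    if len(profiles) == 0:
        return np.zeros(0)
    stats = regressor.norm_stats
    if stats is None:
        raise ConfigurationError("regressor carries no norm_stats")
    z = predict(regressor, stats.standardize_cyto(profiles))
    return np.clip(stats.destandardize_deficit(z), 0.0, stats.deficit_max)


def horizon_mse(models: list[SurrogateModel],
                trajectories: list[Trajectory],
                horizons: tuple = DEFAULT_HORIZONS,
                stride: int = 25,
                max_windows: int | None = None) -> HorizonReport:
    """Score recursive-rollout accuracy at fixed forecast depths.

    Evaluation windows are taken every ``stride`` steps from each
    trajectory; windows without ``max(horizons)`` true future steps are
    skipped (and counted). MSE is averaged over the 11 cytokines and all
    retained windows, in standardized units so channels are commensurate.
    """
    stats = _shared_stats(models)
    H = max(horizons)
    wins, futures = [], []
    n_skipped = 0
    for traj in trajectories:
        T = len(traj)
        for t0 in range(0, T - WINDOW_LEN, stride):
            if t0 + WINDOW_LEN + H > T:
                n_skipped += 1
                continue
            wins.append(traj.cytokines[t0:t0 + WINDOW_LEN])
            futures.append(
                traj.cytokines[t0 + WINDOW_LEN:t0 + WINDOW_LEN + H])
    if n_skipped:
        logger.info("horizon_mse: skipped %d windows lacking %d future "
                    "steps", n_skipped, H)
    if max_windows is not None:
        wins, futures = wins[:max_windows], futures[:max_windows]
    if not wins:
        return HorizonReport(horizons, np.full(len(horizons), np.nan),
                             0, n_skipped)
    win_std = stats.standardize_cyto(np.stack(wins))
    fut_std = stats.standardize_cyto(np.stack(futures))
    pred_std = _rollout_std(models, win_std, H, None, stats)
    mse = np.array([
        float(np.mean((pred_std[:, h - 1, :] - fut_std[:, h - 1, :]) ** 2))
        for h in horizons
    ])
    return HorizonReport(tuple(horizons), mse, len(wins), n_skipped)


def make_cone(cytokine_models: list[SurrogateModel],
              regressor: SurrogateModel, window: np.ndarray,
              horizon: int = DEFAULT_HORIZON, M: int = 100,
              seed: int = 0, start_t: int = 0,
              stochastic: bool = True) -> ForecastCone:
    """Build a Monte-Carlo-dropout forecast cone of M ensemble members.

    Each member is an independent stochastic rollout of the cytokine
    models passed through the health regressor; the cone is the pointwise
    min/max envelope (5th/95th percentiles are stored alongside). With
    ``stochastic=False`` (dropout disabled) all members coincide and the
    cone has zero width.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1: {M}")
    stats = _shared_stats(cytokine_models)
    window = np.asarray(window, dtype=float)
    root = np.random.SeedSequence(seed)
    member_seeds = [int(s) for s in
                    np.random.default_rng(root).integers(0, 2 ** 31, M)]
    if stochastic:
        rng = np.random.default_rng(root.spawn(1)[0])
        win_std = np.repeat(stats.standardize_cyto(window)[None, :, :],
                            M, axis=0)
        cyto_std = _rollout_std(cytokine_models, win_std, horizon, rng,
                                stats)
    else:
        # without dropout all members coincide by definition; roll out
        # once and tile, so the envelope is exactly zero-width
        one = _rollout_std(cytokine_models,
                           stats.standardize_cyto(window)[None, :, :],
                           horizon, None, stats)
        cyto_std = np.repeat(one, M, axis=0)
    cyto = stats.destandardize_cyto(cyto_std)
    flat = cyto.reshape(-1, N_CYTOKINES)
    deficits = regress_health(regressor, flat).reshape(M, horizon)
    return ForecastCone(
        start_t=start_t,
        horizon=horizon,
        ensemble=deficits,
        lower=deficits.min(axis=0),
        upper=deficits.max(axis=0),
        member_seeds=member_seeds,
        cytokine_ensemble=cyto,
        p05=np.percentile(deficits, 5, axis=0),
        p95=np.percentile(deficits, 95, axis=0),
    )


def rolling_forecast(cytokine_models: list[SurrogateModel],
                     regressor: SurrogateModel, true_trajectory: Trajectory,
                     start_t: int, horizon: int = DEFAULT_HORIZON,
                     M: int = 100, seed: int = 0) -> list[ForecastCone]:
    """Re-anchored forecast cones along a true trajectory.

    The cone anchored at step ``t`` uses the true observations
    ``t-5 .. t-1`` (never stale predictions) and predicts steps ``t``
    onward; one cone is produced for every step from ``start_t`` to the
    recorded end of the trajectory.
    """
    if start_t < WINDOW_LEN:
        raise ValueError(
            f"start_t must be >= {WINDOW_LEN} (five observations needed); "
            f"got {start_t}")
    T = len(true_trajectory)
    if start_t >= T:
        raise ValueError(f"start_t {start_t} beyond trajectory end {T - 1}")
    cones = []
    for k, t in enumerate(range(start_t, T)):
        window = true_trajectory.cytokines[t - WINDOW_LEN:t]
        cones.append(make_cone(cytokine_models, regressor, window,
                               horizon=horizon, M=M, seed=seed + k,
                               start_t=t))
    return cones
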