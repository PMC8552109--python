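"""Rollout mechanics, horizon scoring, health regression, cones, and the
rolling forecast — validated against closed-form stub predictors."""

import numpy as np
import pytest

from sepsiscast import forecast
from sepsiscast.forecast import (DEFAULT_HORIZONS, make_cone, regress_health,
                                 rolling_forecast, rollout, horizon_mse)
from sepsiscast.surrogates import ConfigurationError
from conftest import (identity_stats, increment_stubs, last_value_stubs,
                      stub_model, synthetic_trajectory)


@pytest.fixture
def window():
    # positive values keep the zero-concentration clip inactive
    return 10.0 + np.arange(55, dtype=float).reshape(5, 11)


class TestRollout:
    def test_horizon_zero_is_empty(self, window):
        out = rollout(last_value_stubs(), window, horizon=0)
        assert out.shape == (0, 11)

    def test_last_value_stub_gives_constant_continuation(self, window):
        out = rollout(last_value_stubs(), window, horizon=12)
        assert np.allclose(out, np.tile(window[-1], (12, 1)))

    def test_increment_stub_gives_arithmetic_progression(self, window):
        # hand-derived: channel value at horizon h = last obs + h
        out = rollout(increment_stubs(1.0), window, horizon=7)
        for h in range(7):
            assert np.allclose(out[h], window[-1] + (h + 1))

    def test_wrong_model_count_rejected(self, window):
        with pytest.raises(ConfigurationError, match="11"):
            rollout(last_value_stubs()[:5], window, horizon=3)

    def test_mismatched_norm_stats_rejected(self, window):
        stubs = last_value_stubs()
        other = identity_stats()
        other = type(other)(cyto_mean=np.ones(11) * 5,
                            cyto_std=np.ones(11),
                            deficit_mean=0.0, deficit_std=1.0,
                            deficit_max=1089.0)
        stubs[3].norm_stats = other
        with pytest.raises(ConfigurationError, match="norm_stats"):
            rollout(stubs, window, horizon=2)

    def test_negative_predictions_clipped_at_zero(self, window):
        stubs = [stub_model(lambda x, c=c: x[:, -1, c] - 1e6, channel=c)
                 for c in range(11)]
        out = rollout(stubs, window, horizon=3)
        assert np.all(out == 0.0)

    def test_default_rollout_depth_is_100_steps(self):
        import inspect
        assert forecast.DEFAULT_HORIZON == 100
        sig = inspect.signature(rollout)
        assert sig.parameters["horizon"].default == 100


class TestHorizonMse:
    def _linear_trajs(self, n=3, T=160):
        # exactly linear-in-time channels: the +1 stub predicts perfectly
        out = []
        for i in range(n):
            t = synthetic_trajectory(T, pid=i)
            t.cytokines = (10.0 + np.arange(T, dtype=float)[:, None]
                           + np.arange(11)[None, :])
            out.append(t)
        return out

    def test_perfect_predictions_give_zero_report(self):
        trajs = self._linear_trajs()
        rep = horizon_mse(increment_stubs(1.0), trajs,
                          horizons=(1, 2, 5, 10), stride=30)
        assert rep.n_windows > 0
        assert np.allclose(rep.mse_per_horizon, 0.0)

    def test_constant_offset_gives_c_squared_everywhere(self):
        trajs = []
        for i in range(2):
            t = synthetic_trajectory(130, pid=i)
            t.cytokines = np.full((130, 11), 50.0)
            trajs.append(t)
        c = 0.75
        stubs = [stub_model(lambda x, ch=ch: np.full(len(x), 50.0 + c),
                            channel=ch) for ch in range(11)]
        rep = horizon_mse(stubs, trajs, horizons=(1, 3, 9), stride=40)
        assert np.allclose(rep.mse_per_horizon, c * c)

    def test_windows_without_future_are_skipped_and_counted(self):
        trajs = self._linear_trajs(n=1, T=40)
        rep = horizon_mse(increment_stubs(1.0), trajs, horizons=(1, 100),
                          stride=10)
        assert rep.n_windows == 0
        assert rep.n_skipped > 0

    def test_reported_horizons_match_the_standard_ladder(self):
        assert DEFAULT_HORIZONS == (1, 2, 3, 4, 5, 10, 25, 50, 100)


class TestRegressHealth:
    def test_empty_input_gives_empty_output(self):
        reg = stub_model(lambda x: x.sum(axis=1),
                         kind="health_regressor")
        assert regress_health(reg, np.zeros((0, 11))).shape == (0,)

    def test_negative_outputs_clipped_to_zero(self):
        reg = stub_model(lambda x: np.full(len(x), -50.0),
                         kind="health_regressor")
        out = regress_health(reg, np.ones((4, 11)))
        assert np.all(out == 0.0)

    def test_outputs_clipped_to_grid_scale(self):
        reg = stub_model(lambda x: np.full(len(x), 1e9),
                         kind="health_regressor")
        out = regress_health(reg, np.ones((4, 11)))
        assert np.all(out == 1089.0)

    def test_wrong_channel_count_rejected(self):
        reg = stub_model(lambda x: x.sum(axis=1),
                         kind="health_regressor")
        with pytest.raises(ValueError, match="profiles"):
            regress_health(reg, np.zeros((3, 7)))


class TestMakeCone:
    def _models(self):
        rng = np.random.default_rng(0)

        def noisy(x, c):
            return x[:, -1, c]

        stubs = last_value_stubs()
        reg = stub_model(lambda x: x.sum(axis=1), kind="health_regressor")
        return stubs, reg

    def test_single_member_degenerates(self, window):
        stubs, reg = self._models()
        cone = make_cone(stubs, reg, window, horizon=6, M=1, seed=0)
        assert np.array_equal(cone.lower, cone.upper)
        assert cone.ensemble.shape == (1, 6)

    def test_dropout_disabled_gives_zero_width(self, window):
        stubs, reg = self._models()
        cone = make_cone(stubs, reg, window, horizon=5, M=20, seed=0,
                         stochastic=False)
        assert np.all(cone.width == 0.0)
        det = regress_health(reg, rollout(stubs, window, horizon=5))
        assert np.allclose(cone.lower, det)

    def test_envelope_is_exact_columnwise_min_max(self, window):
        # per-sample dropout-like noise via a stochastic stub
        def jitter(x, c):
            return x[:, -1, c] + 0.01 * np.sin(x[:, :, c].sum(axis=1))

        stubs = [stub_model(lambda x, c=c: jitter(x, c), channel=c)
                 for c in range(11)]

        class _Noisy:
            def __init__(self, inner):
                self.inner = inner

            def forward(self, x, rng=None):
                out = self.inner.forward(x)
                if rng is not None:
                    out = out + rng.normal(0, 0.1, size=out.shape)
                return out

        for s in stubs:
            s.net = _Noisy(s.net)
        reg = stub_model(lambda x: x.sum(axis=1), kind="health_regressor")
        cone = make_cone(stubs, reg, window, horizon=4, M=30, seed=3)
        assert np.array_equal(cone.lower, cone.ensemble.min(axis=0))
        assert np.array_equal(cone.upper, cone.ensemble.max(axis=0))
        assert np.all(cone.lower <= cone.upper)

    def test_same_seed_reproduces_cone(self, window):
        stubs, reg = self._models()
        a = make_cone(stubs, reg, window, horizon=5, M=10, seed=11)
        b = make_cone(stubs, reg, window, horizon=5, M=10, seed=11)
        assert np.array_equal(a.ensemble, b.ensemble)
        assert a.member_seeds == b.member_seeds

    def test_m_below_one_rejected(self, window):
        stubs, reg = self._models()
        with pytest.raises(ValueError, match="M"):
            make_cone(stubs, reg, window, horizon=3, M=0)


class TestRollingForecast:
    def _setup(self, T=12):
        traj = synthetic_trajectory(T)
        traj.cytokines = 10.0 + traj.cytokines / 1000.0
        stubs = last_value_stubs()
        reg = stub_model(lambda x: x.sum(axis=1), kind="health_regressor")
        return traj, stubs, reg

    def test_one_cone_per_step_to_trajectory_end(self):
        traj, stubs, reg = self._setup(T=12)
        cones = rolling_forecast(stubs, reg, traj, start_t=5, horizon=4,
                                 M=2, seed=0)
        assert len(cones) == 12 - 5
        assert [c.start_t for c in cones] == list(range(5, 12))

    def test_trajectory_ending_at_start_gives_single_cone(self):
        traj, stubs, reg = self._setup(T=6)
        cones = rolling_forecast(stubs, reg, traj, start_t=5, horizon=3,
                                 M=2, seed=0)
        assert len(cones) == 1

    def test_cones_anchor_on_true_observations(self):
        traj, stubs, reg = self._setup(T=10)
        cones = rolling_forecast(stubs, reg, traj, start_t=5, horizon=1,
                                 M=1, seed=0)
        for c in cones:
            # last-value stub: prediction equals the true profile at t-1
            expected = regress_health(
                reg, traj.cytokines[c.start_t - 1][None, :])
            assert np.allclose(c.ensemble[0, 0], expected[0])

    def test_start_before_five_observations_rejected(self):
        traj, stubs, reg = self._setup()
        with pytest.raises(ValueError, match="start_t"):
            rolling_forecast(stubs, reg, traj, start_t=4, horizon=2, M=1)
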