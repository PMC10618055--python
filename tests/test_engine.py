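"""Configuration, the monthly loop, determinism and checkpointing."""

import numpy as np
import pandas as pd
import pytest

from foragersim import culture as cult
from foragersim.engine import (Simulation, SimulationConfig, SystemState,
                               landscape_windows, replay_cultural_history,
                               run_simulation)
from foragersim.landscape import TimeMap, generate_synthetic_landscape


def small_config(**overrides):
    cfg = SimulationConfig(
        N0=40, horizon_months=240, seed=5,
        landscape={"kind": "synthetic", "shape": [40, 40], "cell_size": 5.0,
                   "n_slices": 2, "smoothness": 40.0, "seed": 99,
                   "slice_years": 20.0},
        traj_stride_months=12, metrics_stride_months=12)
    return cfg.replace(**overrides)


class TestConfig:
    def test_yaml_roundtrip_uses_published_symbols(self, tmp_path):
        cfg = small_config(lam=0.03, phi1=0.08)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(path))
        text = path.read_text()
        for key in ("r_f", "N0", "h_fus", "h_fis", "gamma", "lambda",
                    "rho_d", "rho_g", "phi1", "phi2", "r1", "r2", "sigma",
                    "dt"):
            assert f"{key}:" in text
        cfg2 = SimulationConfig.from_yaml(str(path))
        assert cfg2 == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({"not_a_parameter": 1})


class TestInitialize:
    def test_progressive_statuses_start_at_floor(self):
        sim = Simulation(small_config())
        state = sim.initialize()
        assert len(state.agents) == 40
        assert np.all(state.agents.statuses == 0)

    def test_nonprogressive_statuses_random_in_range(self):
        sim = Simulation(small_config(mode="non-progressive", Q=4))
        state = sim.initialize()
        assert state.agents.statuses.min() >= 0
        assert state.agents.statuses.max() < 4
        assert len(np.unique(state.agents.statuses, axis=0)) > 1

    def test_populations_between_thresholds(self):
        state = Simulation(small_config()).initialize()
        assert np.all(state.agents.populations >= 18.0)
        assert np.all(state.agents.populations <= 60.0)

    def test_same_seed_identical_initial_state(self):
        a = Simulation(small_config()).initialize()
        b = Simulation(small_config()).initialize()
        np.testing.assert_array_equal(a.agents.positions, b.agents.positions)
        np.testing.assert_array_equal(a.agents.populations,
                                      b.agents.populations)
        assert a.rng_mobility.bit_generator.state == \
            b.rng_mobility.bit_generator.state


class TestStep:
    def test_quiescent_step_changes_only_time(self):
        """All rates zero, sigma 0, flat landscape: nothing moves."""
        cfg = small_config(sigma=0.0, gamma=0.0, lam=0.0, phi1=0.0,
                           phi2=0.0, rho_g=0.0, rho_d=0.0, N0=1)
        sim = Simulation(cfg)
        L = sim.L
        L.suitability[:] = 0.5          # flat: zero drift
        state = sim.initialize()
        pos0 = state.agents.positions.copy()
        pop0 = state.agents.populations.copy()
        sim.step()
        assert state.t_months == 1.0
        np.testing.assert_array_equal(state.agents.positions, pos0)
        np.testing.assert_array_equal(state.agents.populations, pop0)

    def test_extinction_terminates_cleanly(self):
        cfg = small_config(N0=2, rho_d=0.5, horizon_months=60)
        sim = Simulation(cfg)
        state = sim.initialize()
        # isolated, starving camps beyond the fusion radius of each other
        state.agents.positions[:] = [[10.0, 10.0], [150.0, 150.0]]
        state.agents.populations[:] = 19.0
        # force the decline branch by exceeding capacity
        sim.L.suitability[:] = 0.01
        res = sim.run()
        assert res.final_state.extinct
        assert len(res.final_state.agents) == 0


class TestRun:
    def test_full_run_determinism(self):
        r1 = run_simulation(small_config())
        r2 = run_simulation(small_config())
        pd.testing.assert_frame_equal(r1.trajectory, r2.trajectory)
        pd.testing.assert_frame_equal(r1.moves, r2.moves)
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)
        assert [e.__dict__ for e in r1.cultural_events] == \
            [e.__dict__ for e in r2.cultural_events]

    def test_horizon_zero_only_initial_state(self):
        res = run_simulation(small_config(horizon_months=0))
        assert res.metrics["t"].tolist() == [0.0]
        assert set(res.trajectory["t"]) == {0.0}

    def test_population_ledger_reconciles(self):
        res = run_simulation(small_config(horizon_months=360))
        ledger = res.population_ledger()
        assert abs(ledger["residual"]) < 1e-6 * max(ledger["initial"], 1.0)

    def test_event_log_replay_matches_final_statuses(self):
        res = run_simulation(small_config(
            horizon_months=360, gamma=0.01, lam=0.02, phi1=0.1, phi2=0.01))
        assert len(res.cultural_events) > 0
        replayed = replay_cultural_history(res)
        final = res.final_state.agents
        assert set(replayed) == set(int(g) for g in final.ids)
        for g, s in zip(final.ids, final.statuses):
            np.testing.assert_array_equal(replayed[int(g)], s)

    def test_run_writes_csv_outputs(self, tmp_path):
        res = run_simulation(small_config(horizon_months=24))
        res.write(str(tmp_path))
        for name in ("trajectory.csv", "moves.csv", "cultural_events.csv",
                     "demographic_events.csv", "metrics.csv", "config.yaml"):
            assert (tmp_path / name).exists()
        traj = pd.read_csv(tmp_path / "trajectory.csv")
        assert {"t", "agent_id", "x", "y", "population",
                "s_0", "s_1", "s_2"} <= set(traj.columns)


class TestCheckpoint:
    def test_checkpoint_resume_bit_exact(self, tmp_path):
        cfg = small_config(horizon_months=120)
        sim = Simulation(cfg)
        sim.initialize()
        for _ in range(60):
            sim.step()
        path = tmp_path / "state.json"
        sim.state.save(str(path))
        # continue the original
        for _ in range(60):
            sim.step()
        # resume a fresh simulation from the checkpoint
        sim2 = Simulation(cfg)
        sim2.restore(SystemState.load(str(path)))
        for _ in range(60):
            sim2.step()
        a, b = sim.state.agents, sim2.state.agents
        np.testing.assert_array_equal(a.ids, b.ids)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.populations, b.populations)
        np.testing.assert_array_equal(a.statuses, b.statuses)
        assert sim.state.rng_mobility.bit_generator.state == \
            sim2.state.rng_mobility.bit_generator.state


class TestCapacityBound:
    def test_total_population_bounded_by_landscape_capacity(self):
        """An overcrowded start declines until the landscape-wide
        integrated carrying capacity bounds the total population."""
        import numpy as np
        from foragersim import landscape as land
        layers = np.ones((1, 20, 20))
        L = land.SuitabilityLandscape((0, 0), 10.0, layers,
                                      np.array([[120_000.0, 0.0]]))
        cfg = SimulationConfig(N0=120, horizon_months=900, seed=1,
                               gamma=0.0, lam=0.0, phi1=0.0, phi2=0.0,
                               log_cultural_events=False)
        sim = Simulation(cfg, landscape=L)
        sim.initialize()
        initial = sim.state.agents.total_population
        for _ in range(900):
            sim.step()
        k_tot = cfg.kappa * 200.0 * 200.0
        final = sim.state.agents.total_population
        assert final < initial
        assert final <= 1.1 * k_tot


class TestWindows:
    def test_windows_follow_slice_boundaries(self):
        L = generate_synthetic_landscape((20, 20), 5.0, 3, 20.0, seed=1,
                                         slice_years=100.0)
        win = landscape_windows(L, TimeMap(120_000.0), 3_000.0)
        assert win == [(0.0, 1_200.0), (1_200.0, 2_400.0),
                       (2_400.0, 3_000.0)]
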