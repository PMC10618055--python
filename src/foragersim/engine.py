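"""Simulation engine: configuration, the monthly loop and run products.

Each monthly step executes, in fixed order:

1. refresh the landscape slice if a slice boundary was crossed (the
   carrying-capacity grid is recomputed only then);
2. Euler-Maruyama move of all camps, logging residential moves (>= 2 km);
3. rebuild of the distance-banded interaction network;
4. a Gillespie window of cultural events at the new positions;
5. demographic update against local carrying capacity;
6. fission of camps above the fission threshold;
7. fusion/extinction of camps below the fusion threshold.

The order is a documented convention: the network used for cultural
exchange reflects post-move positions, and fission/fusion act on
post-growth populations.  A run is fully deterministic given (config,
seed); mobility and culture consume independent random streams derived
from the seed, so disabling one subsystem does not perturb the other.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import culture as cult
from . import demography as demo
from . import landscape as land
from . import metrics as metr
from . import mobility as mob
from .agents import AgentSet

#: YAML keys follow the published parameter-table symbols where one exists.
_YAML_KEYS = {"lam": "lambda"}
_ATTR_KEYS = {v: k for k, v in _YAML_KEYS.items()}


@dataclass
class SimulationConfig:
    # demographic / interaction parameter-table values
    r_f: float = 20.0          # foraging radius, km
    N0: int = 300              # starting number of agents
    h_fus: float = 18.0        # fusion threshold, people
    h_fis: float = 60.0        # fission threshold, people
    gamma: float = 1e-4        # innovation / switch rate, month^-1
    lam: float = 0.02          # loss rate (progressive), month^-1
    rho_d: float = 0.001       # population decline rate, month^-1
    rho_g: float = 0.001       # population growth rate, month^-1
    phi1: float = 0.02         # short-range adoption rate, month^-1
    phi2: float = 0.002        # long-range adoption rate, month^-1
    r1: float = 20.0           # short-range interaction radius, km
    r2: float = 50.0           # long-range interaction radius, km
    sigma: float = 0.4         # random force scaling, km month^-1/2
    dt: float = 1.0            # time-step size, months

    # culture system
    mode: str = cult.PROGRESSIVE
    c: int = 3
    Q: int = 16

    # landscape scaling
    w_env: float = 1.0
    kappa: float = 0.25
    barrier_sigma_floor: float = 0.05

    # interaction-force shape
    d_rep: float = 10.0
    a_rep: float = 5.0
    l_rep: float = 5.0
    a_att: float = 5.0
    l_att: float = 25.0
    f_max: float = 2.0
    move_threshold: float = 2.0

    # run control
    N0_population_range: tuple[float, float] | None = None  # default (h_fus, h_fis)
    horizon_months: int = 12_000
    seed: int = 0
    start_bp: float = 120_000.0
    burn_in_months: int = 0
    traj_stride_months: int = 12
    metrics_stride_months: int = 120
    log_cultural_events: bool = True
    landscape: dict = field(default_factory=lambda: {
        "kind": "synthetic", "shape": [100, 100], "cell_size": 5.0,
        "n_slices": 4, "smoothness": 60.0, "seed": 1234,
    })

    # -- parameter-group views -------------------------------------------
    def landscape_params(self) -> land.LandscapeParams:
        return land.LandscapeParams(w_env=self.w_env, kappa=self.kappa,
                                    sigma0=self.sigma,
                                    barrier_sigma_floor=self.barrier_sigma_floor)

    def mobility_params(self) -> mob.MobilityParams:
        return mob.MobilityParams(d_rep=self.d_rep, a_rep=self.a_rep,
                                  l_rep=self.l_rep, a_att=self.a_att,
                                  l_att=self.l_att,
                                  attraction_cutoff=self.r2, dt=self.dt,
                                  move_threshold=self.move_threshold,
                                  f_max=self.f_max)

    def demography_params(self) -> demo.DemographyParams:
        return demo.DemographyParams(rho_g=self.rho_g, rho_d=self.rho_d,
                                     h_fis=self.h_fis, h_fus=self.h_fus,
                                     r_f=self.r_f)

    def culture_params(self) -> cult.CultureParams:
        return cult.CultureParams(mode=self.mode, c=self.c, gamma=self.gamma,
                                  lam=self.lam, phi1=self.phi1, phi2=self.phi2,
                                  r1=self.r1, r2=self.r2, Q=self.Q)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            out[_YAML_KEYS.get(f.name, f.name)] = getattr(self, f.name)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in data.items():
            name = _ATTR_KEYS.get(key, key)
            if name not in known:
                raise ValueError(f"unknown configuration key {key!r}")
            kwargs[name] = val
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def build_landscape(spec: dict) -> land.SuitabilityLandscape:
    """Construct a landscape from a config ``landscape`` block."""
    spec = dict(spec)
    kind = spec.pop("kind", "synthetic")
    if kind == "synthetic":
        barrier = spec.pop("barrier", None)
        if isinstance(barrier, dict):
            barrier = land.BarrierSpec(**barrier)
        return land.generate_synthetic_landscape(
            shape=tuple(spec.pop("shape", (100, 100))),
            cell_size=float(spec.pop("cell_size", 5.0)),
            n_slices=int(spec.pop("n_slices", 4)),
            smoothness=float(spec.pop("smoothness", 60.0)),
            barrier=barrier, seed=int(spec.pop("seed", 0)), **spec)
    if kind == "files":
        return land.load_landscape(spec["rasters"], spec["time_index"],
                                   spec.get("friction"))
    raise ValueError(f"unknown landscape kind {kind!r}")


# ---------------------------------------------------------------------------
# system state
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


@dataclass
class SystemState:
    t_months: float
    agents: AgentSet
    rng_mobility: np.random.Generator
    rng_culture: np.random.Generator
    slice_index: int = -1
    agent_months: float = 0.0
    growth_delta: float = 0.0
    extinction_loss: float = 0.0
    initial_population: float = 0.0
    extinct: bool = False

    def to_dict(self) -> dict:
        a = self.agents
        return {
            "version": CHECKPOINT_VERSION,
            "t_months": self.t_months,
            "ids": a.ids.tolist(),
            "positions": a.positions.tolist(),
            "populations": a.populations.tolist(),
            "statuses": a.statuses.tolist(),
            "next_id": a._next_id,
            "rng_mobility": self.rng_mobility.bit_generator.state,
            "rng_culture": self.rng_culture.bit_generator.state,
            "slice_index": self.slice_index,
            "agent_months": self.agent_months,
            "growth_delta": self.growth_delta,
            "extinction_loss": self.extinction_loss,
            "initial_population": self.initial_population,
            "extinct": self.extinct,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemState":
        if d.get("version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        agents = AgentSet(np.array(d["ids"], dtype=np.int64),
                          np.array(d["positions"], dtype=float).reshape(-1, 2),
                          np.array(d["populations"], dtype=float),
                          np.array(d["statuses"], dtype=np.int64).reshape(
                              len(d["ids"]), -1))
        agents._next_id = int(d["next_id"])
        rng_m = np.random.default_rng()
        rng_m.bit_generator.state = d["rng_mobility"]
        rng_c = np.random.default_rng()
        rng_c.bit_generator.state = d["rng_culture"]
        return cls(t_months=d["t_months"], agents=agents,
                   rng_mobility=rng_m, rng_culture=rng_c,
                   slice_index=d["slice_index"],
                   agent_months=d["agent_months"],
                   growth_delta=d["growth_delta"],
                   extinction_loss=d["extinction_loss"],
                   initial_population=d["initial_population"],
                   extinct=d["extinct"])

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "SystemState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimResult:
    config: SimulationConfig
    trajectory: pd.DataFrame          # sampled per-agent states
    moves: pd.DataFrame
    cultural_events: list[cult.CulturalEvent]
    demographic_events: pd.DataFrame
    metrics: pd.DataFrame
    agent_months: float
    final_state: SystemState
    initial_statuses: np.ndarray
    initial_ids: np.ndarray

    def mobility_summary(self) -> tuple[float, float, float]:
        return mob.mobility_stats(self.moves, self.agent_months)

    def population_ledger(self) -> dict[str, float]:
        """Exact people accounting: initial + growth - extinctions = final."""
        s = self.final_state
        return {
            "initial": s.initial_population,
            "net_growth": s.growth_delta,
            "extinction_loss": s.extinction_loss,
            "final": s.agents.total_population,
            "residual": (s.initial_population + s.growth_delta
                         - s.extinction_loss - s.agents.total_population),
        }

    def write(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        self.trajectory.to_csv(os.path.join(directory, "trajectory.csv"),
                               index=False)
        self.moves.to_csv(os.path.join(directory, "moves.csv"), index=False)
        cult.cultural_events_to_frame(self.cultural_events).to_csv(
            os.path.join(directory, "cultural_events.csv"), index=False)
        self.demographic_events.to_csv(
            os.path.join(directory, "demographic_events.csv"), index=False)
        self.metrics.to_csv(os.path.join(directory, "metrics.csv"), index=False)
        self.config.to_yaml(os.path.join(directory, "config.yaml"))


# ---------------------------------------------------------------------------
# the simulation proper
# ---------------------------------------------------------------------------

class Simulation:
    """One model run on a (possibly supplied) suitability landscape."""

    def __init__(self, config: SimulationConfig,
                 landscape: land.SuitabilityLandscape | None = None):
        self.config = config
        self.L = landscape if landscape is not None else build_landscape(
            config.landscape)
        self.timemap = land.TimeMap(config.start_bp)
        self.lparams = config.landscape_params()
        self.mparams = config.mobility_params()
        self.dparams = config.demography_params()
        self.cparams = config.culture_params()
        self.field = mob.LandscapeField(self.L, self.lparams, self.timemap)
        self.state: SystemState | None = None
        self._K_grid: np.ndarray | None = None
        self._reset_logs()

    def _reset_logs(self) -> None:
        self._traj_rows: list[tuple] = []
        self._moves: list[mob.MoveEvent] = []
        self._cultural: list[cult.CulturalEvent] = []
        self._demographic: list[demo.DemographicEvent] = []
        self._metrics_rows: list[tuple] = []
        self._initial_statuses: np.ndarray | None = None
        self._initial_ids: np.ndarray | None = None

    # -- initialization ---------------------------------------------------
    def initialize(self) -> SystemState:
        """Place N0 camps from the suitability equilibrium of the first slice.

        Progressive statuses start at the floor (all zero); non-progressive
        statuses are uniform over {0..Q-1}^c.  Camp populations are drawn
        uniformly between the fusion and fission thresholds.  An optional
        cultural/demographic burn-in runs on the frozen initial landscape
        before the logged study period begins.
        """
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        s_init, s_mob, s_cul = ss.spawn(3)
        rng_init = np.random.default_rng(s_init)
        pos = land.sample_equilibrium_positions(self.L, cfg.start_bp, cfg.N0,
                                                rng_init)
        lo, hi = cfg.N0_population_range or (cfg.h_fus, cfg.h_fis)
        pops = rng_init.uniform(lo, hi, size=cfg.N0)
        if cfg.mode == cult.PROGRESSIVE:
            statuses = np.zeros((cfg.N0, cfg.c), dtype=np.int64)
        else:
            statuses = rng_init.integers(0, cfg.Q, size=(cfg.N0, cfg.c))
        agents = AgentSet(np.arange(cfg.N0), pos, pops, statuses)
        self.state = SystemState(
            t_months=0.0, agents=agents,
            rng_mobility=np.random.default_rng(s_mob),
            rng_culture=np.random.default_rng(s_cul),
            initial_population=agents.total_population)
        self._reset_logs()
        if cfg.burn_in_months > 0:
            for _ in range(int(cfg.burn_in_months / cfg.dt)):
                if not len(self.state.agents):
                    break
                self.step(log=False, freeze_landscape=True)
            # burn-in happens "before" the study period
            st = self.state
            st.t_months = 0.0
            st.agent_months = 0.0
            st.growth_delta = 0.0
            st.extinction_loss = 0.0
            st.initial_population = st.agents.total_population
            self._reset_logs()
        self._initial_statuses = self.state.agents.statuses.copy()
        self._initial_ids = self.state.agents.ids.copy()
        return self.state

    def restore(self, state: SystemState) -> None:
        """Resume from a checkpoint (bit-exact continuation)."""
        self.state = state
        self.state.slice_index = -1        # force K-grid refresh
        if self._initial_statuses is None:
            self._initial_statuses = state.agents.statuses.copy()
            self._initial_ids = state.agents.ids.copy()

    def _refresh_slice(self, t_bp: float) -> None:
        k = self.L.slice_index(t_bp)
        if k != self.state.slice_index:
            self.state.slice_index = k
            self._K_grid = land.carrying_capacity_grid(
                self.L, self.lparams, k, self.config.r1)

    def _capacity_at(self, positions: np.ndarray) -> np.ndarray:
        row, col, inside = self.L.cell_of(positions)
        K = self._K_grid[row, col]
        return np.where(inside, K, 0.0)

    # -- the monthly step -------------------------------------------------
    def step(self, log: bool = True, freeze_landscape: bool = False) -> None:
        cfg, st = self.config, self.state
        if not len(st.agents):
            st.extinct = True
            return
        t = st.t_months
        t_eff = 0.0 if freeze_landscape else t
        # (1) landscape slice
        self._refresh_slice(float(self.timemap.to_bp(t_eff)))
        agents = st.agents
        n = len(agents)
        # (2) movement
        prev = agents.positions
        dist = mob.pairwise_distances(prev)
        new_pos = mob.em_step(prev, self.field, self.mparams, t_eff,
                              st.rng_mobility, ids=agents.ids, dist=dist)
        if log:
            self._moves.extend(mob.record_moves(prev, new_pos, agents.ids, t,
                                                cfg.move_threshold))
        agents.positions = new_pos
        st.agent_months += n * cfg.dt
        # (3) interaction network at post-move positions
        dist = mob.pairwise_distances(new_pos)
        A = cult.network_from_distances(dist, cfg.r1, cfg.r2, cfg.phi1,
                                        cfg.phi2)
        # (4) cultural events within the step
        events = cult.gillespie_window(
            agents.statuses, A, self.cparams, t, cfg.dt, st.rng_culture,
            ids=agents.ids,
            collect_events=log and cfg.log_cultural_events)
        if log and cfg.log_cultural_events:
            self._cultural.extend(events)
        # (5) demographic update
        local = demo.local_population(new_pos, agents.populations, cfg.r_f,
                                      dist=dist)
        K = self._capacity_at(new_pos)
        before = agents.populations.sum()
        agents.populations = demo.update_populations(
            agents.populations, local, K, self.dparams, cfg.dt)
        st.growth_delta += agents.populations.sum() - before
        # (6) fission, (7) fusion/extinction — stamped at the end of the
        # month, after the cultural window they follow
        fis = demo.apply_fission(agents, cfg.h_fis, t=t + cfg.dt)
        fus = demo.apply_fusion(agents, cfg.h_fus, cfg.r2,
                                culture_mode=cfg.mode, t=t + cfg.dt)
        if log:
            self._demographic.extend(fis)
            self._demographic.extend(fus)
        st.extinction_loss += sum(e.population for e in fus
                                  if e.kind == "extinction")
        st.t_months = t + cfg.dt
        if not len(agents):
            st.extinct = True

    # -- logging ----------------------------------------------------------
    def _record_trajectory(self) -> None:
        st = self.state
        for k in range(len(st.agents)):
            self._traj_rows.append((
                st.t_months, int(st.agents.ids[k]),
                st.agents.positions[k, 0], st.agents.positions[k, 1],
                st.agents.populations[k], *st.agents.statuses[k]))

    def _record_metrics(self) -> None:
        st = self.state
        if not len(st.agents):
            return
        row = [st.t_months, len(st.agents), st.agents.total_population,
               metr.simpson_diversity(st.agents.statuses)]
        if self.config.mode == cult.PROGRESSIVE:
            row.extend(metr.mean_complexity(st.agents.statuses))
        self._metrics_rows.append(tuple(row))

    def _build_result(self) -> SimResult:
        cfg = self.config
        traj_cols = (["t", "agent_id", "x", "y", "population"]
                     + [f"s_{i}" for i in range(cfg.c)])
        met_cols = ["t", "n_agents", "total_population", "simpson"]
        if cfg.mode == cult.PROGRESSIVE:
            met_cols += [f"mean_complexity_{i}" for i in range(cfg.c)]
        return SimResult(
            config=cfg,
            trajectory=pd.DataFrame(self._traj_rows, columns=traj_cols),
            moves=mob.moves_to_frame(self._moves),
            cultural_events=list(self._cultural),
            demographic_events=demo.demographic_events_to_frame(
                self._demographic),
            metrics=pd.DataFrame(self._metrics_rows, columns=met_cols),
            agent_months=self.state.agent_months,
            final_state=self.state,
            initial_statuses=self._initial_statuses,
            initial_ids=self._initial_ids)

    def run(self, progress: bool = False) -> SimResult:
        """Execute the configured horizon and assemble all run products."""
        cfg = self.config
        if self.state is None:
            self.initialize()
        st = self.state
        self._record_trajectory()
        self._record_metrics()
        n_steps = int(round((cfg.horizon_months - st.t_months) / cfg.dt))
        for k in range(n_steps):
            if st.extinct or not len(st.agents):
                break
            self.step()
            t = st.t_months
            if abs(t / cfg.traj_stride_months
                   - round(t / cfg.traj_stride_months)) < 1e-9:
                self._record_trajectory()
            if abs(t / cfg.metrics_stride_months
                   - round(t / cfg.metrics_stride_months)) < 1e-9:
                self._record_metrics()
            if progress and (k + 1) % 1200 == 0:
                print(f"step {k + 1}/{n_steps}: n_agents={len(st.agents)} "
                      f"population={st.agents.total_population:.0f}")
        return self._build_result()


def replay_cultural_history(result: SimResult) -> dict[int, np.ndarray]:
    """Re-derive final status vectors from the logged event streams alone.

    Starting from the initial statuses, applies cultural events
    (innovation/loss/adoption/...) and demographic events (fission copies
    the parent status to the child; progressive fusion takes per-feature
    maxima; extinction removes the camp) in time order.  The outcome must
    equal the final live statuses exactly — the event log fully
    determines the cultural state.
    """
    mode = result.config.mode
    S: dict[int, np.ndarray] = {
        int(g): s.copy() for g, s in zip(result.initial_ids,
                                         result.initial_statuses)}
    cultural = sorted(result.cultural_events, key=lambda e: e.t)
    demographic = result.demographic_events
    ci = 0
    boundaries = sorted(set(demographic["t"])) if len(demographic) else []
    for tb in boundaries:
        while ci < len(cultural) and cultural[ci].t < tb:
            e = cultural[ci]
            s = S[e.agent_id]
            if int(s[e.feature]) != e.old:
                raise ValueError(f"replay mismatch at t={e.t}")
            s[e.feature] = e.new
            ci += 1
        block = demographic[demographic["t"] == tb]
        for _, rec in block.iterrows():
            if rec["kind"] == "fission":
                S[int(rec["partner_id"])] = S[int(rec["agent_id"])].copy()
            elif rec["kind"] == "fusion":
                dying, absorber = int(rec["agent_id"]), int(rec["partner_id"])
                if mode == cult.PROGRESSIVE:
                    S[absorber] = np.maximum(S[absorber], S[dying])
                del S[dying]
            else:  # extinction
                del S[int(rec["agent_id"])]
    for e in cultural[ci:]:
        s = S[e.agent_id]
        if int(s[e.feature]) != e.old:
            raise ValueError(f"replay mismatch at t={e.t}")
        s[e.feature] = e.new
    return S


def landscape_windows(L: land.SuitabilityLandscape, timemap: land.TimeMap,
                      horizon_months: float) -> list[tuple[float, float]]:
    """Static-landscape intervals [t1, t2] in months, clipped to the run."""
    out = []
    for start_bp, end_bp in L.slice_times:
        t1 = float(np.clip(timemap.to_months(start_bp), 0, horizon_months))
        t2 = float(np.clip(timemap.to_months(end_bp), 0, horizon_months))
        if t2 > t1:
            out.append((t1, t2))
    return out


def run_simulation(config: SimulationConfig,
                   landscape: land.SuitabilityLandscape | None = None,
                   progress: bool = False) -> SimResult:
    """Convenience wrapper: build, initialize and run one simulation."""
    sim = Simulation(config, landscape=landscape)
    sim.initialize()
    return sim.run(progress=progress)
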