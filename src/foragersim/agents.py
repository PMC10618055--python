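"""Array-backed container for the live camp population.

Each agent is a hunter-gatherer camp with a planar position (km), a real
camp population (people) and an integer cultural status vector of ``c``
features.  For speed the simulation stores all live agents column-wise
in numpy arrays; :class:`Agent` is a per-agent read-only view used for
logging and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Agent:
    id: int
    position: np.ndarray      # (2,), km
    population: float         # people, > 0 while alive
    status: np.ndarray        # (c,), non-negative integers


class AgentSet:
    """All live agents, stored as parallel arrays.

    ``ids`` are unique and never reused; ``next_id`` allocates fresh ones
    (fission children, for instance).
    """

    def __init__(self, ids: np.ndarray, positions: np.ndarray,
                 populations: np.ndarray, statuses: np.ndarray):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 2)
        self.populations = np.asarray(populations, dtype=float)
        self.statuses = np.asarray(statuses, dtype=np.int64).reshape(len(self.ids), -1)
        if not (len(self.ids) == len(self.positions) == len(self.populations)
                == len(self.statuses)):
            raise ValueError("agent arrays must have equal length")
        if np.any(self.populations <= 0):
            raise ValueError("live agents must have positive population")
        if np.any(self.statuses < 0):
            raise ValueError("trait values must be non-negative")
        self._next_id = int(self.ids.max()) + 1 if len(self.ids) else 0

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.statuses.shape[1]

    @property
    def total_population(self) -> float:
        return float(self.populations.sum())

    def agent(self, idx: int) -> Agent:
        return Agent(int(self.ids[idx]), self.positions[idx].copy(),
                     float(self.populations[idx]), self.statuses[idx].copy())

    def index_of(self, agent_id: int) -> int:
        hit = np.nonzero(self.ids == agent_id)[0]
        if not hit.size:
            raise KeyError(f"no live agent with id {agent_id}")
        return int(hit[0])

    def allocate_id(self) -> int:
        out = self._next_id
        self._next_id += 1
        return out

    # -- structural edits -------------------------------------------------
    def append(self, agent_id: int, position: np.ndarray, population: float,
               status: np.ndarray) -> None:
        self.ids = np.append(self.ids, np.int64(agent_id))
        self.positions = np.vstack([self.positions, np.asarray(position, float)])
        self.populations = np.append(self.populations, float(population))
        self.statuses = np.vstack([self.statuses,
                                   np.asarray(status, np.int64).reshape(1, -1)])
        self._next_id = max(self._next_id, agent_id + 1)

    def remove(self, indices) -> None:
        keep = np.ones(len(self.ids), dtype=bool)
        keep[np.asarray(indices, dtype=int)] = False
        self.ids = self.ids[keep]
        self.positions = self.positions[keep]
        self.populations = self.populations[keep]
        self.statuses = self.statuses[keep]

    def copy(self) -> "AgentSet":
        out = AgentSet(self.ids.copy(), self.positions.copy(),
                       self.populations.copy(), self.statuses.copy())
        out._next_id = self._next_id
        return out
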