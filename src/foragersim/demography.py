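"""Camp demography: growth against local carrying capacity, fission and fusion.

Camp populations change deterministically.  The *local population* an
agent experiences is its own size plus neighbouring camps' sizes
weighted by the fractional overlap of their circular foraging areas
(radius ``r_f``).  While that local population is strictly below the
local carrying capacity the camp grows exponentially at ``rho_g`` per
month; otherwise it declines at ``rho_d``.

Camps exceeding the fission threshold split into two equal halves with
identical position and cultural status.  Camps falling below the fusion
threshold merge into the nearest camp within the long-range radius —
in progressive mode the absorbing camp takes the per-feature maximum of
the two status vectors (it instantly learns all variants known to the
joining camp) — or go extinct if no camp is within reach.  Fission and
fusion conserve people exactly; only extinction removes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import AgentSet


@dataclass
class DemographyParams:
    rho_g: float = 0.001     # growth rate, month^-1
    rho_d: float = 0.001     # decline rate, month^-1
    h_fis: float = 60.0      # fission threshold, people
    h_fus: float = 18.0      # fusion threshold, people
    r_f: float = 20.0        # foraging radius, km

    def __post_init__(self) -> None:
        if not (0 < self.h_fus < self.h_fis):
            raise ValueError("need 0 < h_fus < h_fis")
        if self.rho_g < 0 or self.rho_d < 0 or self.r_f <= 0:
            raise ValueError("rates must be >= 0 and r_f > 0")


@dataclass
class DemographicEvent:
    t: float                 # months
    kind: str                # fission | fusion | extinction
    agent_id: int
    partner_id: int | None   # fission child / fusion absorber
    population: float        # people moved (child size / merged size / lost)


def demographic_events_to_frame(events: list[DemographicEvent]) -> pd.DataFrame:
    cols = ["t", "kind", "agent_id", "partner_id", "population"]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.__dict__ for e in events])[cols]


def lens_fraction(d, r: float):
    """Intersection area of two radius-r discs at centre distance d,
    as a fraction of one disc's area.  1 at d = 0, 0 at d >= 2r."""
    d = np.asarray(d, dtype=float)
    dc = np.clip(d, 0.0, 2.0 * r)
    lens = 2 * r**2 * np.arccos(dc / (2 * r)) - (dc / 2) * np.sqrt(
        np.maximum(4 * r**2 - dc**2, 0.0))
    frac = np.where(d < 2 * r, lens / (np.pi * r**2), 0.0)
    return float(frac) if np.isscalar(d) or np.asarray(d).ndim == 0 else frac


def local_population(positions: np.ndarray, populations: np.ndarray,
                     r_f: float, dist: np.ndarray | None = None) -> np.ndarray:
    """Per-agent local population L_alpha.

    ``L_a = D_a + sum_b D_b * overlap(d_ab, r_f)`` where ``overlap`` is
    the fractional intersection of the two foraging discs.  Camps at
    distance >= 2 r_f contribute nothing.
    """
    if r_f <= 0:
        raise ValueError("r_f must be positive")
    X = np.atleast_2d(np.asarray(positions, dtype=float))
    D = np.asarray(populations, dtype=float)
    n = X.shape[0]
    if n == 1:
        return D.copy()
    if dist is None:
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    near = dist < 2 * r_f
    np.fill_diagonal(near, False)
    ii, jj = np.nonzero(near)
    w = lens_fraction(dist[ii, jj], r_f)
    return D + np.bincount(ii, weights=w * D[jj], minlength=n)


def update_populations(populations: np.ndarray, local_pop: np.ndarray,
                       capacity: np.ndarray, params: DemographyParams,
                       dt: float = 1.0) -> np.ndarray:
    """Exponential growth where L < K (strict), exponential decline otherwise."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    grow = np.asarray(local_pop) < np.asarray(capacity)
    factor = np.where(grow, np.exp(params.rho_g * dt), np.exp(-params.rho_d * dt))
    return np.asarray(populations, dtype=float) * factor


def apply_fission(agents: AgentSet, h_fis: float, t: float = 0.0
                  ) -> list[DemographicEvent]:
    """Split every camp whose population strictly exceeds ``h_fis``.

    Each such camp becomes two camps of half the population with the
    parent's position and status.  The parent keeps its id (trajectory
    continuity); the twin gets a fresh id.  Loops until no camp exceeds
    the threshold (relevant only for pathologically large camps).
    """
    events: list[DemographicEvent] = []
    while True:
        over = np.nonzero(agents.populations > h_fis)[0]
        if not over.size:
            return events
        for idx in over:
            half = agents.populations[idx] / 2.0
            agents.populations[idx] = half
            child = agents.allocate_id()
            agents.append(child, agents.positions[idx].copy(), half,
                          agents.statuses[idx].copy())
            events.append(DemographicEvent(t, "fission", int(agents.ids[idx]),
                                           child, half))


def apply_fusion(agents: AgentSet, h_fus: float, r2: float,
                 culture_mode: str = "progressive", t: float = 0.0
                 ) -> list[DemographicEvent]:
    """Merge or retire every camp whose population is below ``h_fus``.

    Starving camps are processed smallest-first (deterministic cascades).
    Each merges into the *nearest* other live camp within the long-range
    radius ``r2`` — the absorber gains the people and, in progressive
    mode, the per-feature maximum of the two status vectors.  With no
    camp in reach the starving camp goes extinct and its people leave
    the system.
    """
    events: list[DemographicEvent] = []
    while True:
        under = np.nonzero(agents.populations < h_fus)[0]
        if not under.size:
            return events
        # smallest population first; ties by lower id
        order = under[np.lexsort((agents.ids[under], agents.populations[under]))]
        idx = int(order[0])
        d = np.sqrt(((agents.positions - agents.positions[idx]) ** 2).sum(axis=1))
        d[idx] = np.inf
        in_range = np.nonzero(d <= r2)[0]
        if in_range.size:
            # nearest partner; ties broken by lower id
            best = in_range[np.lexsort((agents.ids[in_range], d[in_range]))][0]
            agents.populations[best] += agents.populations[idx]
            if culture_mode == "progressive":
                np.maximum(agents.statuses[best], agents.statuses[idx],
                           out=agents.statuses[best])
            events.append(DemographicEvent(t, "fusion", int(agents.ids[idx]),
                                           int(agents.ids[best]),
                                           float(agents.populations[idx])))
        else:
            events.append(DemographicEvent(t, "extinction", int(agents.ids[idx]),
                                           None, float(agents.populations[idx])))
        agents.remove([idx])
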