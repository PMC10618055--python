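"""Residential mobility: the camp-movement SDE.

Each camp follows

    dX = -grad( V(X, t) + U(X) ) dt + sigma(X) dB

where ``V`` is the environmental potential of the suitability landscape,
``U`` a pairwise interaction potential with a repulsive core (camps keep
their foraging areas apart) and a weak attractive tail (camps avoid
isolation), and the Brownian noise is scaled down by terrain friction.
Integration is Euler-Maruyama at a one-month step; proposals into
impassable cells are rejected (the camp stays put for that step), so
barriers are never crossed.

A displacement of at least ``move_threshold`` km within one step counts
as a residential move; the per-year move statistics computed here are
the quantities compared against ethnographic mobility data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .landscape import (LandscapeParams, SuitabilityLandscape, TimeMap,
                        passable_at, potential_gradient, sigma_at)


@dataclass
class MobilityParams:
    """Interaction-force and integrator constants.

    The pair potential is Morse-like,
    ``W(d) = a_rep exp(-d/l_rep) - a_att exp(-d/l_att)``, truncated at
    ``attraction_cutoff``.  With the defaults the pair force vanishes at
    ``d_rep`` = 10 km, the nominal minimum spacing between camps.
    """

    d_rep: float = 10.0           # nominal repulsion core distance, km
    a_rep: float = 5.0            # repulsion strength
    l_rep: float = 5.0            # repulsion decay length, km
    a_att: float = 5.0            # attraction strength
    l_att: float = 25.0           # attraction decay length, km
    attraction_cutoff: float = 50.0   # km; W truncated beyond this
    dt: float = 1.0               # integration step, months
    move_threshold: float = 2.0   # km; smaller displacements are not "moves"
    f_max: float = 2.0            # cap on pair-force magnitude, km/month

    def __post_init__(self) -> None:
        if self.d_rep < 0 or self.a_rep <= 0 or self.a_att < 0:
            raise ValueError("need d_rep >= 0, a_rep > 0, a_att >= 0")
        if self.attraction_cutoff < self.l_att:
            raise ValueError("attraction_cutoff must be >= l_att")
        if self.move_threshold <= 0 or self.dt <= 0:
            raise ValueError("dt and move_threshold must be positive")


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Dense Euclidean distance matrix via the Gram-matrix identity."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


class DriftField(Protocol):
    """What the integrator needs to know about the environment."""

    def grad_V(self, x: np.ndarray, t_months: float) -> np.ndarray: ...
    def sigma(self, x: np.ndarray) -> np.ndarray: ...
    def passable(self, x: np.ndarray) -> np.ndarray: ...


class LandscapeField:
    """Adapter exposing a suitability landscape as a drift field."""

    def __init__(self, L: SuitabilityLandscape, params: LandscapeParams,
                 timemap: TimeMap):
        self.L = L
        self.params = params
        self.timemap = timemap

    def grad_V(self, x: np.ndarray, t_months: float) -> np.ndarray:
        return potential_gradient(self.L, self.params, x,
                                  float(self.timemap.to_bp(t_months)))

    def sigma(self, x: np.ndarray) -> np.ndarray:
        return sigma_at(self.L, self.params, x)

    def passable(self, x: np.ndarray) -> np.ndarray:
        return passable_at(self.L, x)


class QuadraticField:
    """Isotropic quadratic test potential ``V = k |x|^2 / 2``, no friction.

    The SDE then reduces to an Ornstein-Uhlenbeck process with known
    stationary variance ``sigma^2 / (2 k)`` per coordinate — the
    quantitative oracle for the integrator.
    """

    def __init__(self, k: float, sigma0: float):
        self.k = k
        self.sigma0 = sigma0

    def grad_V(self, x: np.ndarray, t_months: float) -> np.ndarray:
        return self.k * np.atleast_2d(x)

    def sigma(self, x: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(x).shape[0], self.sigma0)

    def passable(self, x: np.ndarray) -> np.ndarray:
        return np.ones(np.atleast_2d(x).shape[0], dtype=bool)


# ---------------------------------------------------------------------------
# interaction forces
# ---------------------------------------------------------------------------

def _pair_tiebreak_units(ii: np.ndarray, jj: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Deterministic unit vectors for coincident pairs, seeded by id pair."""
    a = np.minimum(ids[ii], ids[jj]).astype(np.uint64)
    b = np.maximum(ids[ii], ids[jj]).astype(np.uint64)
    h = (a * np.uint64(2654435761) + b * np.uint64(40503)) % np.uint64(2**32)
    ang = 2 * np.pi * (h.astype(float) / 2**32)
    units = np.column_stack([np.cos(ang), np.sin(ang)])
    # the two partners must push in opposite directions
    flip = ids[ii] > ids[jj]
    units[flip] *= -1.0
    return units


def pair_force_magnitude(d: np.ndarray, params: MobilityParams) -> np.ndarray:
    """-W'(d): positive = repulsive. Zero beyond the attraction cutoff."""
    d = np.asarray(d, dtype=float)
    mag = (params.a_rep / params.l_rep) * np.exp(-d / params.l_rep) \
        - (params.a_att / params.l_att) * np.exp(-d / params.l_att)
    mag = np.where(d <= params.attraction_cutoff, mag, 0.0)
    return np.clip(mag, -params.f_max, params.f_max)


def interaction_force(positions: np.ndarray, params: MobilityParams,
                      ids: np.ndarray | None = None,
                      dist: np.ndarray | None = None) -> np.ndarray:
    """Net interaction force ``-grad U`` on every agent, km/month.

    All-pairs evaluation of the truncated Morse-like potential.  The
    force a pair exerts is equal and opposite; coincident agents (e.g.
    fresh fission twins) are pushed apart along a deterministic
    pseudo-random direction derived from the id pair, at the capped
    d -> 0 magnitude, so runs stay reproducible.
    """
    X = np.atleast_2d(np.asarray(positions, dtype=float))
    n = X.shape[0]
    if ids is None:
        ids = np.arange(n)
    if n < 2:
        return np.zeros_like(X)
    if dist is None:
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    # only pairs within the cutoff contribute; accumulate sparsely
    near = dist <= params.attraction_cutoff
    np.fill_diagonal(near, False)
    ii, jj = np.nonzero(near)
    d = dist[ii, jj]
    mag = pair_force_magnitude(d, params)
    sep = d > 0
    unit = np.empty((len(ii), 2))
    unit[sep] = (X[ii[sep]] - X[jj[sep]]) / d[sep, None]
    if np.any(~sep):
        unit[~sep] = _pair_tiebreak_units(ii[~sep], jj[~sep], np.asarray(ids))
        mag[~sep] = pair_force_magnitude(0.0, params)
    w = mag[:, None] * unit
    return np.column_stack([
        np.bincount(ii, weights=w[:, 0], minlength=n),
        np.bincount(ii, weights=w[:, 1], minlength=n),
    ])


# ---------------------------------------------------------------------------
# Euler-Maruyama step
# ---------------------------------------------------------------------------

def em_step(positions: np.ndarray, field: DriftField, params: MobilityParams,
            t_months: float, rng: np.random.Generator,
            ids: np.ndarray | None = None,
            interactions: bool = True,
            dist: np.ndarray | None = None) -> np.ndarray:
    """One Euler-Maruyama step of the mobility SDE for all agents.

    ``x' = x + (-grad V - grad U) dt + sigma(x) sqrt(dt) xi`` with
    independent standard bivariate normal ``xi`` per agent.  Proposals
    landing outside the domain or in friction-1 cells are rejected and
    the agent keeps its position for this step.
    """
    X = np.atleast_2d(np.asarray(positions, dtype=float))
    drift = -field.grad_V(X, t_months)
    if interactions and X.shape[0] > 1:
        drift = drift + interaction_force(X, params, ids=ids, dist=dist)
    sig = np.asarray(field.sigma(X))
    noise = rng.standard_normal(X.shape) if np.any(sig > 0) else np.zeros_like(X)
    prop = X + drift * params.dt + sig[:, None] * np.sqrt(params.dt) * noise
    ok = np.asarray(field.passable(prop))
    return np.where(ok[:, None], prop, X)


@dataclass
class MoveEvent:
    agent_id: int
    t: float          # months
    distance: float   # km
    x_from: float
    y_from: float
    x_to: float
    y_to: float


def record_moves(prev_positions: np.ndarray, new_positions: np.ndarray,
                 ids: np.ndarray, t_months: float,
                 move_threshold: float) -> list[MoveEvent]:
    """Residential moves: per-step displacements >= the threshold (2 km)."""
    prev = np.atleast_2d(prev_positions)
    new = np.atleast_2d(new_positions)
    d = np.sqrt(((new - prev) ** 2).sum(axis=1))
    out = []
    for k in np.nonzero(d >= move_threshold)[0]:
        out.append(MoveEvent(int(ids[k]), float(t_months), float(d[k]),
                             float(prev[k, 0]), float(prev[k, 1]),
                             float(new[k, 0]), float(new[k, 1])))
    return out


def moves_to_frame(moves: list[MoveEvent]) -> pd.DataFrame:
    cols = ["agent_id", "t", "distance", "x_from", "y_from", "x_to", "y_to"]
    if not moves:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([m.__dict__ for m in moves])[cols]


def mobility_stats(moves: pd.DataFrame, agent_months: float
                   ) -> tuple[float, float, float]:
    """(moves per agent-year, mean km per move, total km per agent-year).

    ``agent_months`` is the total observation time summed over agents
    (each agent weighted by its alive time).  Raises on an empty log —
    the statistics are undefined without at least one qualifying move.
    """
    if agent_months < 12:
        raise ValueError("need at least 12 agent-months of observation")
    n_moves = len(moves)
    if n_moves == 0:
        raise ValueError("no qualifying moves in log; statistics undefined")
    moves_per_year = n_moves * 12.0 / agent_months
    mean_km = float(moves["distance"].mean())
    return moves_per_year, mean_km, moves_per_year * mean_km
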