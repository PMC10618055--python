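"""Macroscopic observables: diversity, complexity and their correlates.

Simpson's diversity here is one minus the probability that two camps
drawn at random (with replacement) share the *same full status vector*;
camps weight equally regardless of their population.  Mean trait
complexity is the plain across-camp mean of each progressive feature's
trait value.  The population-complexity correlation is a Pearson
correlation of camp counts against mean complexity across sampled time
points of a run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def simpson_diversity(statuses: np.ndarray, per_feature: bool = False) -> float:
    """1 - sum_k p_k^2 over distinct status vectors (or per feature).

    ``per_feature=True`` instead averages the single-feature Simpson
    indices — a less strict reading of "sharing across all features".
    """
    S = np.atleast_2d(np.asarray(statuses))
    n = S.shape[0]
    if n == 0:
        raise ValueError("diversity undefined for zero agents")
    if per_feature:
        vals = []
        for i in range(S.shape[1]):
            _, counts = np.unique(S[:, i], return_counts=True)
            p = counts / n
            vals.append(1.0 - float(p @ p))
        return float(np.mean(vals))
    _, counts = np.unique(S, axis=0, return_counts=True)
    p = counts / n
    return 1.0 - float(p @ p)


def mean_complexity(statuses: np.ndarray) -> np.ndarray:
    """Across-camp mean trait value per feature (progressive features)."""
    S = np.atleast_2d(np.asarray(statuses))
    if S.shape[0] == 0:
        raise ValueError("complexity undefined for zero agents")
    return S.mean(axis=0)


def population_complexity_correlation(series: pd.DataFrame
                                      ) -> tuple[float, float]:
    """Pearson r (and p-value) of n_agents vs feature-averaged complexity.

    ``series`` needs an ``n_agents`` column and either a
    ``mean_complexity`` column or per-feature ``mean_complexity_*``
    columns, one row per sampled time point.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 time points")
    n = series["n_agents"].to_numpy(dtype=float)
    if "mean_complexity" in series.columns:
        comp = series["mean_complexity"].to_numpy(dtype=float)
    else:
        cols = [c for c in series.columns if c.startswith("mean_complexity_")]
        if not cols:
            raise ValueError("no mean_complexity columns in series")
        comp = series[cols].to_numpy(dtype=float).mean(axis=1)
    if np.all(n == n[0]) or np.all(comp == comp[0]):
        raise ValueError("correlation undefined for a constant series")
    r, p = stats.pearsonr(n, comp)
    return float(r), float(p)
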