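"""Mobility clusters and cultural clusters over static-landscape windows.

*Mobility clusters* answer "which regions held densely interacting
camps while the landscape was stable": all sampled camp positions
within a window are pooled and clustered with hierarchical density-based
clustering (HDBSCAN); each camp takes the majority label among its own
pooled points, with -1 for noise.

*Cultural clusters* are connected components of a thresholded
time-averaged status-closeness matrix ``C``: two camps are close in
status if their vectors are identical (non-progressive) or within
Euclidean distance ``epsilon`` (progressive), and ``C[a, b]`` is the
fraction of co-alive sampled steps on which they were close.

The cell map paints each landscape cell with the cultural cluster that
most frequently occupied it, and the overlap table (the data behind an
alluvial diagram) cross-tabulates mobility against cultural labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import HDBSCAN

from .landscape import SuitabilityLandscape


# ---------------------------------------------------------------------------
# mobility clusters
# ---------------------------------------------------------------------------

def mobility_clusters(points: np.ndarray, point_agent_ids: np.ndarray,
                      min_cluster_size: int | None = None,
                      cluster_selection_epsilon: float = 20.0
                      ) -> dict[int, int]:
    """Density-based clustering of pooled window positions.

    Returns {agent_id: label}, label -1 for noise.  ``min_cluster_size``
    counts pooled points (several per agent), not agents; by default it
    is five agents' worth of pooled points.  Density substructure below
    ``cluster_selection_epsilon`` (km) — e.g. the repulsion-imposed
    spacing of individual camps — is not split into separate clusters.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ids = np.asarray(point_agent_ids)
    if min_cluster_size is None:
        points_per_agent = len(pts) / max(len(np.unique(ids)), 1)
        min_cluster_size = max(int(5 * points_per_agent), 5)
    if len(pts) < min_cluster_size:
        return {int(g): -1 for g in np.unique(ids)}
    labels = HDBSCAN(min_cluster_size=int(min_cluster_size),
                     allow_single_cluster=True, copy=False).fit_predict(pts)
    if cluster_selection_epsilon > 0:
        labels = _merge_close_clusters(pts, labels, cluster_selection_epsilon)
        labels = _drop_sparse_clusters(pts, labels, cluster_selection_epsilon)
    out: dict[int, int] = {}
    for g in np.unique(ids):
        own = labels[ids == g]
        vals, counts = np.unique(own, return_counts=True)
        # majority label; prefer a real cluster over noise on ties
        order = np.lexsort((vals == -1, -counts))
        out[int(g)] = int(vals[order[0]])
    return out


def _drop_sparse_clusters(pts: np.ndarray, labels: np.ndarray,
                          epsilon: float, k: int = 5) -> np.ndarray:
    """Demote clusters with no density at the camp-system scale to noise.

    A cluster whose median distance to the k-th nearest neighbour exceeds
    ``epsilon`` is not a densely connected region of camps, whatever the
    relative-density hierarchy says.
    """
    from sklearn.neighbors import NearestNeighbors

    out = labels.copy()
    for lab in set(labels) - {-1}:
        p = pts[labels == lab]
        kk = min(k + 1, len(p))
        if kk < 2:
            out[labels == lab] = -1
            continue
        nn = NearestNeighbors(n_neighbors=kk).fit(p)
        dists, _ = nn.kneighbors(p)
        if np.median(dists[:, -1]) > epsilon:
            out[labels == lab] = -1
    return out


def _merge_close_clusters(pts: np.ndarray, labels: np.ndarray,
                          epsilon: float, max_sub: int = 200) -> np.ndarray:
    """Single-linkage merge of clusters whose gap is below ``epsilon`` km.

    Keeps spatially contiguous camp systems (whose internal spacing is
    set by the repulsive force, not by true fragmentation) in one
    cluster.  Inter-cluster gaps are measured on subsampled points.
    """
    ks = sorted(set(labels) - {-1})
    parent = {k: k for k in ks}

    def find(k: int) -> int:
        while parent[k] != k:
            k = parent[k]
        return k

    subs = {}
    for k in ks:
        p = pts[labels == k]
        subs[k] = p[:: max(len(p) // max_sub, 1)]
    for a_i, ki in enumerate(ks):
        for kj in ks[a_i + 1:]:
            if find(ki) == find(kj):
                continue
            d2 = ((subs[ki][:, None, :] - subs[kj][None, :, :]) ** 2).sum(-1)
            if d2.min() < epsilon**2:
                ra, rb = sorted((find(ki), find(kj)))
                parent[rb] = ra
    return np.array([find(k) if k != -1 else -1 for k in labels])


# ---------------------------------------------------------------------------
# cultural closeness and clusters
# ---------------------------------------------------------------------------

def status_close(s_a: np.ndarray, s_b: np.ndarray, mode: str,
                 epsilon: float = 2.0) -> bool:
    """Exact equality (non-progressive) or ||s_a - s_b|| <= epsilon."""
    a = np.asarray(s_a, dtype=float)
    b = np.asarray(s_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("status vectors must have the same length")
    if mode == "non-progressive":
        return bool(np.all(a == b))
    return bool(np.sqrt(((a - b) ** 2).sum()) <= epsilon)


def _closeness_matrix(S: np.ndarray, mode: str, epsilon: float) -> np.ndarray:
    diff = S[:, None, :].astype(float) - S[None, :, :].astype(float)
    if mode == "non-progressive":
        return np.all(diff == 0, axis=2)
    return (diff**2).sum(axis=2) <= epsilon**2


def cultural_connectivity(samples: pd.DataFrame, mode: str,
                          epsilon: float = 2.0
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-averaged status-closeness matrix over a window.

    ``samples`` holds sampled per-step statuses (columns ``t``,
    ``agent_id``, ``s_0..s_{c-1}``) already restricted to the window.
    Returns ``(C, ids, support)`` where ``C[a, b]`` is the fraction of
    sampled steps with both agents alive on which they were close in
    status, and ``support`` counts co-alive sampled steps (0 support
    flags an unsupported pair; its C entry is 0).
    """
    s_cols = sorted([c for c in samples.columns if c.startswith("s_")],
                    key=lambda c: int(c.split("_")[1]))
    ids = np.unique(samples["agent_id"].to_numpy())
    index = {g: k for k, g in enumerate(ids)}
    n = len(ids)
    close = np.zeros((n, n))
    support = np.zeros((n, n))
    for _, frame in samples.groupby("t"):
        rows = frame["agent_id"].map(index).to_numpy()
        S = frame[s_cols].to_numpy()
        cl = _closeness_matrix(S, mode, epsilon)
        support[np.ix_(rows, rows)] += 1
        close[np.ix_(rows, rows)] += cl
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(support > 0, close / np.maximum(support, 1), 0.0)
    np.fill_diagonal(C, 1.0 * (np.diag(support) > 0))
    return C, ids, support


def cultural_clusters(C: np.ndarray, ids: np.ndarray,
                      theta: float = 0.5) -> dict[int, int]:
    """Connected components of the graph ``C >= theta``.

    Labels are consecutive integers ordered by first appearance.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must lie in (0, 1]")
    adj = (C >= theta).astype(np.int8)
    np.fill_diagonal(adj, 1)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    relabel: dict[int, int] = {}
    out: dict[int, int] = {}
    for g, lab in zip(ids, comp):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        out[int(g)] = relabel[lab]
    return out


def cluster_cell_map(samples: pd.DataFrame, labels: dict[int, int],
                     L: SuitabilityLandscape) -> np.ndarray:
    """Per-cell majority cultural cluster; -1 for unvisited cells.

    ``samples`` holds sampled positions (columns ``agent_id``, ``x``,
    ``y``).  Each visit by a labelled agent votes for its cluster in the
    containing cell; ties go to the lowest label; noise agents (-1) do
    not vote.
    """
    ny, nx = L.shape
    lab_of = samples["agent_id"].map(labels).to_numpy()
    keep = ~pd.isna(lab_of)
    lab_of = lab_of[keep].astype(int)
    pos = samples.loc[keep, ["x", "y"]].to_numpy()
    valid = lab_of >= 0
    lab_of, pos = lab_of[valid], pos[valid]
    row, col, inside = L.cell_of(pos)
    row, col, lab_of = row[inside], col[inside], lab_of[inside]
    n_labels = (max(labels.values()) + 1) if labels else 0
    counts = np.zeros((ny, nx, max(n_labels, 1)), dtype=np.int64)
    np.add.at(counts, (row, col, lab_of), 1)
    best = counts.argmax(axis=2)          # argmax takes the lowest on ties
    visited = counts.sum(axis=2) > 0
    return np.where(visited, best, -1)


def cluster_overlap(labels_a: dict[int, int], labels_b: dict[int, int]
                    ) -> pd.DataFrame:
    """Contingency table of two labelings over the same agents.

    Rows are labels from ``labels_a`` (e.g. mobility clusters), columns
    from ``labels_b`` (e.g. cultural clusters); noise (-1) keeps its own
    row/column.  This is the table an alluvial diagram visualizes.
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("labelings must cover the same agent set")
    agents = sorted(labels_a)
    a = pd.Series([labels_a[g] for g in agents], name="a")
    b = pd.Series([labels_b[g] for g in agents], name="b")
    return pd.crosstab(a, b)


def clusters_per_cluster(overlap: pd.DataFrame) -> pd.Series:
    """How many B-clusters (noise excluded) each A-cluster contains."""
    cols = [c for c in overlap.columns if c != -1]
    return (overlap[cols] > 0).sum(axis=1)
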