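"""Functional-connectivity graph analysis of the motor network.

Resting-state BOLD series are band-pass filtered to the low-frequency band
(0.01–0.1 Hz), correlated between ROIs, and binarized at a correlation
threshold (positive correlations only).  Network summaries are the number of
connections E, the interhemispheric connection count, the clustering
coefficient C_i = 2 e_i / (k_i (k_i - 1)) with its network mean C, and the
normalized clustering coefficient gamma = C / <C_random> against
degree-preserving (Maslov–Sneppen) rewired surrogates.  Gamma measures local
connectedness relative to a random network with the same degree sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .synth import ROITimeSeries

__all__ = [
    "FunctionalGraph",
    "GraphMetrics",
    "bandpass_filter",
    "correlation_matrix",
    "threshold_graph",
    "count_connections",
    "count_interhemispheric",
    "clustering_coefficient",
    "rewire_degree_preserving",
    "gamma",
    "graph_metrics",
    "threshold_sweep",
    "load_timeseries_csv",
    "save_edge_list_csv",
]


@dataclass(frozen=True)
class FunctionalGraph:
    """Binarized undirected correlation graph over labelled nodes."""

    nodes: tuple[str, ...]
    hemispheres: tuple[str, ...]
    adjacency: np.ndarray  # (k, k) bool, symmetric, zero diagonal
    threshold: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape != (len(self.nodes),) * 2:
            raise ValueError("adjacency shape must match node count")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", a)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass(frozen=True)
class GraphMetrics:
    n_connections: int
    n_interhemispheric: int
    degrees: np.ndarray
    clustering_per_node: np.ndarray
    clustering: float
    gamma: float | None


# ---------------------------------------------------------------------------
# Signal processing
# ---------------------------------------------------------------------------

def bandpass_filter(ts: ROITimeSeries, low: float = 0.01, high: float = 0.1,
                    order: int = 2) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    ``low = 0`` degenerates to a pure low-pass.  ``high`` must stay below the
    Nyquist frequency of the series.
    """
    nyq = 0.5 / ts.dt
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below the Nyquist "
                         f"frequency {nyq} Hz for dt={ts.dt} s")
    if low > 0:
        b, a = butter(order, [low / nyq, high / nyq], btype="band")
    else:
        b, a = butter(order, high / nyq, btype="low")
    filtered = filtfilt(b, a, ts.data, axis=0)
    return ROITimeSeries(nodes=ts.nodes, hemispheres=ts.hemispheres,
                         data=filtered, dt=ts.dt)


def correlation_matrix(ts: ROITimeSeries) -> np.ndarray:
    """Pearson correlation between all ROI pairs; symmetric with unit diagonal."""
    if ts.data.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance node(s): {[ts.nodes[i] for i in dead]}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


# ---------------------------------------------------------------------------
# Graph construction and metrics
# ---------------------------------------------------------------------------

def threshold_graph(corr: np.ndarray, threshold: float,
                    nodes: tuple[str, ...] | None = None,
                    hemispheres: tuple[str, ...] | None = None) -> FunctionalGraph:
    """Edge wherever r > threshold (positive correlations only; diagonal ignored)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    corr = np.asarray(corr, dtype=float)
    k = corr.shape[0]
    nodes = nodes or tuple(f"n{i}" for i in range(k))
    hemispheres = hemispheres or tuple("L" if i < k / 2 else "R" for i in range(k))
    adj = corr > threshold
    np.fill_diagonal(adj, False)
    adj = adj & adj.T
    return FunctionalGraph(nodes=nodes, hemispheres=hemispheres,
                           adjacency=adj, threshold=threshold)


def count_connections(g: FunctionalGraph) -> int:
    return int(g.adjacency.sum() // 2)


def count_interhemispheric(g: FunctionalGraph) -> int:
    """Edges whose endpoints carry different hemisphere labels."""
    hemi = np.asarray(g.hemispheres)
    if not set(hemi) <= {"L", "R"} or (hemi == "").any():
        raise ValueError("every node needs an L or R hemisphere label")
    cross = hemi[:, None] != hemi[None, :]
    return int((g.adjacency & cross).sum() // 2)


def clustering_coefficient(g: FunctionalGraph,
                           exclude_low_degree: bool = False) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i = 2 e_i / (k_i (k_i - 1)) and the network mean.

    e_i is the number of edges among node i's neighbours.  Nodes with degree
    < 2 get C_i = 0 and are included in the mean (Watts–Strogatz convention);
    ``exclude_low_degree`` drops them from the mean instead.
    """
    a = g.adjacency.astype(int)
    k = a.sum(axis=1)
    # edges among neighbours of i: (A^3)_ii counts closed triangles twice
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * e_i per node
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    if exclude_low_degree:
        sel = k >= 2
        mean_c = float(c[sel].mean()) if sel.any() else 0.0
    else:
        mean_c = float(c.mean())
    return c, mean_c


def rewire_degree_preserving(g: FunctionalGraph, n_swap_attempts: int,
                             seed: int) -> FunctionalGraph:
    """Maslov–Sneppen rewiring: repeated double-edge swaps.

    Each attempt picks two edges (a,b), (c,d) and proposes rewiring to
    (a,d),(c,b) or (a,c),(b,d); the swap is committed only if it creates no
    self-loop or duplicate edge.  The degree sequence is preserved exactly.
    If no attempt succeeds the input graph is returned with a warning.
    """
    edges = np.argwhere(np.triu(g.adjacency, 1))
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    adj = g.adjacency.copy()
    edges = [tuple(e) for e in edges]
    successes = 0
    for _ in range(int(n_swap_attempts)):
        i, j = rng.integers(0, len(edges), 2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        n1 = tuple(sorted(new1))
        n2 = tuple(sorted(new2))
        if n1 == n2 or adj[n1] or adj[n2]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[n1] = adj[n1[::-1]] = True
        adj[n2] = adj[n2[::-1]] = True
        edges[i], edges[j] = n1, n2
        successes += 1
    if successes == 0:
        warnings.warn("no valid degree-preserving swap exists; graph returned "
                      "unchanged", stacklevel=2)
        return g
    return FunctionalGraph(nodes=g.nodes, hemispheres=g.hemispheres,
                           adjacency=adj, threshold=g.threshold)


def gamma(g: FunctionalGraph, n_random: int = 100, seed: int = 0,
          swap_factor: int = 10) -> float:
    """Normalized clustering gamma = C / <C of degree-matched rewired surrogates>.

    Uses ``n_random`` Maslov–Sneppen surrogates with ``swap_factor * E`` swap
    attempts each.  Raises if the surrogate mean clustering is zero (gamma
    undefined).
    """
    _, c_obs = clustering_coefficient(g)
    n_edges = count_connections(g)
    if n_edges < 2:
        raise ValueError("gamma is undefined for graphs with fewer than 2 edges")
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_random):
            surrogate = rewire_degree_preserving(
                g, swap_factor * n_edges, seed=int(rng.integers(0, 2 ** 31)))
            _, c_rand[i] = clustering_coefficient(surrogate)
    mean_rand = float(c_rand.mean())
    if mean_rand <= 0:
        raise ValueError("gamma undefined: all rewired surrogates have zero "
                         "clustering")
    return c_obs / mean_rand


def graph_metrics(g: FunctionalGraph, n_random: int = 100,
                  seed: int = 0) -> GraphMetrics:
    """All graph summaries in one pass (gamma is None when undefined)."""
    c_i, c = clustering_coefficient(g)
    try:
        gam = gamma(g, n_random=n_random, seed=seed)
    except ValueError:
        gam = None
    return GraphMetrics(
        n_connections=count_connections(g),
        n_interhemispheric=count_interhemispheric(g),
        degrees=g.degrees(),
        clustering_per_node=c_i,
        clustering=c,
        gamma=gam,
    )


def threshold_sweep(corr: np.ndarray, thresholds: np.ndarray,
                    nodes: tuple[str, ...] | None = None,
                    hemispheres: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Edge counts and clustering across a range of thresholds."""
    rows = []
    for thr in thresholds:
        g = threshold_graph(corr, float(thr), nodes, hemispheres)
        _, c = clustering_coefficient(g)
        rows.append({"threshold": float(thr), "n_connections": count_connections(g),
                     "n_interhemispheric": count_interhemispheric(g),
                     "clustering": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_timeseries_csv(path: str, dt: float = 0.5) -> ROITimeSeries:
    """Read the node, hemisphere, sample... layout written by the generator."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["node", "hemisphere"]:
        raise ValueError("expected columns: node, hemisphere, then samples")
    data = df.iloc[:, 2:].to_numpy(dtype=float).T
    return ROITimeSeries(nodes=tuple(df["node"]), hemispheres=tuple(df["hemisphere"]),
                         data=data, dt=dt)


def save_edge_list_csv(g: FunctionalGraph, path: str) -> None:
    rows = [{"node_a": g.nodes[i], "node_b": g.nodes[j],
             "interhemispheric": int(g.hemispheres[i] != g.hemispheres[j])}
            for i, j in np.argwhere(np.triu(g.adjacency, 1))]
    pd.DataFrame(rows, columns=["node_a", "node_b", "interhemispheric"]).to_csv(
        path, index=False)
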