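"""Pearson connectivity matrices, thresholding, and graph-theory metrics.

A functional-connectivity network is the matrix of Pearson correlations
between regional signals.  Binary graphs are obtained either by an absolute
threshold (edge kept iff r > tau, so negative correlations never form edges)
or proportionally (keep a fixed fraction of the strongest edges, guaranteeing
equal network size across subjects).

Seven graph parameters are computed per binarized network: number of edges,
mean degree, clustering coefficient, transitivity, characteristic path length,
global efficiency, local efficiency and small-worldness — following the usual
binary-undirected conventions (clustering of degree-<2 nodes is 0, local
efficiency is the global efficiency of each node's neighbour subgraph,
small-worldness is (C/C_rand)/(L/L_rand) against an Erdos-Renyi G(n, m)
reference ensemble with matched node and edge counts).

All-pairs distances use unweighted BFS realised as repeated boolean matrix
products, which is fast for the small, dense graphs that arise here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import RegionalSignalMatrix

__all__ = [
    "WeightedAdjacency",
    "BinaryGraph",
    "ThresholdGrid",
    "RandomReference",
    "GtaMetrics",
    "METRIC_NAMES",
    "pearson_adjacency",
    "threshold_binarize",
    "proportional_binarize",
    "max_connected_threshold",
    "bfs_distances",
    "is_connected",
    "sample_gnm",
    "er_reference",
    "gta_metrics",
    "gta_profile",
]

#: the seven graph parameters reported per threshold
METRIC_NAMES = ("n_edges", "degree", "clustering", "transitivity",
                "path_length", "global_efficiency", "local_efficiency",
                "small_worldness")


@dataclass
class WeightedAdjacency:
    """Symmetric matrix of inter-regional Pearson correlations (diagonal 0)."""

    weights: np.ndarray
    region_ids: list[int]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if w.shape[0] != len(self.region_ids):
            raise ValueError("region id count does not match matrix size")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")
        if np.nanmax(np.abs(w)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def upper_values(self) -> np.ndarray:
        """Edge weights of the upper triangle (i < j), row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.weights, index=self.region_ids,
                     columns=self.region_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "WeightedAdjacency":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(weights=df.to_numpy(dtype=float),
                   region_ids=[int(c) for c in df.columns])


@dataclass
class BinaryGraph:
    """Undirected simple graph as a boolean adjacency matrix."""

    adjacency: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class ThresholdGrid:
    """Ascending thresholds 0, step, ..., tau_max (graph connected throughout)."""

    values: np.ndarray = field(default_factory=lambda: np.array([0.0]))

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0 or v[0] != 0.0 or np.any(np.diff(v) <= 0):
            raise ValueError("grid must start at 0 and be strictly ascending")
        self.values = v

    @property
    def tau_max(self) -> float:
        return float(self.values[-1])

    @classmethod
    def from_tau_max(cls, tau_max: float, step: float = 0.01) -> "ThresholdGrid":
        n = int(round(tau_max / step))
        return cls(values=np.round(np.arange(n + 1) * step, 10))


def pearson_adjacency(regional: RegionalSignalMatrix) -> WeightedAdjacency:
    """Pearson correlation between every pair of regional signals."""
    if regional.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    sds = regional.signals.std(axis=1)
    if np.any(sds == 0):
        bad = [regional.region_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant signal in region(s) {bad}: correlation undefined")
    r = np.corrcoef(regional.signals)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return WeightedAdjacency(weights=r, region_ids=list(regional.region_ids))


def threshold_binarize(adj: WeightedAdjacency, tau: float) -> BinaryGraph:
    """Keep edges with weight strictly greater than ``tau``."""
    if not 0 <= tau < 1:
        raise ValueError(f"threshold must lie in [0, 1), got {tau}")
    return BinaryGraph(adjacency=adj.weights > tau, threshold=tau)


def proportional_binarize(adj: WeightedAdjacency, density: float) -> BinaryGraph:
    """Keep the strongest ``density`` fraction of possible edges.

    Retains floor(density * n(n-1)/2) edges; ties are broken deterministically
    by (i, j) lexicographic order so two subjects at the same density always
    have identical edge counts.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    n = adj.n_nodes
    iu = np.triu_indices(n, k=1)
    k = int(np.floor(density * n * (n - 1) / 2))
    if k == 0:
        raise ValueError(f"density {density} yields zero edges for n={n}")
    w = adj.weights[iu]
    # stable sort on -w keeps lexicographic (i, j) order among ties
    order = np.argsort(-w, kind="stable")[:k]
    a = np.zeros((n, n), dtype=bool)
    a[iu[0][order], iu[1][order]] = True
    return BinaryGraph(adjacency=a | a.T)


def bfs_distances(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf if unreachable)."""
    a = np.asarray(adjacency, dtype=bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a] = 1.0
    reach = a | np.eye(n, dtype=bool)
    d = 1
    af = a.astype(np.float32)
    frontier = a
    while frontier.any():
        d += 1
        new_reach = (reach.astype(np.float32) @ af) > 0
        new_reach |= reach
        frontier = new_reach & ~reach
        dist[frontier] = d
        reach = new_reach
    return dist


def is_connected(adjacency: np.ndarray) -> bool:
    a = np.asarray(adjacency, dtype=bool)
    n = a.shape[0]
    if n == 0:
        return False
    reach = a[0] | (np.arange(n) == 0)
    while True:
        new = reach | (a[reach].any(axis=0))
        if np.array_equal(new, reach):
            return bool(new.all())
        reach = new


def max_connected_threshold(adj: WeightedAdjacency, step: float = 0.01) -> float:
    """Largest grid threshold at which the binarized graph stays connected.

    Scans 0, step, 2*step, ... and returns the last value before the network
    splits.  Raises if the graph is already disconnected at tau = 0 (the
    threshold sweep is undefined there).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not is_connected(adj.weights > 0.0):
        raise ValueError("graph is disconnected at threshold 0; "
                         "threshold sweep undefined")
    tau = 0.0
    k = 1
    while True:
        nxt = round(k * step, 10)
        if nxt >= 1 or not is_connected(adj.weights > nxt):
            return tau
        tau = nxt
        k += 1


def sample_gnm(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random simple graph with ``n`` nodes and ``m`` edges."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m={m} out of range for n={n}")
    iu = np.triu_indices(n, k=1)
    chosen = rng.choice(max_m, size=m, replace=False)
    a = np.zeros((n, n), dtype=bool)
    a[iu[0][chosen], iu[1][chosen]] = True
    return a | a.T


@dataclass
class RandomReference:
    """Ensemble-mean clustering and path length of matched random graphs."""

    c_rand: float
    l_rand: float
    n_graphs: int


def _clustering_and_triples(a: np.ndarray):
    af = a.astype(float)
    deg = af.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", af, af, af)  # 2x triangles per node
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, tri2 / denom, 0.0)
    return ci, tri2, denom, deg


def _mean_finite_offdiag(dist: np.ndarray) -> float:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = dist[off]
    finite = np.isfinite(vals)
    if not finite.any():
        return np.nan
    return float(vals[finite].mean())


def er_reference(n: int, m: int, seed: int, n_graphs: int = 20) -> RandomReference:
    """C_rand and L_rand from ``n_graphs`` G(n, m) samples.

    L on a disconnected sample is averaged over reachable ordered pairs only.
    Deterministic in (n, m, seed, n_graphs).
    """
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_graphs):
        a = sample_gnm(n, m, rng)
        ci, *_ = _clustering_and_triples(a)
        cs.append(ci.mean())
        ls.append(_mean_finite_offdiag(bfs_distances(a)))
    return RandomReference(c_rand=float(np.mean(cs)), l_rand=float(np.nanmean(ls)),
                           n_graphs=n_graphs)


@dataclass
class GtaMetrics:
    """One row of a GTA profile: the seven parameters of a binary graph."""

    n_edges: int
    degree: float
    clustering: float
    transitivity: float
    path_length: float
    global_efficiency: float
    local_efficiency: float
    small_worldness: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def gta_metrics(g: BinaryGraph, reference: RandomReference | None = None,
                seed: int = 0, n_random: int = 20,
                allow_disconnected: bool = False) -> GtaMetrics:
    """All seven graph parameters of a connected binary graph.

    The small-worldness reference is either supplied (``reference``) or
    generated as an Erdos-Renyi ensemble with matching node/edge counts using
    ``seed`` (deterministic).  A disconnected graph raises (the path length is
    undefined) unless ``allow_disconnected`` is set, in which case path length
    and small-worldness are NaN while the efficiencies remain defined
    (unreachable pairs contribute zero).
    """
    a = g.adjacency
    n = g.n_nodes
    if n < 3:
        raise ValueError("graph metrics require at least 3 nodes")
    dist = bfs_distances(a)
    connected = bool(np.all(np.isfinite(dist)))
    if not connected and not allow_disconnected:
        raise ValueError("graph is disconnected: characteristic path length "
                         "undefined")
    m = g.n_edges
    degree = 2.0 * m / n

    ci, tri2, denom, deg = _clustering_and_triples(a)
    clustering = float(ci.mean())
    triples = denom.sum()  # = 2 * number of connected triples
    transitivity = float(tri2.sum() / triples) if triples > 0 else 0.0

    off = ~np.eye(n, dtype=bool)
    path_length = float(dist[off].mean()) if connected else float("nan")
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~off] = 0.0
    inv[~np.isfinite(dist)] = 0.0
    global_eff = float(inv[off].mean())

    # local efficiency: global efficiency of each node's neighbour subgraph
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        dsub = bfs_distances(sub)
        offk = ~np.eye(k, dtype=bool)
        with np.errstate(divide="ignore"):
            isub = 1.0 / dsub
        eloc[i] = isub[offk].mean()
    local_eff = float(eloc.mean())

    if reference is None:
        reference = er_reference(n, m, seed=seed, n_graphs=n_random)
    if reference.c_rand > 0 and reference.l_rand > 0 and path_length > 0:
        sigma = (clustering / reference.c_rand) / (path_length / reference.l_rand)
    else:
        sigma = np.nan

    return GtaMetrics(n_edges=m, degree=degree, clustering=clustering,
                      transitivity=transitivity, path_length=path_length,
                      global_efficiency=global_eff, local_efficiency=local_eff,
                      small_worldness=float(sigma))


def gta_profile(adj: WeightedAdjacency, grid: ThresholdGrid,
                seed: int = 0, n_random: int = 20) -> pd.DataFrame:
    """Evaluate all seven metrics at every grid threshold.

    Returns a DataFrame with a ``threshold`` column and one column per metric.
    The small-world reference ensemble seed is fixed per threshold index, so
    the profile is deterministic.
    """
    rows = []
    for j, tau in enumerate(grid.values):
        g = threshold_binarize(adj, float(tau))
        mets = gta_metrics(g, seed=seed * 100003 + j, n_random=n_random)
        rows.append({"threshold": float(tau), **mets.as_dict()})
    return pd.DataFrame(rows)


def profiles_to_tidy(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-subject profiles into tidy (subject_id, threshold, metric, value)."""
    frames = []
    for sid, df in profiles.items():
        melted = df.melt(id_vars="threshold", var_name="metric", value_name="value")
        melted.insert(0, "subject_id", sid)
        frames.append(melted)
    return pd.concat(frames, ignore_index=True)
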