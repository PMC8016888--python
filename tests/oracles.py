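"""Independent brute-force oracles for graph metrics.

Deliberately naive algorithms, structurally different from the package
implementation: triangle counting by enumerating node triples, all-pairs
distances by Floyd-Warshall, clustering/transitivity/efficiencies assembled
from those primitives with explicit loops.
"""

from itertools import combinations

import numpy as np


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.where(a, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def triangles_per_node(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    tri = np.zeros(n)
    for i, j, k in combinations(range(n), 3):
        if a[i, j] and a[j, k] and a[i, k]:
            tri[[i, j, k]] += 1
    return tri


def clustering(a: np.ndarray) -> float:
    tri = triangles_per_node(a)
    deg = a.sum(axis=1)
    cs = []
    for i in range(a.shape[0]):
        k = deg[i]
        cs.append(tri[i] / (k * (k - 1) / 2.0) if k >= 2 else 0.0)
    return float(np.mean(cs))


def transitivity(a: np.ndarray) -> float:
    tri = triangles_per_node(a).sum() / 3.0
    deg = a.sum(axis=1)
    triples = sum(k * (k - 1) / 2.0 for k in deg)
    return float(3.0 * tri / triples) if triples > 0 else 0.0


def path_length(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    n = a.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def global_efficiency(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    n = a.shape[0]
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def local_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    es = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            es.append(0.0)
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        es.append(global_efficiency(sub))
    return float(np.mean(es))


def is_connected(a: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(floyd_warshall(a))))


def all_metrics(a: np.ndarray, reference=None) -> dict:
    """All seven parameters; ``reference`` = (c_rand, l_rand) for sigma_sw."""
    a = np.asarray(a, dtype=bool)
    n = a.shape[0]
    m = int(a.sum()) // 2
    out = {
        "n_edges": m,
        "degree": 2.0 * m / n,
        "clustering": clustering(a),
        "transitivity": transitivity(a),
        "path_length": path_length(a),
        "global_efficiency": global_efficiency(a),
        "local_efficiency": local_efficiency(a),
    }
    if reference is not None:
        c_rand, l_rand = reference
        if c_rand > 0 and l_rand > 0 and out["path_length"] > 0:
            out["small_worldness"] = ((out["clustering"] / c_rand)
                                      / (out["path_length"] / l_rand))
        else:
            out["small_worldness"] = np.nan
    return out


def reference_stats(graphs_list) -> tuple[float, float]:
    """Ensemble-mean clustering and reachable-pair path length (oracle route)."""
    cs, ls = [], []
    for g in graphs_list:
        cs.append(clustering(g))
        d = floyd_warshall(g)
        n = g.shape[0]
        vals = [d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j])]
        ls.append(np.mean(vals))
    return float(np.mean(cs)), float(np.mean(ls))
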