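"""Time-resolved graph measures on functional network sequences.

Implemented measures: link density rho (fraction of realized ordered node
pairs), clustering coefficient C (mean over all nodes of the neighbour link
density, zero by convention for degree < 2), normalized clustering
C' = C / rho, connected components, and shortest-path distances.  Because
each functional network is a union of cliques, every defined node
clustering equals 1, component membership coincides with
equality-of-symbols, and pairwise distances are 0, 1 or infinity.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

__all__ = [
    "MetricSeries",
    "link_density",
    "clustering",
    "components",
    "shortest_path_distance",
    "metric_time_series",
    "available_metrics",
]


@dataclass
class MetricSeries:
    """One graph metric evaluated at every network time point."""

    name: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")

    def __len__(self) -> int:
        return self.values.size


def _check_adjacency(a) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    return a


def link_density(a) -> float:
    """rho = sum_{i != j} A_ij / (N (N-1)); 1 for the complete graph."""
    a = _check_adjacency(a)
    n = a.shape[0]
    off_diag = a.sum() - np.trace(a)
    return float(off_diag) / (n * (n - 1))


def clustering(a) -> tuple[np.ndarray, float, float]:
    """Per-node clustering C_i, network mean C, and normalized C' = C / rho.

    C_i = 2 E_i / (k_i (k_i - 1)) with E_i the number of links among node
    i's neighbours; nodes of degree < 2 contribute 0.  C' is NaN when the
    network has no links.
    """
    a = _check_adjacency(a).astype(float)
    k = a.sum(axis=1)
    # links among neighbours: triangles through each node
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    denom = k * (k - 1)
    c_i = np.zeros(a.shape[0])
    mask = denom > 0
    c_i[mask] = 2.0 * triangles[mask] / denom[mask]
    c_mean = float(c_i.mean())
    rho = link_density(a)
    c_norm = c_mean / rho if rho > 0 else float("nan")
    return c_i, c_mean, c_norm


def components(a) -> tuple[int, np.ndarray, np.ndarray]:
    """Connected components: (count, per-node labels, sizes).

    Isolated nodes count as components of size 1.
    """
    a = _check_adjacency(a)
    n_comp, labels = _cc(csr_matrix(a), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return int(n_comp), labels, sizes


def shortest_path_distance(a, i: int, j: int) -> float:
    """Breadth-first shortest-path distance between nodes ``i`` and ``j``;
    0 for i == j, ``inf`` across components."""
    a = _check_adjacency(a)
    n = a.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError("node index out of range")
    if i == j:
        return 0.0
    seen = {i}
    queue = deque([(i, 0)])
    while queue:
        node, dist = queue.popleft()
        for nb in np.flatnonzero(a[node]):
            nb = int(nb)
            if nb == j:
                return float(dist + 1)
            if nb not in seen:
                seen.add(nb)
                queue.append((nb, dist + 1))
    return float("inf")


_METRICS = {
    "density": lambda a: link_density(a),
    "clustering": lambda a: clustering(a)[1],
    "normalized_clustering": lambda a: clustering(a)[2],
    "components": lambda a: float(components(a)[0]),
    "largest_component": lambda a: float(components(a)[2].max()),
}


def available_metrics() -> list[str]:
    return sorted(_METRICS)


def metric_time_series(nets, name: str) -> MetricSeries:
    """Evaluate a named metric on every network of a NetworkSequence."""
    if name not in _METRICS:
        raise ValueError(
            f"unknown metric {name!r}; available: {', '.join(available_metrics())}"
        )
    fn = _METRICS[name]
    values = np.array([fn(a) for a in nets.iter_adjacency()])
    return MetricSeries(name=name, times=nets.times, values=values)
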