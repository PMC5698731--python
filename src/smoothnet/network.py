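"""Weighted correlation networks and fixed-density thresholding.

Link weights are Pearson correlations of ROI series (diagonal zeroed).
Thresholding to density d keeps exactly round(d * R(R-1)/2) of the largest
weights as unweighted links, so the mean degree at fixed density is
invariant under any preprocessing that only reshuffles weights.

Negative correlations compete on their signed value (-0.9 is weaker than
0.1), and ties at the cutoff are broken by lexicographic node-pair order;
both choices are deliberate so that networks are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numpy.typing import NDArray

from .parcellate import ROITimeSeriesSet

__all__ = [
    "AdjacencyMatrix",
    "BinaryNetwork",
    "correlation_adjacency",
    "link_count_at_density",
    "threshold_to_density",
]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric ROI x ROI Pearson weight matrix with zero diagonal."""

    weights: NDArray[np.float64]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if (np.abs(np.diag(w)) > 0).any():
            raise ValueError("diagonal must be zero")
        if np.abs(w).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("correlation weights must lie in [-1, 1]")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Unweighted network: node indices 0..n_nodes-1, edges as (i, j), i < j."""

    n_nodes: int
    edges: NDArray[np.int64]
    density: float

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        bad = (e[:, 0] >= e[:, 1]) | (e < 0).any(axis=1) | (e >= self.n_nodes).any(axis=1)
        if e.size and bad.any():
            raise ValueError("edges must be 0-based pairs with i < j")
        object.__setattr__(self, "edges", e)

    @classmethod
    def from_edges(cls, n_nodes: int, edges) -> "BinaryNetwork":
        e = np.asarray(sorted(tuple(sorted(p)) for p in edges), dtype=np.int64)
        e = e.reshape(-1, 2)
        possible = n_nodes * (n_nodes - 1) // 2
        return cls(n_nodes=n_nodes, edges=e, density=len(e) / possible)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency_matrix(self) -> NDArray[np.float64]:
        a = np.zeros((self.n_nodes, self.n_nodes))
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


def correlation_adjacency(roits: ROITimeSeriesSet) -> AdjacencyMatrix:
    """Pearson correlation of every ROI pair; self-links removed."""
    if roits.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for correlations")
    sd = roits.series.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"ROI {roits.roi_ids[flat[0]]} has a constant series")
    a = np.corrcoef(roits.series)
    a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(weights=a)


def link_count_at_density(n_nodes: int, d: float) -> int:
    """Number of links at density d: round(d * n(n-1)/2), half rounded up."""
    if not 0 < d <= 1:
        raise ValueError("density must be in (0, 1]")
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    return int(math.floor(d * (n_nodes * (n_nodes - 1) // 2) + 0.5))


def threshold_to_density(
    adj: AdjacencyMatrix | NDArray[np.float64], d: float
) -> BinaryNetwork:
    """Keep exactly the top-k weighted node pairs as unweighted links.

    k = :func:`link_count_at_density`.  Selection is by signed weight; ties
    at the cutoff are resolved in lexicographic (i, j) order.
    """
    w = adj.weights if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    n = w.shape[0]
    k = link_count_at_density(n, d)
    iu, ju = np.triu_indices(n, 1)
    # np.lexsort sorts by the last key first: weight desc, then (i, j) asc
    order = np.lexsort((ju, iu, -w[iu, ju]))[:k]
    pairs = np.stack([iu[order], ju[order]], axis=1)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return BinaryNetwork(n_nodes=n, edges=pairs, density=d)
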