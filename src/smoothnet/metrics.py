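"""Node- and cohort-level network measures.

Covers everything the smoothing-sweep analysis reports: degree and
competition-style degree ranks, eigenvector centrality by power iteration,
largest connected components and their cross-subject membership fractions,
link prevalence, Fisher-Z arithmetic for averaging and differencing
correlation coefficients, and distance-binned link-weight profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import rankdata

from .network import BinaryNetwork
from .parcellate import LinkGeometry

__all__ = [
    "CentralityTable",
    "LCCResult",
    "degree",
    "degree_ranks",
    "eigenvector_centrality",
    "centrality_table",
    "largest_connected_component",
    "lcc_membership_fraction",
    "link_prevalence",
    "fisher_z",
    "inverse_fisher_z",
    "average_correlations",
    "correlation_difference",
    "weight_vs_distance_profile",
    "WeightDistanceProfile",
]

#: correlations are clipped to +/- (1 - _R_CLIP) before arctanh
_R_CLIP = 1e-7


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within max_iter."""


# ---------------------------------------------------------------------------
# node centralities
# ---------------------------------------------------------------------------


def degree(net: BinaryNetwork) -> NDArray[np.int64]:
    """Neighbor count per node."""
    deg = np.zeros(net.n_nodes, dtype=np.int64)
    if net.n_edges:
        np.add.at(deg, net.edges[:, 0], 1)
        np.add.at(deg, net.edges[:, 1], 1)
    return deg


def degree_ranks(degrees: NDArray[np.int64]) -> NDArray[np.int64]:
    """Competition ranking in descending degree order.

    Rank 1 is the largest degree; tied degrees share the minimum rank of
    their tie group and the next distinct degree gets 1 + (number of
    strictly greater nodes).
    """
    return rankdata(-np.asarray(degrees), method="min").astype(np.int64)


def _leading_eigenpair(a: NDArray[np.float64]) -> NDArray[np.float64]:
    """Nonnegative unit leading eigenvector via symmetric eigendecomposition."""
    w, v = np.linalg.eigh(a)
    vec = v[:, -1]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    if vec.min() < -1e-8:
        raise ConvergenceError(
            "leading eigenvector is not sign-consistent (degenerate spectrum)"
        )
    vec = np.clip(vec, 0.0, None)
    return vec / np.linalg.norm(vec)


def eigenvector_centrality(
    net: BinaryNetwork, tol: float = 1e-10, max_iter: int = 100_000
) -> NDArray[np.float64]:
    """Leading-eigenvector score of the binary adjacency matrix.

    Power iteration v <- A v / |A v|_2 from a uniform positive start until
    the successive-iterate L-infinity change drops below ``tol``.  Isolated
    nodes score 0.  If the largest connected component is bipartite the
    iteration would oscillate between the +/- lambda_max eigenspaces, so the
    computation falls back to a direct symmetric eigensolve.
    """
    if net.n_edges == 0:
        raise ValueError("network has no links")
    a = net.adjacency_matrix()
    lcc_nodes = sorted(largest_connected_component(net).nodes)
    sub = net.to_networkx().subgraph(lcc_nodes)
    if nx.is_bipartite(sub):
        return _leading_eigenpair(a)
    n = net.n_nodes
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = a @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ConvergenceError("iterate collapsed to zero")
        w /= nrm
        if np.max(np.abs(w - v)) < tol:
            return np.clip(w, 0.0, None)
        v = w
    residual = float(np.max(np.abs(a @ v / np.linalg.norm(a @ v) - v)))
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


@dataclass(frozen=True)
class CentralityTable:
    """Per-ROI degree, degree rank, and eigenvector centrality."""

    roi_ids: NDArray[np.int64]
    degree: NDArray[np.int64]
    degree_rank: NDArray[np.int64]
    eigenvector_centrality: NDArray[np.float64]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_ids,
                "degree": self.degree,
                "degree_rank": self.degree_rank,
                "eigenvector_centrality": self.eigenvector_centrality,
            }
        )


def centrality_table(net: BinaryNetwork) -> CentralityTable:
    deg = degree(net)
    return CentralityTable(
        roi_ids=np.arange(1, net.n_nodes + 1),
        degree=deg,
        degree_rank=degree_ranks(deg),
        eigenvector_centrality=eigenvector_centrality(net),
    )


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class LCCResult:
    """Largest connected component; ``tied`` flags a size tie resolved by
    taking the component containing the smallest node id."""

    nodes: frozenset[int]
    tied: bool = False

    def __contains__(self, node: int) -> bool:
        return node in self.nodes

    def __iter__(self):
        return iter(sorted(self.nodes))

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        if isinstance(other, LCCResult):
            return self.nodes == other.nodes
        return self.nodes == frozenset(other)

    def __hash__(self) -> int:
        return hash(self.nodes)


def largest_connected_component(net: BinaryNetwork) -> LCCResult:
    """Maximum-cardinality component (singletons count as components)."""
    comps = [frozenset(c) for c in nx.connected_components(net.to_networkx())]
    top = max(len(c) for c in comps)
    winners = [c for c in comps if len(c) == top]
    winners.sort(key=min)
    return LCCResult(nodes=winners[0], tied=len(winners) > 1)


def lcc_membership_fraction(networks: list[BinaryNetwork]) -> NDArray[np.float64]:
    """Per node, the fraction of subjects whose LCC contains it."""
    if not networks:
        raise ValueError("empty cohort")
    n = networks[0].n_nodes
    if any(net.n_nodes != n for net in networks):
        raise ValueError("all networks must share the node set")
    counts = np.zeros(n)
    for net in networks:
        counts[sorted(largest_connected_component(net).nodes)] += 1
    return counts / len(networks)


def link_prevalence(networks: list[BinaryNetwork]) -> NDArray[np.float64]:
    """Per node pair, the fraction of subjects whose network has the link."""
    if not networks:
        raise ValueError("empty cohort")
    n = networks[0].n_nodes
    if any(net.n_nodes != n for net in networks):
        raise ValueError("all networks must share the node set")
    counts = np.zeros((n, n))
    for net in networks:
        counts += net.adjacency_matrix()
    return counts / len(networks)


# ---------------------------------------------------------------------------
# Fisher-Z arithmetic
# ---------------------------------------------------------------------------


def _clip_r(r: NDArray[np.float64]) -> NDArray[np.float64]:
    r = np.asarray(r, dtype=np.float64)
    if not np.isfinite(r).all() or (np.abs(r) > 1 + 1e-12).any():
        raise ValueError("correlations must be finite and in [-1, 1]")
    if (np.abs(r) >= 1 - _R_CLIP).any():
        warnings.warn(
            "correlations at +/-1 clipped before Fisher transform",
            RuntimeWarning,
            stacklevel=3,
        )
        r = np.clip(r, -(1 - _R_CLIP), 1 - _R_CLIP)
    return r


def fisher_z(r):
    """Fisher transform Z = arctanh(r), clipping |r| at 1 - 1e-7."""
    return np.arctanh(_clip_r(r))


def inverse_fisher_z(z):
    """Inverse Fisher transform r = tanh(Z)."""
    return np.tanh(np.asarray(z, dtype=np.float64))


def average_correlations(rs, axis=None):
    """Bias-reduced mean of correlations: tanh(mean(arctanh(r)))."""
    return np.tanh(np.mean(fisher_z(rs), axis=axis))


def correlation_difference(r1, r2):
    """Difference of two correlations on the Fisher-Z scale."""
    return fisher_z(r1) - fisher_z(r2)


# ---------------------------------------------------------------------------
# distance-resolved weight profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightDistanceProfile:
    """Per-bin Fisher-averaged link weight vs. centroid distance.

    ``bins`` columns: bin_lo_mm, bin_hi_mm, bin_center_mm, mean_weight
    (NaN where the bin holds no pairs), n_pairs.  ``homotopic`` lists
    mirror-hemisphere pairs separately (roi_i, roi_j, distance_mm, weight).
    """

    bins: pd.DataFrame
    homotopic: pd.DataFrame | None = None


def weight_vs_distance_profile(
    adj,
    geometry: LinkGeometry,
    bin_edges_mm: NDArray[np.float64] | None = None,
    homotopic_pairs: tuple[tuple[int, int], ...] = (),
) -> WeightDistanceProfile:
    """Bin unordered ROI pairs by centroid distance and Fisher-average the
    link weights within each bin (bins are left-closed, right-open)."""
    w = adj.weights if hasattr(adj, "weights") else np.asarray(adj, float)
    d = geometry.centroid_distance_mm
    if w.shape != d.shape:
        raise ValueError("adjacency and geometry sizes differ")
    iu, ju = np.triu_indices(w.shape[0], 1)
    dists = d[iu, ju]
    if bin_edges_mm is None:
        top = np.ceil(dists.max() / 10.0) * 10.0
        bin_edges_mm = np.arange(0.0, top + 10.0, 10.0)
    edges = np.asarray(bin_edges_mm, dtype=np.float64)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    if dists.min() < edges[0] or dists.max() >= edges[-1]:
        raise ValueError("bin edges do not cover the observed distances")
    idx = np.digitize(dists, edges) - 1
    weights = w[iu, ju]
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n_pairs = int(sel.sum())
        mean_w = float(average_correlations(weights[sel])) if n_pairs else np.nan
        rows.append(
            {
                "bin_lo_mm": edges[b],
                "bin_hi_mm": edges[b + 1],
                "bin_center_mm": (edges[b] + edges[b + 1]) / 2.0,
                "mean_weight": mean_w,
                "n_pairs": n_pairs,
            }
        )
    homotopic = None
    if homotopic_pairs:
        homotopic = pd.DataFrame(
            {
                "roi_i": [a for a, _ in homotopic_pairs],
                "roi_j": [b for _, b in homotopic_pairs],
                "distance_mm": [d[a - 1, b - 1] for a, b in homotopic_pairs],
                "weight": [w[a - 1, b - 1] for a, b in homotopic_pairs],
            }
        )
    return WeightDistanceProfile(bins=pd.DataFrame(rows), homotopic=homotopic)
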