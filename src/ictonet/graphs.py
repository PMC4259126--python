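"""Graph measures and mean-degree-preserving artificial networks.

Implements the measures used to characterize functional networks — mean
degree (MD), degree variance (DV), and local clustering coefficient (CC) —
plus the construction of artificial binary surrogates: thresholding a
weighted network at the level that preserves its mean degree, then
scrambling topology by degree-preserving double-edge swaps.  The surrogates
isolate mean degree from all other topological structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .funcnet import FunctionalNetwork

__all__ = [
    "BinaryNetwork",
    "GraphMeasures",
    "measures",
    "binarize_preserving_md",
    "degree_preserving_randomize",
    "spectrum",
    "make_artificial_ensemble",
]


@dataclass
class BinaryNetwork:
    """Undirected binary (0/1) network with provenance of its construction."""

    adjacency: np.ndarray
    labels: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency entries must be exactly 0 or 1")
        a = a.astype(np.int8)
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a
        if self.labels is None:
            self.labels = [f"n{i}" for i in range(a.shape[0])]
        elif len(self.labels) != a.shape[0]:
            raise ValueError("labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GraphMeasures:
    """Node degrees, mean degree, degree variance, and clustering."""

    degrees: np.ndarray
    mean_degree: float
    degree_variance: float  # population variance of the degrees
    local_cc: np.ndarray
    mean_cc: float


def _as_adjacency(network) -> tuple[np.ndarray, bool]:
    """Extract a validated (adjacency, is_binary) pair from any network type."""
    if isinstance(network, BinaryNetwork):
        return network.adjacency.astype(float), True
    if isinstance(network, FunctionalNetwork):
        a = network.adjacency
    else:
        a = np.asarray(network, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
    is_binary = bool(np.all((a == 0) | (a == 1)))
    return a.astype(float), is_binary


def measures(network) -> GraphMeasures:
    """Compute MD, DV, and local CC for a weighted or binary network.

    Degrees are row sums of the adjacency (edge counts for binary networks,
    summed weights otherwise).  DV is the population variance of the
    degrees.  Local CC uses the Watts-Strogatz triangle fraction on binary
    networks and the Onnela geometric-mean generalization on weighted ones;
    nodes of degree < 2 get CC = 0.
    """
    a, is_binary = _as_adjacency(network)
    degrees = a.sum(axis=1)
    g = nx.from_numpy_array(a)
    cc_dict = nx.clustering(g, weight=None if is_binary else "weight")
    local_cc = np.array([cc_dict[i] for i in range(a.shape[0])], dtype=float)
    return GraphMeasures(
        degrees=degrees,
        mean_degree=float(degrees.mean()),
        degree_variance=float(degrees.var()),
        local_cc=local_cc,
        mean_cc=float(local_cc.mean()),
    )


def binarize_preserving_md(network: FunctionalNetwork) -> BinaryNetwork:
    """Threshold a weighted network at the level that preserves mean degree.

    Scans candidate thresholds (0 plus every distinct off-diagonal weight),
    keeps edges with weight strictly above the threshold, and returns the
    binary network whose binary MD is closest to the weighted MD.  Ties pick
    the lower threshold (denser network).  The chosen threshold and the
    residual MD gap are recorded in the provenance.
    """
    w = network.adjacency
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    upper = w[iu]
    uniq = np.unique(upper)
    if uniq.size < 2:
        raise ValueError(
            "all off-diagonal weights are equal: no threshold can resolve MD"
        )
    md_weighted = 2.0 * upper.sum() / n
    candidates = np.concatenate(([0.0], uniq)) if uniq[0] > 0 else uniq
    best_thr, best_gap = None, np.inf
    for thr in candidates:  # ascending, so ties keep the lower threshold
        md_bin = 2.0 * np.count_nonzero(upper > thr) / n
        gap = abs(md_bin - md_weighted)
        if gap < best_gap:
            best_thr, best_gap = float(thr), gap
    adj = (w > best_thr).astype(np.int8)
    return BinaryNetwork(
        adj,
        list(network.labels),
        provenance={
            "source": "binarize_preserving_md",
            "threshold": best_thr,
            "weighted_md": md_weighted,
            "md_gap": best_gap,
        },
    )


def degree_preserving_randomize(
    network: BinaryNetwork, n_swaps: int | None = None, seed: int | None = None
) -> BinaryNetwork:
    """Randomize topology by double-edge swaps that preserve every degree.

    Attempts ``n_swaps`` swaps (default ``10 * n_edges``, a standard mixing
    heuristic): pick two edges (u,v), (x,y) and rewire to (u,y), (x,v),
    rejecting any swap that would create a self-loop or duplicate edge.  The
    degree vector of the output equals the input's exactly; graphs admitting
    no valid swap (e.g. stars) are returned unchanged.
    """
    if network.n_edges < 2:
        raise ValueError("degree-preserving randomization needs at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * network.n_edges
    rng = np.random.default_rng(seed)
    adj = network.adjacency.copy()
    edges = [tuple(e) for e in np.argwhere(np.triu(adj, k=1))]
    accepted = 0
    for _ in range(n_swaps):
        ei, ej = rng.integers(len(edges)), rng.integers(len(edges))
        if ei == ej:
            continue
        u, v = edges[ei]
        x, y = edges[ej]
        if rng.random() < 0.5:  # both pairings of the two edges are reachable
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, y] or adj[x, v]:
            continue
        adj[u, v] = adj[v, u] = 0
        adj[x, y] = adj[y, x] = 0
        adj[u, y] = adj[y, u] = 1
        adj[x, v] = adj[v, x] = 1
        edges[ei] = (u, y)
        edges[ej] = (x, v)
        accepted += 1
    return BinaryNetwork(
        adj,
        list(network.labels),
        provenance={
            **network.provenance,
            "randomized": True,
            "n_swap_attempts": n_swaps,
            "n_swaps_accepted": accepted,
            "seed": seed,
        },
    )


def spectrum(network) -> np.ndarray:
    """Adjacency eigenvalues in descending order (real, by symmetry)."""
    a, _ = _as_adjacency(network)
    return np.sort(np.linalg.eigvalsh(a))[::-1]


def make_artificial_ensemble(
    network: FunctionalNetwork, n: int, seed: int | None = None, n_swaps: int | None = None
) -> list[BinaryNetwork]:
    """MD-preserving binarization followed by ``n`` independent randomizations.

    Every member shares the degree *sum* (hence MD) of the binarized source;
    individual degree vectors equal the binarized network's exactly.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    binary = binarize_preserving_md(network)
    seeds = np.random.SeedSequence(seed).spawn(n)
    return [
        degree_preserving_randomize(
            binary, n_swaps=n_swaps, seed=int(s.generate_state(1)[0] % (2**31))
        )
        for s in seeds
    ]
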