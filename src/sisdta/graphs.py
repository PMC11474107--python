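"""Relationship-graph construction from a similarity matrix.

Pipeline: threshold at δ → k-NN backfill of orphan nodes → unit self-loops →
symmetric degree normalization D̂^{-1/2} Â D̂^{-1/2}.  Adjacency entry (i, j)
is the weight node i collects from node j, so a node's row sums over its
information sources; with the asymmetric SIS kernel the result is a directed
graph, with a symmetric kernel (e.g. normalized Smith–Waterman for proteins)
the whole pipeline preserves symmetry.

The backfill step guarantees every node at least min(k, N-1) in-neighbors:
after thresholding, an orphan drug would have no sources to learn from, so
it is reattached to its most similar peers at their original (sub-threshold)
weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, DomainError, InputError
from .similarity import SimilarityMatrix

DEFAULT_DELTA = 0.6  # Davis-like datasets; 0.7 for KIBA-like
DEFAULT_K = 5


@dataclass
class WeightedDigraph:
    """Weighted adjacency; entry (i, j) = weight node i collects from node j."""

    node_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.node_ids)
        if self.adjacency.shape != (n, n):
            raise InputError(f"adjacency shape {self.adjacency.shape} != ({n}, {n})")
        if self.adjacency.min() < -1e-12 or self.adjacency.max() > 1 + 1e-12:
            raise InputError("edge weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def in_degrees(self) -> np.ndarray:
        """Number of off-diagonal nonzero entries per row (information sources)."""
        off = self.adjacency.copy()
        np.fill_diagonal(off, 0.0)
        return (off > 0).sum(axis=1)


@dataclass
class NormalizedAdjacency:
    """D̂^{-1/2} Â D̂^{-1/2} of a source digraph."""

    matrix: np.ndarray
    source: WeightedDigraph

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise DomainError("normalized adjacency has non-finite entries")


def threshold_edges(S: SimilarityMatrix, delta: float) -> WeightedDigraph:
    """Keep edge (i, j) iff S(i, j) >= delta; diagonal left at 0 here."""
    if not 0.0 <= delta <= 1.0:
        raise ConfigError(f"delta must be in [0, 1], got {delta}")
    adj = np.where(S.values >= delta, S.values, 0.0)
    np.fill_diagonal(adj, 0.0)
    return WeightedDigraph(list(S.entity_ids), adj)


def knn_backfill(G: WeightedDigraph, S: SimilarityMatrix, k: int) -> WeightedDigraph:
    """Ensure each node has >= min(k, N-1) in-neighbors.

    Nodes short of sources gain edges from their most similar non-neighbors
    at the original similarity weights; ties break by descending similarity
    then ascending node index, so the result is deterministic.  Existing
    edges are never touched.
    """
    if k < 0:
        raise ConfigError("k must be >= 0")
    n = G.n
    adj = G.adjacency.copy()
    target = min(k, n - 1)
    for i in range(n):
        row = adj[i].copy()
        row[i] = 0.0
        have = int((row > 0).sum())
        if have >= target:
            continue
        candidates = [j for j in range(n) if j != i and adj[i, j] == 0.0]
        # stable sort on ascending index, then stable sort on descending sim
        candidates.sort()
        candidates.sort(key=lambda j: -S.values[i, j])
        for j in candidates[: target - have]:
            adj[i, j] = S.values[i, j]
    return WeightedDigraph(list(G.node_ids), adj)


def add_self_loops(G: WeightedDigraph) -> WeightedDigraph:
    """Set the diagonal to 1 (a node always keeps its own information)."""
    adj = G.adjacency.copy()
    np.fill_diagonal(adj, 1.0)
    return WeightedDigraph(list(G.node_ids), adj)


def normalize_adjacency(G: WeightedDigraph) -> NormalizedAdjacency:
    """Symmetric degree normalization D̂^{-1/2} Â D̂^{-1/2}, D̂ = diag(row sums)."""
    row_sums = G.adjacency.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = [G.node_ids[i] for i in np.flatnonzero(row_sums <= 0)]
        raise DomainError(
            f"zero row sum for node(s) {bad}; add self-loops before normalizing"
        )
    d = 1.0 / np.sqrt(row_sums)
    return NormalizedAdjacency(d[:, None] * G.adjacency * d[None, :], G)


def build_relationship_graph(
    S: SimilarityMatrix,
    delta: float = DEFAULT_DELTA,
    k: int = DEFAULT_K,
    symmetric: bool = False,
) -> tuple[WeightedDigraph, NormalizedAdjacency]:
    """Full pipeline: threshold → backfill → self-loops → normalize.

    With ``symmetric=True`` (undirected protein graphs) the input matrix must
    be symmetric and backfilled edges are mirrored so the adjacency stays
    equal to its transpose.
    """
    if symmetric and not S.symmetric:
        raise InputError("symmetric graph requested from an asymmetric similarity matrix")
    G = threshold_edges(S, delta)
    G = knn_backfill(G, S, k)
    if symmetric:
        adj = np.maximum(G.adjacency, G.adjacency.T)
        G = WeightedDigraph(G.node_ids, adj)
    G = add_self_loops(G)
    return G, normalize_adjacency(G)


def write_edge_list(G: WeightedDigraph, path: str | Path) -> None:
    """TSV (collector, source, weight) including self-loops; round-trippable."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("collector\tsource\tweight\n")
        for i, src_id in enumerate(G.node_ids):
            for j, dst_id in enumerate(G.node_ids):
                w = G.adjacency[i, j]
                if w != 0.0:
                    fh.write(f"{src_id}\t{dst_id}\t{w:.10g}\n")


def read_edge_list(path: str | Path, node_ids: list[str]) -> WeightedDigraph:
    index = {nid: i for i, nid in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)))
    lines = Path(path).read_text(encoding="utf-8-sig").replace("\r\n", "\n").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        a, b, w = line.split("\t")
        adj[index[a], index[b]] = float(w)
    return WeightedDigraph(list(node_ids), adj)
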