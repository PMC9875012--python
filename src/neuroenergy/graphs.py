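"""Directed graph generation and I/O for network simulations.

The study networks are directed binary graphs sized to the C. elegans
somatic connectome used as the biological reference: 297 neurons and
2,345 directed gap-junction edges.  Three synthetic families (Erdos-Renyi,
Watts-Strogatz, Barabasi-Albert) are generated at matched size and density
so every downstream stage runs without external data; a loader accepts a
user-supplied connectome as an edge list or adjacency CSV.

Construction of the directed variants:

* ER is drawn as a directed G(n, m) — exactly ``target_edges`` distinct
  directed non-self edges, uniformly without replacement.
* WS builds the canonical undirected rewired ring lattice and symmetrizes
  it (each undirected edge contributes both directions), giving
  ``n * neighbors`` directed edges — within a few percent of the target
  at the default parameters.
* BA grows the canonical undirected preferential-attachment graph, orients
  each edge uniformly at random, then adds (or removes) uniformly random
  directed edges to hit ``target_edges`` exactly while preserving the
  heavy-tailed degree distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DirectedGraph",
    "StimulusVector",
    "generate_er",
    "generate_ws",
    "generate_ba",
    "load_connectome",
    "save_graph",
    "draw_stimulus",
    "CELEGANS_N",
    "CELEGANS_EDGES",
]

#: Node and edge counts of the reference C. elegans network.
CELEGANS_N = 297
CELEGANS_EDGES = 2345


class GraphSpecError(ValueError):
    """Raised when generator parameters are infeasible."""


class GraphFormatError(ValueError):
    """Raised when a graph file does not parse in the declared format."""


@dataclass(frozen=True)
class DirectedGraph:
    """Binary directed graph; ``adjacency[i, j] == 1`` iff edge i -> j.

    Neuron ``j`` receives gap-junction current from every presynaptic
    neuron ``i`` with ``adjacency[i, j] == 1``.
    """

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise GraphFormatError(f"adjacency must be square, got {A.shape}")
        if not np.isin(A, (0, 1)).all():
            raise GraphFormatError("adjacency entries must be 0/1")
        if np.diagonal(A).any():
            raise GraphFormatError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", A.astype(np.int8))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def edges(self) -> set[tuple[int, int]]:
        src, dst = np.nonzero(self.adjacency)
        return set(zip(src.tolist(), dst.tolist()))

    def in_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def total_degree(self) -> np.ndarray:
        return self.in_degree() + self.out_degree()

    @classmethod
    def empty(cls, n: int) -> "DirectedGraph":
        return cls(np.zeros((n, n), dtype=np.int8))

    @classmethod
    def from_edges(cls, n: int, edges) -> "DirectedGraph":
        A = np.zeros((n, n), dtype=np.int8)
        for i, j in edges:
            A[i, j] = 1
        return cls(A)


@dataclass(frozen=True)
class StimulusVector:
    """Per-neuron constant stimulus current in uA (per 1 cm^2 membrane)."""

    currents: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "currents", np.asarray(self.currents, dtype=np.float64)
        )

    @property
    def n(self) -> int:
        return self.currents.shape[0]


def _check_edge_budget(n: int, target_edges: int) -> None:
    cap = n * (n - 1)
    if not 0 < target_edges <= cap:
        raise GraphSpecError(
            f"target_edges={target_edges} outside (0, {cap}] for n={n}"
        )


def generate_er(n: int, target_edges: int, seed: int) -> DirectedGraph:
    """Directed Erdos-Renyi G(n, m): exactly ``target_edges`` edges.

    The fixed-edge-count construction is used (rather than G(n, p)) so the
    edge budget of the reference connectome is matched exactly.
    """
    _check_edge_budget(n, target_edges)
    g = nx.gnm_random_graph(n, target_edges, seed=int(seed), directed=True)
    A = nx.to_numpy_array(g, dtype=np.int8, nodelist=range(n))
    return DirectedGraph(A)


def generate_ws(
    n: int, neighbors: int, rewire_prob: float, seed: int
) -> DirectedGraph:
    """Directed Watts-Strogatz graph: rewired ring lattice, symmetrized.

    Each undirected edge of the classical WS graph becomes a reciprocal
    pair of directed edges, so the directed edge count is ``n * neighbors``
    (rewiring preserves the count).
    """
    if neighbors % 2 != 0:
        raise GraphSpecError(f"neighbors must be even, got {neighbors}")
    if neighbors >= n:
        raise GraphSpecError("neighbors must be < n")
    if not 0.0 <= rewire_prob <= 1.0:
        raise GraphSpecError("rewire_prob must lie in [0, 1]")
    g = nx.watts_strogatz_graph(n, neighbors, rewire_prob, seed=int(seed))
    A = nx.to_numpy_array(g, dtype=np.int8, nodelist=range(n))
    A = np.maximum(A, A.T)  # symmetrize: both directions per undirected edge
    np.fill_diagonal(A, 0)
    return DirectedGraph(A)


def _adjust_edge_count(
    A: np.ndarray, target_edges: int, rng: np.random.Generator
) -> np.ndarray:
    """Add or delete uniformly random directed edges to hit the target."""
    n = A.shape[0]
    current = int(A.sum())
    if current < target_edges:
        free = np.flatnonzero((A == 0).ravel())
        diag = np.arange(n) * (n + 1)
        free = np.setdiff1d(free, diag, assume_unique=False)
        pick = rng.choice(free, size=target_edges - current, replace=False)
        A.ravel()[pick] = 1
    elif current > target_edges:
        occupied = np.flatnonzero(A.ravel())
        pick = rng.choice(occupied, size=current - target_edges, replace=False)
        A.ravel()[pick] = 0
    return A


def generate_ba(
    n: int, attach: int, target_edges: int, seed: int
) -> DirectedGraph:
    """Directed Barabasi-Albert graph with exactly ``target_edges`` edges.

    Grows the undirected preferential-attachment graph (``attach`` edges
    per new node), orients every edge uniformly at random, then tops up
    (or trims) with uniformly random directed edges to reach the target.
    The heavy-tailed degree distribution survives the adjustment because
    the added/removed edges are a small uniform perturbation.
    """
    if not 1 <= attach < n:
        raise GraphSpecError(f"attach must be in [1, n), got {attach}")
    _check_edge_budget(n, target_edges)
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, attach, seed=int(seed))
    A = np.zeros((n, n), dtype=np.int8)
    for u, v in g.edges():
        if rng.random() < 0.5:
            u, v = v, u
        A[u, v] = 1
    A = _adjust_edge_count(A, target_edges, rng)
    return DirectedGraph(A)


def load_connectome(
    path: str | Path, format: str = "edge_list", one_based: bool = False
) -> DirectedGraph:
    """Load a user-supplied connectome as a DirectedGraph.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edge_list"`` — whitespace-separated "source target" pairs, one
        per line, ``#`` comments allowed; or ``"adjacency_csv"`` — an
        n x n CSV of 0/1 entries with row index = source.
    one_based
        For edge lists whose node ids start at 1.

    Self-loops are dropped with a warning; weighted entries are rejected
    (synapse weights are not modeled).
    """
    path = Path(path)
    if format == "edge_list":
        pairs: list[tuple[int, int]] = []
        for raw in path.read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphFormatError(f"bad edge-list line in {path}: {raw!r}")
            i, j = int(parts[0]), int(parts[1])
            if one_based:
                i, j = i - 1, j - 1
            pairs.append((i, j))
        if not pairs:
            raise GraphFormatError(f"no edges found in {path}")
        n = max(max(i, j) for i, j in pairs) + 1
        A = np.zeros((n, n), dtype=np.int8)
        for i, j in pairs:
            A[i, j] = 1
    elif format == "adjacency_csv":
        A = np.loadtxt(path, delimiter=",", dtype=np.float64)
        A = np.atleast_2d(A)
        if A.shape[0] != A.shape[1]:
            raise GraphFormatError(
                f"adjacency in {path} is not square: {A.shape}"
            )
        if not np.isin(A, (0, 1)).all():
            raise GraphFormatError(
                f"adjacency in {path} has non-binary entries"
            )
        A = A.astype(np.int8)
    else:
        raise ValueError(f"unknown format {format!r}")

    if np.diagonal(A).any():
        k = int(np.diagonal(A).sum())
        warnings.warn(
            f"{path}: dropped {k} self-loop(s)", stacklevel=2
        )
        np.fill_diagonal(A, 0)
    return DirectedGraph(A)


def save_graph(
    graph: DirectedGraph, path: str | Path, format: str = "edge_list"
) -> None:
    """Write a graph so that :func:`load_connectome` round-trips it."""
    path = Path(path)
    if format == "edge_list":
        src, dst = np.nonzero(graph.adjacency)
        lines = [f"{i} {j}" for i, j in zip(src.tolist(), dst.tolist())]
        path.write_text("\n".join(lines) + "\n")
    elif format == "adjacency_csv":
        np.savetxt(path, graph.adjacency, fmt="%d", delimiter=",")
    else:
        raise ValueError(f"unknown format {format!r}")


def draw_stimulus(
    n: int, lo: float = 7.0, hi: float = 30.0, seed: int = 0
) -> StimulusVector:
    """Per-neuron constant currents drawn i.i.d. uniform on [lo, hi] uA."""
    if not lo < hi:
        raise GraphSpecError(f"require lo < hi, got [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    return StimulusVector(rng.uniform(lo, hi, size=n), seed=seed)
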