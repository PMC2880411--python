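"""Regular-graph construction, type assignment, and frequency summaries.

The population is a fixed undirected k-regular graph with a type label in
{A, C} on every vertex.  Summaries report the global fractions P_A, P_C, the
ordered-pair edge frequencies P_AA, P_AC, P_CA, P_CC (each undirected edge
counted once per direction, which makes P_AC == P_CA an identity), and the
conditional neighbour frequencies q_X|Y = P_XY / P_Y.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "NetworkConfig",
    "GraphState",
    "StateSummary",
    "build_regular_graph",
    "assign_types",
    "summarize_state",
    "neighbor_array",
    "save_graph_fixture",
    "load_graph_fixture",
]

TOPOLOGIES = ("random-regular", "ring", "torus")

# label encoding shared with the simulation kernel
TYPE_C = 0
TYPE_A = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Structural parameters of the cell network.

    N cells each link to exactly k neighbours.  ``topology`` selects how the
    regular graph is wired: 'random-regular' (default; configuration model
    with rejection), 'ring' (circulant, k even), or 'torus' (periodic square
    lattice, k=4, N a perfect square).
    """

    N: int
    k: int
    topology: str = "random-regular"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"N must be positive, got {self.N}")
        if not (2 <= self.k < self.N):
            raise ValueError(f"need 2 <= k < N, got k={self.k}, N={self.N}")
        if (self.N * self.k) % 2 != 0:
            raise ValueError(
                f"N*k must be even (handshake lemma), got N={self.N}, k={self.k}"
            )
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}"
            )
        if self.topology == "ring" and self.k % 2 != 0:
            raise ValueError("ring topology requires even k")
        if self.topology == "torus":
            if self.k != 4:
                raise ValueError("torus topology requires k=4")
            side = int(round(self.N ** 0.5))
            if side * side != self.N:
                raise ValueError("torus topology requires N to be a perfect square")


@dataclass
class GraphState:
    """A k-regular graph with a type label on every vertex.

    ``types`` is an int8 array with 1 for type A and 0 for type C.
    """

    graph: nx.Graph
    types: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.types = np.asarray(self.types, dtype=np.int8)
        if self.types.shape != (self.graph.number_of_nodes(),):
            raise ValueError("types array must have one entry per vertex")

    @property
    def N(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_A(self) -> int:
        return int(self.types.sum())

    @property
    def n_C(self) -> int:
        return self.N - self.n_A

    def copy(self) -> "GraphState":
        return GraphState(self.graph, self.types.copy(), self.k)


@dataclass(frozen=True)
class StateSummary:
    """Global, pair and conditional frequencies of a labelled network state.

    Satisfies the closure identities P_A + P_C = 1,
    P_AA + P_AC + P_CA + P_CC = 1, P_AC = P_CA, q_A|Y + q_C|Y = 1 and
    P_XY = q_X|Y * P_Y.  A conditional q_X|Y is reported as 0 when type Y is
    absent (``absent_types`` flags this); the dynamics never consults it at
    absorption.
    """

    P_A: float
    P_C: float
    P_AA: float
    P_AC: float
    P_CA: float
    P_CC: float
    q_A_given_A: float
    q_C_given_A: float
    q_A_given_C: float
    q_C_given_C: float
    absent_types: tuple[str, ...] = field(default=())


def build_regular_graph(cfg: NetworkConfig, max_retries: int = 100) -> nx.Graph:
    """Build a connected simple k-regular graph, deterministic given the seed.

    The random-regular topology draws from the configuration model with
    rejection of self-loops/multi-edges (networkx ``random_regular_graph``)
    and retries with derived seeds until the sample is connected.
    """
    if cfg.topology == "ring":
        # circulant: each vertex linked to the k/2 nearest on each side
        g = nx.circulant_graph(cfg.N, list(range(1, cfg.k // 2 + 1)))
    elif cfg.topology == "torus":
        side = int(round(cfg.N ** 0.5))
        g = nx.grid_2d_graph(side, side, periodic=True)
        g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    else:
        g = None
        for attempt in range(max_retries):
            cand = nx.random_regular_graph(cfg.k, cfg.N, seed=cfg.seed + attempt)
            if nx.is_connected(cand):
                g = cand
                break
        if g is None:
            raise RuntimeError(
                f"failed to sample a connected {cfg.k}-regular graph on "
                f"{cfg.N} vertices after {max_retries} attempts"
            )
    degrees = [d for _, d in g.degree()]
    assert all(d == cfg.k for d in degrees)
    return g


def assign_types(
    graph: nx.Graph, n_A: int, seed: int, k: int | None = None,
    clustered: bool = False,
) -> GraphState:
    """Label exactly ``n_A`` vertices as type A, the rest type C.

    Placement is uniform without replacement (deterministic given seed).
    ``clustered=True`` instead grows one connected patch of A cells by
    breadth-first search from a random root — a robustness fixture, not the
    default initial condition.
    """
    N = graph.number_of_nodes()
    if not (0 <= n_A <= N):
        raise ValueError(f"n_A must be in [0, {N}], got {n_A}")
    if k is None:
        k = next(iter(dict(graph.degree()).values())) if N else 0
    rng = np.random.default_rng(seed)
    types = np.zeros(N, dtype=np.int8)
    if clustered and 0 < n_A < N:
        root = int(rng.integers(N))
        chosen: list[int] = []
        seen = {root}
        frontier = [root]
        while frontier and len(chosen) < n_A:
            v = frontier.pop(0)
            chosen.append(v)
            for u in graph.neighbors(v):
                if u not in seen:
                    seen.add(u)
                    frontier.append(u)
        types[chosen[:n_A]] = TYPE_A
    else:
        idx = rng.choice(N, size=n_A, replace=False)
        types[idx] = TYPE_A
    return GraphState(graph, types, k)


def _edge_type_counts(state: GraphState) -> tuple[int, int, int]:
    """Undirected edge counts (m_AA, m_AC, m_CC)."""
    t = state.types
    m_AA = m_AC = m_CC = 0
    for u, v in state.graph.edges():
        s = int(t[u]) + int(t[v])
        if s == 2:
            m_AA += 1
        elif s == 1:
            m_AC += 1
        else:
            m_CC += 1
    return m_AA, m_AC, m_CC


def summarize_state(state: GraphState) -> StateSummary:
    """Compute global, pair and conditional frequencies of the current state."""
    N = state.N
    n_A = state.n_A
    m_AA, m_AC, m_CC = _edge_type_counts(state)
    return summary_from_counts(N, state.k, n_A, m_AA, m_AC, m_CC)


def summary_from_counts(
    N: int, k: int, n_A: int, m_AA: int, m_AC: int, m_CC: int
) -> StateSummary:
    """Build a :class:`StateSummary` from population and undirected edge counts.

    Used both by :func:`summarize_state` and by the simulation kernel, which
    maintains the edge counts incrementally.
    """
    n_dir = N * k  # directed edge count = 2 |E|
    P_A = n_A / N
    P_C = 1.0 - P_A
    P_AA = 2.0 * m_AA / n_dir
    P_CC = 2.0 * m_CC / n_dir
    P_AC = m_AC / n_dir  # ordered A->C
    P_CA = P_AC
    absent = []
    if n_A == 0:
        absent.append("A")
    if n_A == N:
        absent.append("C")
    q_A_A = P_AA / P_A if n_A > 0 else 0.0
    q_C_A = P_CA / P_A if n_A > 0 else 0.0
    q_A_C = P_AC / P_C if n_A < N else 0.0
    q_C_C = P_CC / P_C if n_A < N else 0.0
    return StateSummary(
        P_A=P_A, P_C=P_C,
        P_AA=P_AA, P_AC=P_AC, P_CA=P_CA, P_CC=P_CC,
        q_A_given_A=q_A_A, q_C_given_A=q_C_A,
        q_A_given_C=q_A_C, q_C_given_C=q_C_C,
        absent_types=tuple(absent),
    )


def neighbor_array(graph: nx.Graph, k: int) -> np.ndarray:
    """Adjacency of a k-regular graph as an (N, k) int32 array of neighbour ids."""
    N = graph.number_of_nodes()
    out = np.empty((N, k), dtype=np.int32)
    for v in range(N):
        nbrs = list(graph.neighbors(v))
        if len(nbrs) != k:
            raise ValueError(f"vertex {v} has degree {len(nbrs)}, expected {k}")
        out[v, :] = nbrs
    return out


def save_graph_fixture(state: GraphState, edges_path: str | Path,
                       labels_path: str | Path) -> None:
    """Write a graph fixture: edge list ('u v' per line) + label CSV."""
    with open(edges_path, "w") as fh:
        for u, v in sorted(state.graph.edges()):
            fh.write(f"{u} {v}\n")
    with open(labels_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_id", "type"])
        for v in range(state.N):
            w.writerow([v, "A" if state.types[v] == TYPE_A else "C"])


def load_graph_fixture(edges_path: str | Path,
                       labels_path: str | Path) -> GraphState:
    """Read a graph fixture written by :func:`save_graph_fixture`."""
    g = nx.Graph()
    with open(edges_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, v = line.split()
            g.add_edge(int(u), int(v))
    with open(labels_path) as fh:
        rows = list(csv.DictReader(fh))
    N = g.number_of_nodes()
    if len(rows) != N:
        raise ValueError(
            f"label file has {len(rows)} rows but graph has {N} vertices"
        )
    types = np.zeros(N, dtype=np.int8)
    for row in rows:
        types[int(row["vertex_id"])] = TYPE_A if row["type"] == "A" else TYPE_C
    degrees = {d for _, d in g.degree()}
    if len(degrees) != 1:
        raise ValueError(f"fixture graph is not regular: degrees {sorted(degrees)}")
    return GraphState(g, types, degrees.pop())
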