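"""Graph Ricci curvature: Forman, Ollivier, and multiscale profiles.

Two discrete curvatures are supported on simple undirected graphs:

* Forman-Ricci curvature of an edge (a1, a2), in the clique-complex form
  limited to triangles:  ``4 - deg(a1) - deg(a2) + 3 * (#triangles through
  the edge)``.  The triangle-free form is the special case with zero
  triangles.
* Ollivier-Ricci curvature ``k_alpha = 1 - W(m_i, m_j) / d(i, j)`` where
  ``m_a`` is the lazy random-walk measure placing mass ``alpha`` on ``a``
  and ``(1 - alpha)/deg(a)`` on each neighbour, ``d`` is the graph
  distance, and ``W`` is the optimal-transport (Wasserstein-1) distance
  solved exactly as a transportation linear program.

The multiscale profile of an edge concatenates its curvature across a
nested sequence of distance-filtration subgraphs: threshold ``l_k`` keeps
all nodes and exactly the edges of weight <= ``l_k``; an edge absent from a
subgraph contributes 0 at that position.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .graph import InteractionGraph

#: Filtration thresholds used by default: 0.0, 0.1, ..., 4.9 Angstrom.
DEFAULT_FILTRATIONS: np.ndarray = np.round(np.arange(50) * 0.1, 10)
DEFAULT_ALPHA = 0.5


def forman_curvature(graph: nx.Graph, edge: Tuple[int, int]) -> float:
    """Forman-Ricci curvature of ``edge`` in a simple undirected graph."""
    u, v = edge
    if not graph.has_edge(u, v):
        raise ValueError(f"edge {edge!r} not in graph")
    triangles = len(set(graph[u]) & set(graph[v]))
    return 4.0 - graph.degree(u) - graph.degree(v) + 3.0 * triangles


def _hop_distances(graph: nx.Graph, sources: Iterable, targets: set) -> dict:
    """BFS hop distances from each source to every reachable target."""
    out = {}
    for s in sources:
        lengths = nx.single_source_shortest_path_length(graph, s)
        out[s] = {t: lengths[t] for t in targets if t in lengths}
    return out


def ollivier_curvature(
    graph: nx.Graph,
    edge: Tuple[int, int],
    alpha: float = DEFAULT_ALPHA,
    weighted_distance: bool = False,
) -> float:
    """Ollivier-Ricci curvature of ``edge`` with idleness ``alpha``.

    ``weighted_distance`` switches the graph distance (both the denominator
    and the transport ground metric) from unweighted hop count to
    'weight'-weighted shortest paths.
    """
    u, v = edge
    if not graph.has_edge(u, v):
        raise ValueError(f"edge {edge!r} not in graph")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")

    def measure(a):
        nbrs = list(graph[a])
        support = [a] + nbrs
        mass = [alpha] + [(1.0 - alpha) / len(nbrs)] * len(nbrs)
        return support, mass

    sup_u, m_u = measure(u)
    sup_v, m_v = measure(v)

    if weighted_distance:
        dist = {
            s: nx.single_source_dijkstra_path_length(graph, s, weight="weight")
            for s in sup_u
        }
        d_uv = dist[u][v]
    else:
        dist = _hop_distances(graph, sup_u, set(sup_v))
        d_uv = dist[u][v]

    cost = np.array([[dist[a][b] for b in sup_v] for a in sup_u], dtype=float)
    w = _transport_lp(np.array(m_u), np.array(m_v), cost)
    return 1.0 - w / d_uv


def _transport_lp(mu: np.ndarray, nu: np.ndarray, cost: np.ndarray) -> float:
    """Exact Wasserstein-1 via the transportation LP (scipy highs)."""
    n, m = cost.shape
    # variables A[a, b] flattened row-major; marginal equality constraints
    a_eq = np.zeros((n + m, n * m))
    for a in range(n):
        a_eq[a, a * m : (a + 1) * m] = 1.0
    for b in range(m):
        a_eq[n + b, b::m] = 1.0
    res = linprog(
        cost.ravel(),
        A_eq=a_eq,
        b_eq=np.concatenate([mu, nu]),
        bounds=(0, None),
        method="highs",
    )
    if not res.success or not np.isfinite(res.fun):
        raise ArithmeticError(f"transportation LP failed: {res.message}")
    return float(res.fun)


def filtration_subgraphs(
    graph: nx.Graph, filtration_values: Sequence[float]
) -> List[nx.Graph]:
    """Nested subgraphs keeping all nodes and edges of weight <= l_k."""
    values = np.asarray(filtration_values, dtype=float)
    if values.size > 1 and np.any(np.diff(values) <= 0):
        raise ValueError("filtration_values must be strictly increasing")
    out = []
    for lk in values:
        sub = nx.Graph()
        sub.add_nodes_from(graph.nodes)
        sub.add_edges_from(
            (u, v, d)
            for u, v, d in graph.edges(data=True)
            if d.get("weight", 1.0) <= lk
        )
        out.append(sub)
    return out


def undirected_weighted_graph(graph: InteractionGraph) -> nx.Graph:
    """Collapse a directed interaction graph to its weighted undirected form."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    for i, j, d in graph.undirected_edges():
        g.add_edge(i, j, weight=d)
    return g


def multiscale_curvature(
    graph: InteractionGraph,
    filtration_values: Sequence[float] = DEFAULT_FILTRATIONS,
    curvature_kind: str = "forman",
    alpha: float = DEFAULT_ALPHA,
) -> InteractionGraph:
    """Attach per-edge multiscale curvature profiles to a graph (in place).

    Curvature is evaluated on the undirected simple graph underlying the
    directed interaction graph, with edge weights equal to the Euclidean
    distances; both directed orientations of an edge share one profile.
    Profile entry ``k`` is the curvature of the edge inside the subgraph at
    threshold ``l_k``, or 0 while the edge's weight exceeds ``l_k``.
    """
    if curvature_kind not in ("forman", "ollivier"):
        raise ValueError("curvature_kind must be 'forman' or 'ollivier'")
    values = np.asarray(filtration_values, dtype=float)
    if values.size > 1 and np.any(np.diff(values) <= 0):
        raise ValueError("filtration_values must be strictly increasing")

    und = undirected_weighted_graph(graph)
    subs = filtration_subgraphs(und, values)

    profiles = np.zeros((graph.n_edges, values.size))
    for k, sub in enumerate(subs):
        if sub.number_of_edges() == 0:
            continue
        cache = {}
        for e, (i, j) in enumerate(graph.edges):
            key = (min(int(i), int(j)), max(int(i), int(j)))
            if not sub.has_edge(*key):
                continue
            if key not in cache:
                if curvature_kind == "forman":
                    cache[key] = forman_curvature(sub, key)
                else:
                    cache[key] = ollivier_curvature(sub, key, alpha=alpha)
            profiles[e, k] = cache[key]

    graph.curvature_profiles = profiles
    graph.filtration_values = values
    return graph
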