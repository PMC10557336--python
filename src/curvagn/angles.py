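"""Angle-domain line graph over the directed edges of an interaction graph.

The line graph's nodes are the directed edges; an arc connects e_ki -> e_ij
whenever edge e_ki points to the source atom of e_ij (a chain k -> i -> j).
Each arc carries the planar angle at the shared atom a_i between the
vectors towards a_k and towards a_j, and the index q of the angle domain
(180*(q-1)/N, 180*q/N] containing it (a numerically exact 0 degrees maps
to q = 1).  By default the backtracking arc with k = j is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexes import InvalidGeometryError
from .graph import InteractionGraph


@dataclass
class AngleLineGraph:
    """Arcs between directed edges, labelled with angles and domains.

    ``arc_src`` / ``arc_tgt`` index into the interaction graph's edge list:
    arc a carries the message from edge ``arc_src[a]`` into ``arc_tgt[a]``.
    ``arc_angle`` is in degrees in [0, 180]; ``arc_domain`` in 1..N.
    """

    n_edges: int
    n_domains: int
    arc_src: np.ndarray
    arc_tgt: np.ndarray
    arc_angle: np.ndarray
    arc_domain: np.ndarray

    @property
    def n_arcs(self) -> int:
        return int(self.arc_src.size)


def angle_domain(angle_deg: np.ndarray, n_domains: int) -> np.ndarray:
    """Domain index q in 1..N for angles in [0, 180] degrees.

    Domains are half-open on the left: q covers (180(q-1)/N, 180q/N];
    angle 0 is assigned to q = 1.
    """
    angle = np.asarray(angle_deg, dtype=float)
    width = 180.0 / n_domains
    q = np.ceil(angle / width).astype(int)
    return np.clip(q, 1, n_domains)


def build_angle_line_graph(
    graph: InteractionGraph,
    n_domains: int = 6,
    exclude_reverse: bool = True,
) -> AngleLineGraph:
    """Build the angle-labelled line graph of a directed interaction graph."""
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    xyz = graph.coordinates()
    edges = graph.edges
    n_edges = edges.shape[0]

    # incoming directed edges grouped by their target atom
    in_edges: list = [[] for _ in range(graph.n_nodes)]
    for e, (i, j) in enumerate(edges):
        in_edges[int(j)].append(e)

    src_list, tgt_list = [], []
    for e_t, (i, j) in enumerate(edges):
        i, j = int(i), int(j)
        for e_s in in_edges[i]:
            k = int(edges[e_s, 0])
            if exclude_reverse and k == j:
                continue
            src_list.append(e_s)
            tgt_list.append(e_t)

    arc_src = np.array(src_list, dtype=int)
    arc_tgt = np.array(tgt_list, dtype=int)
    if arc_src.size == 0:
        return AngleLineGraph(
            n_edges=n_edges,
            n_domains=n_domains,
            arc_src=arc_src,
            arc_tgt=arc_tgt,
            arc_angle=np.zeros(0),
            arc_domain=np.zeros(0, dtype=int),
        )

    # angle at the shared atom a_i between c(a_k) - c(a_i) and c(a_j) - c(a_i)
    shared = edges[arc_tgt, 0]
    k_atoms = edges[arc_src, 0]
    j_atoms = edges[arc_tgt, 1]
    v1 = xyz[k_atoms] - xyz[shared]
    v2 = xyz[j_atoms] - xyz[shared]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise InvalidGeometryError("zero-length edge vector; angle undefined")
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))

    return AngleLineGraph(
        n_edges=n_edges,
        n_domains=n_domains,
        arc_src=arc_src,
        arc_tgt=arc_tgt,
        arc_angle=angle,
        arc_domain=angle_domain(angle, n_domains),
    )
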