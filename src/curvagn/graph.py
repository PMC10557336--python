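"""The complex interaction graph and the atom-type interaction matrix.

The interaction graph is a directed graph over all ligand atoms plus the
protein atoms lying within a cutoff distance ``d`` of at least one ligand
atom; every ordered pair of retained atoms closer than ``d`` contributes a
directed edge in each direction.  The interaction matrix is the normalised
co-occurrence table of (protein element, ligand element) pairs within a
larger interaction cutoff ``d_rho``; the network's pairwise pooling layer is
trained to approximate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .complexes import (
    Atom,
    InvalidGeometryError,
    LIGAND_ELEMENTS,
    MIN_SEPARATION,
    MolecularComplex,
    PROTEIN_ELEMENTS,
)
from .featurize import featurize_atoms

DEFAULT_CUTOFF = 5.0  # graph cutoff d_theta, Angstrom
DEFAULT_INTERACTION_CUTOFF = 12.0  # interaction-matrix cutoff d_rho, Angstrom


@dataclass
class InteractionGraph:
    """Directed interaction graph of a complex.

    Attributes
    ----------
    atoms:
        The retained atoms, ligand block first.
    node_features:
        (n, 36) feature matrix aligned with ``atoms``.
    edges:
        (E, 2) int array of directed edges (source, target); for every edge
        (i, j) the reverse (j, i) is also present.
    edge_distance:
        (E,) Euclidean distances in Angstrom (equal for both orientations).
    curvature_profiles:
        Optional (E, n_filtrations) multiscale-curvature profile matrix,
        attached by the curvature module; both orientations share a profile.
    filtration_values:
        Filtration thresholds the profiles were computed at, if attached.
    cutoff_d:
        The graph cutoff used to build the edge set.
    """

    atoms: List[Atom]
    node_features: np.ndarray
    edges: np.ndarray
    edge_distance: np.ndarray
    cutoff_d: float
    curvature_profiles: Optional[np.ndarray] = None
    filtration_values: Optional[np.ndarray] = None
    _edge_index: Dict[Tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_distance = np.asarray(self.edge_distance, dtype=float)
        if not self._edge_index:
            self._edge_index = {
                (int(i), int(j)): e for e, (i, j) in enumerate(self.edges)
            }

    @property
    def n_nodes(self) -> int:
        return len(self.atoms)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def coordinates(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def edge_id(self, i: int, j: int) -> int:
        """Index of directed edge (i, j); KeyError if absent."""
        return self._edge_index[(int(i), int(j))]

    def has_edge(self, i: int, j: int) -> bool:
        return (int(i), int(j)) in self._edge_index

    def undirected_edges(self) -> List[Tuple[int, int, float]]:
        """Each undirected edge once, as (min(i,j), max(i,j), distance)."""
        seen: Set[Tuple[int, int]] = set()
        out: List[Tuple[int, int, float]] = []
        for e, (i, j) in enumerate(self.edges):
            key = (min(int(i), int(j)), max(int(i), int(j)))
            if key not in seen:
                seen.add(key)
                out.append((key[0], key[1], float(self.edge_distance[e])))
        return out


@dataclass
class InteractionMatrix:
    """|S_P| x |S_L| normalised pair-count table, rows=protein elements."""

    values: np.ndarray
    cutoff_rho: float
    protein_types: Tuple[str, ...] = PROTEIN_ELEMENTS
    ligand_types: Tuple[str, ...] = LIGAND_ELEMENTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.protein_types), len(self.ligand_types))
        if self.values.shape != expected:
            raise ValueError(f"values must have shape {expected}")
        if np.any(self.values < 0):
            raise ValueError("interaction-matrix entries must be non-negative")

    def __getitem__(self, key: Tuple[str, str]) -> float:
        pk, lk = key
        return float(
            self.values[self.protein_types.index(pk), self.ligand_types.index(lk)]
        )


def build_interaction_graph(
    complex_: MolecularComplex,
    cutoff_d: float = DEFAULT_CUTOFF,
) -> InteractionGraph:
    """Build the directed interaction graph of a complex.

    Node set: all ligand atoms plus protein atoms within ``cutoff_d`` of at
    least one ligand atom.  Edges: both directions between every distinct
    retained pair at Euclidean distance <= ``cutoff_d``.  Distinct atoms
    closer than 1e-3 Angstrom raise :class:`InvalidGeometryError`.
    """
    if cutoff_d <= 0:
        raise ValueError("cutoff_d must be positive")
    lig = list(complex_.ligand_atoms)
    lig_xyz = np.array([a.coord for a in lig])
    prot = list(complex_.protein_atoms)

    kept_prot: List[Atom] = []
    if prot:
        prot_xyz = np.array([a.coord for a in prot])
        tree = cKDTree(lig_xyz)
        dmin, _ = tree.query(prot_xyz, k=1)
        kept_prot = [a for a, d in zip(prot, dmin) if d <= cutoff_d]

    atoms = lig + kept_prot
    xyz = np.array([a.coord for a in atoms])
    n = len(atoms)

    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    close = dist[iu, ju] < MIN_SEPARATION
    if np.any(close):
        k = int(np.argmax(close))
        raise InvalidGeometryError(
            f"atoms {iu[k]} and {ju[k]} are {dist[iu[k], ju[k]]:.2e} A apart "
            "(closer than the 1e-3 A minimum separation)"
        )

    mask = dist[iu, ju] <= cutoff_d
    src = np.concatenate([iu[mask], ju[mask]])
    dst = np.concatenate([ju[mask], iu[mask]])
    d = np.concatenate([dist[iu, ju][mask]] * 2)

    return InteractionGraph(
        atoms=atoms,
        node_features=featurize_atoms(atoms),
        edges=np.stack([src, dst], axis=1) if src.size else np.zeros((0, 2), int),
        edge_distance=d,
        cutoff_d=float(cutoff_d),
    )


def edge_oriented_neighbors(
    graph: InteractionGraph,
    target: Union[int, Tuple[int, int]],
    exclude_reverse: bool = False,
) -> FrozenSet[Tuple[int, int]]:
    """Directed edges pointing into a node, or into an edge's source atom.

    For a node ``i``: all directed edges (k, i).  For a directed edge
    (i, j): all directed edges (k, i); with ``exclude_reverse`` the
    backtracking edge (j, i) is omitted (used for angle message passing).
    """
    if isinstance(target, tuple):
        i, j = int(target[0]), int(target[1])
        if not graph.has_edge(i, j):
            raise KeyError(f"edge ({i}, {j}) not in graph")
        incoming = {
            (int(a), int(b))
            for a, b in graph.edges
            if int(b) == i and (not exclude_reverse or int(a) != j)
        }
        return frozenset(incoming)
    node = int(target)
    if node < 0 or node >= graph.n_nodes:
        raise KeyError(f"node {node} not in graph")
    return frozenset((int(a), int(b)) for a, b in graph.edges if int(b) == node)


def compute_interaction_matrix(
    complex_: MolecularComplex,
    cutoff_rho: float = DEFAULT_INTERACTION_CUTOFF,
) -> InteractionMatrix:
    """Normalised (protein element, ligand element) pair-count table.

    Entry (T_k, T_l) counts intermolecular pairs of those element types at
    distance strictly below ``cutoff_rho`` (Heaviside of ``cutoff_rho - d``),
    normalised by the total qualifying pair count.  All-zero when no pair
    qualifies.
    """
    if cutoff_rho <= 0:
        raise ValueError("cutoff_rho must be positive")
    p_idx = {el: k for k, el in enumerate(PROTEIN_ELEMENTS)}
    l_idx = {el: k for k, el in enumerate(LIGAND_ELEMENTS)}
    counts = np.zeros((len(PROTEIN_ELEMENTS), len(LIGAND_ELEMENTS)), dtype=float)

    prot_xyz = np.array([a.coord for a in complex_.protein_atoms])
    lig_xyz = np.array([a.coord for a in complex_.ligand_atoms])
    dist = np.sqrt(
        np.sum((prot_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2, axis=-1)
    )
    within = dist < cutoff_rho
    for pi, pa in enumerate(complex_.protein_atoms):
        for li, la in enumerate(complex_.ligand_atoms):
            if within[pi, li]:
                counts[p_idx[pa.element], l_idx[la.element]] += 1.0
    total = counts.sum()
    if total > 0:
        counts /= total
    return InteractionMatrix(values=counts, cutoff_rho=float(cutoff_rho))
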