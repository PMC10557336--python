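"""Featurization pipeline and on-disk dataset container.

:func:`featurize_complex` turns a :class:`MolecularComplex` into a
:class:`GraphSample` — the fully preprocessed arrays the network consumes:
node features, directed edges with distances, multiscale curvature
profiles, angle-domain line-graph arcs, the ground-truth interaction
matrix, and the label.  Samples round-trip through ``.npz`` files; a
dataset directory holds one ``.npz`` per complex plus a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .angles import build_angle_line_graph
from .complexes import LIGAND_ELEMENTS, PROTEIN_ELEMENTS, MolecularComplex
from .curvature import DEFAULT_ALPHA, DEFAULT_FILTRATIONS, multiscale_curvature
from .graph import (
    DEFAULT_CUTOFF,
    DEFAULT_INTERACTION_CUTOFF,
    build_interaction_graph,
    compute_interaction_matrix,
)

MANIFEST_NAME = "manifest.json"


@dataclass
class GraphSample:
    """A featurized complex, ready for the network's forward pass."""

    name: str
    node_features: np.ndarray  # (n, 36)
    edges: np.ndarray  # (E, 2) directed
    edge_distance: np.ndarray  # (E,)
    curvature_profiles: np.ndarray  # (E, n_filtrations)
    arc_src: np.ndarray  # line-graph arcs, indices into edges
    arc_tgt: np.ndarray
    arc_domain: np.ndarray  # 1..N
    n_angle_domains: int
    interaction_matrix: np.ndarray  # (|S_P|, |S_L|) ground truth Z
    pipool_edge_idx: np.ndarray  # directed protein->ligand edges
    pipool_cell: np.ndarray  # flat (k * |S_L| + l) cell per such edge
    cutoff_d: float
    label: Optional[float] = None

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def arcs_in_domain(self, q: int):
        mask = self.arc_domain == q
        return self.arc_src[mask], self.arc_tgt[mask]


def featurize_complex(
    complex_: MolecularComplex,
    cutoff_d: float = DEFAULT_CUTOFF,
    cutoff_rho: float = DEFAULT_INTERACTION_CUTOFF,
    filtration_values: Sequence[float] = DEFAULT_FILTRATIONS,
    curvature_kind: str = "forman",
    alpha: float = DEFAULT_ALPHA,
    n_angle_domains: int = 6,
    exclude_reverse: bool = True,
) -> GraphSample:
    """Run the full preprocessing chain on one complex."""
    graph = build_interaction_graph(complex_, cutoff_d=cutoff_d)
    multiscale_curvature(
        graph,
        filtration_values=filtration_values,
        curvature_kind=curvature_kind,
        alpha=alpha,
    )
    lg = build_angle_line_graph(
        graph, n_domains=n_angle_domains, exclude_reverse=exclude_reverse
    )
    z = compute_interaction_matrix(complex_, cutoff_rho=cutoff_rho)

    p_idx = {el: k for k, el in enumerate(PROTEIN_ELEMENTS)}
    l_idx = {el: k for k, el in enumerate(LIGAND_ELEMENTS)}
    pip_edges: List[int] = []
    pip_cells: List[int] = []
    for e, (i, j) in enumerate(graph.edges):
        ai, aj = graph.atoms[int(i)], graph.atoms[int(j)]
        if ai.origin == "protein" and aj.origin == "ligand":
            pip_edges.append(e)
            pip_cells.append(p_idx[ai.element] * len(LIGAND_ELEMENTS) + l_idx[aj.element])

    return GraphSample(
        name=complex_.name,
        node_features=graph.node_features,
        edges=graph.edges,
        edge_distance=graph.edge_distance,
        curvature_profiles=graph.curvature_profiles,
        arc_src=lg.arc_src,
        arc_tgt=lg.arc_tgt,
        arc_domain=lg.arc_domain,
        n_angle_domains=n_angle_domains,
        interaction_matrix=z.values,
        pipool_edge_idx=np.asarray(pip_edges, dtype=int),
        pipool_cell=np.asarray(pip_cells, dtype=int),
        cutoff_d=float(cutoff_d),
        label=complex_.affinity,
    )


# -- persistence ---------------------------------------------------------

def save_sample(sample: GraphSample, path) -> None:
    """Write one featurized sample as a compressed ``.npz`` record."""
    np.savez_compressed(
        path,
        name=np.array(sample.name),
        node_features=sample.node_features,
        edges=sample.edges,
        edge_distance=sample.edge_distance,
        curvature_profiles=sample.curvature_profiles,
        arc_src=sample.arc_src,
        arc_tgt=sample.arc_tgt,
        arc_domain=sample.arc_domain,
        n_angle_domains=np.array(sample.n_angle_domains),
        interaction_matrix=sample.interaction_matrix,
        pipool_edge_idx=sample.pipool_edge_idx,
        pipool_cell=sample.pipool_cell,
        cutoff_d=np.array(sample.cutoff_d),
        label=np.array(np.nan if sample.label is None else sample.label),
    )


def load_sample(path) -> GraphSample:
    with np.load(path) as z:
        label = float(z["label"])
        return GraphSample(
            name=str(z["name"]),
            node_features=z["node_features"],
            edges=z["edges"],
            edge_distance=z["edge_distance"],
            curvature_profiles=z["curvature_profiles"],
            arc_src=z["arc_src"],
            arc_tgt=z["arc_tgt"],
            arc_domain=z["arc_domain"],
            n_angle_domains=int(z["n_angle_domains"]),
            interaction_matrix=z["interaction_matrix"],
            pipool_edge_idx=z["pipool_edge_idx"],
            pipool_cell=z["pipool_cell"],
            cutoff_d=float(z["cutoff_d"]),
            label=None if np.isnan(label) else label,
        )


def save_dataset(samples: Sequence[GraphSample], out_dir) -> None:
    """Write a dataset directory: one npz per sample plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for k, s in enumerate(samples):
        fname = f"{k:05d}_{s.name}.npz"
        save_sample(s, out / fname)
        names.append(fname)
    (out / MANIFEST_NAME).write_text(
        json.dumps({"n_samples": len(samples), "files": names}, indent=1)
    )


def load_dataset(in_dir) -> List[GraphSample]:
    src = Path(in_dir)
    manifest = json.loads((src / MANIFEST_NAME).read_text())
    return [load_sample(src / f) for f in manifest["files"]]
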