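"""Atom featurization: the 36-dimensional origin-separated node vector.

Each heavy atom carries an 18-dimensional raw descriptor block:

    element one-hot over the 9-element ligand vocabulary (9)
    || hybridization (1) || n heavy neighbours (1) || n hetero neighbours (1)
    || SMARTS flags: hydrophobic, aromatic, acceptor, donor, ring (5)
    || partial charge (1)

Ligand atoms place this block in the first 18 slots (second half zero);
protein atoms place it in the second 18 slots (first half zero), so the
network can tell the two molecules apart from the node features alone.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .complexes import Atom, LIGAND_ELEMENTS

RAW_DIM = 18
NODE_FEATURE_DIM = 2 * RAW_DIM

_ELEMENT_INDEX = {el: i for i, el in enumerate(LIGAND_ELEMENTS)}


def raw_atom_block(atom: Atom) -> np.ndarray:
    """The 18-dim descriptor block of a single atom (no origin placement)."""
    v = np.zeros(RAW_DIM, dtype=float)
    try:
        v[_ELEMENT_INDEX[atom.element]] = 1.0
    except KeyError:  # pragma: no cover - upstream filters should prevent this
        raise ValueError(f"element {atom.element!r} outside the 9-element vocabulary")
    v[9] = float(atom.hybridization)
    v[10] = float(atom.n_heavy_attached)
    v[11] = float(atom.n_hetero_attached)
    v[12:17] = [float(f) for f in atom.smarts_flags]
    v[17] = float(atom.partial_charge)
    return v


def featurize_atom(atom: Atom) -> np.ndarray:
    """36-dim node feature vector with the raw block placed by origin.

    Ligand atoms occupy indices 0..17, protein atoms indices 18..35.
    """
    v = np.zeros(NODE_FEATURE_DIM, dtype=float)
    block = raw_atom_block(atom)
    if atom.origin == "ligand":
        v[:RAW_DIM] = block
    else:
        v[RAW_DIM:] = block
    return v


def featurize_atoms(atoms: Sequence[Atom]) -> np.ndarray:
    """(n, 36) node feature matrix for a sequence of atoms."""
    if len(atoms) == 0:
        return np.zeros((0, NODE_FEATURE_DIM), dtype=float)
    return np.stack([featurize_atom(a) for a in atoms])
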