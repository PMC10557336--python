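"""Core domain types: atoms and protein-ligand complexes.

A complex is modelled as two heavy-atom clouds (protein side, ligand side)
with per-atom chemistry descriptors and an optional experimental binding
affinity on the pK_a scale (-log K_d / K_i / IC50).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

#: Element vocabulary for protein-side atoms (S_P).
PROTEIN_ELEMENTS: Tuple[str, ...] = ("C", "N", "O", "S")
#: Element vocabulary for ligand-side atoms (S_L).
LIGAND_ELEMENTS: Tuple[str, ...] = ("C", "N", "O", "S", "P", "I", "Cl", "B", "F")

#: Names of the five SMARTS-derived boolean descriptors, in feature order.
SMARTS_FLAG_NAMES: Tuple[str, ...] = (
    "hydrophobic",
    "aromatic",
    "acceptor",
    "donor",
    "ring",
)

#: Minimum allowed separation (Angstrom) between distinct atoms; closer pairs
#: are treated as invalid geometry (they would break distance/angle math).
MIN_SEPARATION = 1e-3


class InvalidGeometryError(ValueError):
    """Raised when atom coordinates are unusable (coincident atoms etc.)."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom with the chemistry descriptors used for featurization.

    Parameters
    ----------
    element:
        Element symbol; must belong to the vocabulary of ``origin``
        (protein: C/N/O/S; ligand: C/N/O/S/P/I/Cl/B/F).
    coord:
        Cartesian coordinate in Angstrom (finite 3-vector).
    hybridization:
        Orbital hybridization as an integer in {1, 2, 3} (sp, sp2, sp3).
    n_heavy_attached:
        Number of bonded heavy-atom neighbours.
    n_hetero_attached:
        Number of bonded heteroatom (non C/H) neighbours.
    smarts_flags:
        Five booleans: hydrophobic, aromatic, acceptor, donor, ring.
    partial_charge:
        Partial charge (e.g. Gasteiger), float.
    origin:
        ``"protein"`` or ``"ligand"``.
    """

    element: str
    coord: np.ndarray
    hybridization: int = 3
    n_heavy_attached: int = 0
    n_hetero_attached: int = 0
    smarts_flags: Tuple[bool, bool, bool, bool, bool] = (False,) * 5
    partial_charge: float = 0.0
    origin: str = "ligand"

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"coord must be a finite 3-vector, got {self.coord!r}")
        object.__setattr__(self, "coord", coord)
        if self.origin not in ("protein", "ligand"):
            raise ValueError(f"origin must be 'protein' or 'ligand', got {self.origin!r}")
        vocab = PROTEIN_ELEMENTS if self.origin == "protein" else LIGAND_ELEMENTS
        if self.element not in vocab:
            raise ValueError(
                f"element {self.element!r} is not in the {self.origin} vocabulary {vocab}"
            )
        if self.hybridization not in (1, 2, 3):
            raise ValueError(f"hybridization must be 1, 2 or 3, got {self.hybridization}")
        if self.n_heavy_attached < 0 or self.n_hetero_attached < 0:
            raise ValueError("attached-atom counts must be non-negative")
        if len(self.smarts_flags) != 5:
            raise ValueError("smarts_flags must have exactly 5 entries")
        object.__setattr__(self, "smarts_flags", tuple(bool(f) for f in self.smarts_flags))

    def moved_to(self, coord: np.ndarray) -> "Atom":
        """Return a copy of this atom at a new coordinate."""
        return replace(self, coord=np.asarray(coord, dtype=float))


@dataclass
class MolecularComplex:
    """A protein-ligand complex: two non-empty atom lists plus optional label.

    ``affinity`` is the experimental binding affinity on the pK_a scale,
    or ``None`` when unknown (prediction-time input).
    """

    protein_atoms: Sequence[Atom]
    ligand_atoms: Sequence[Atom]
    affinity: Optional[float] = None
    name: str = field(default="complex")

    def __post_init__(self) -> None:
        self.protein_atoms = list(self.protein_atoms)
        self.ligand_atoms = list(self.ligand_atoms)
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms must be non-empty")
        if not self.protein_atoms:
            raise ValueError("protein_atoms must be non-empty")
        for atom in self.protein_atoms:
            if atom.origin != "protein":
                raise ValueError("protein_atoms contains a non-protein atom")
        for atom in self.ligand_atoms:
            if atom.origin != "ligand":
                raise ValueError("ligand_atoms contains a non-ligand atom")

    @property
    def atoms(self) -> list:
        """Ligand atoms followed by protein atoms."""
        return list(self.ligand_atoms) + list(self.protein_atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of coordinates, ligand block first."""
        return np.array([a.coord for a in self.atoms], dtype=float)
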