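"""Structure readers: PDB proteins, mol2/SDF ligands (via RDKit).

Hydrogens are excluded everywhere; atoms whose element falls outside the
side's vocabulary (metal ions, selenium, ...) are dropped with a logged
warning, since the element one-hot cannot represent them.  Chemistry
descriptors (hybridization, neighbour counts, SMARTS flags, Gasteiger
charges) are computed from the parsed molecule; the SMARTS pattern set is
configurable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

logger = logging.getLogger(__name__)

from .complexes import Atom, LIGAND_ELEMENTS, MolecularComplex, PROTEIN_ELEMENTS


class ParseError(ValueError):
    """A structure file could not be read."""


#: Default SMARTS patterns for the flag descriptors.  ``aromatic`` and
#: ``ring`` are perceived directly from the molecule (pattern ``None``).
DEFAULT_SMARTS: Dict[str, Optional[str]] = {
    "hydrophobic": "[#6;+0;!$([#6]~[#7,#8,#16])]",
    "aromatic": None,
    "acceptor": "[$([O,S;H1;v2]),$([O,S;H0;v2]),$([O,S;-]),$([N;v3;H0]),$([nH0,o,s;+0])]",
    "donor": "[$([N;!H0;v3]),$([O,S;H1;+0]),$([n;H1])]",
    "ring": None,
}


def _load_rdkit():
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    return Chem, AllChem


_HYB_MAP = {"SP": 1, "SP2": 2, "SP3": 3}


def _mol_atoms(
    mol,
    origin: str,
    smarts: Dict[str, Optional[str]],
    source: str,
) -> List[Atom]:
    Chem, AllChem = _load_rdkit()
    vocab = PROTEIN_ELEMENTS if origin == "protein" else LIGAND_ELEMENTS

    try:
        AllChem.ComputeGasteigerCharges(mol)
    except Exception:  # charges stay at 0 for exotic molecules
        logger.warning("Gasteiger charges failed for %s; using 0", source)

    flag_members: Dict[str, set] = {}
    for name, pattern in smarts.items():
        if pattern is None:
            continue
        patt = Chem.MolFromSmarts(pattern)
        flag_members[name] = {
            match[0] for match in mol.GetSubstructMatches(patt)
        }

    conf = mol.GetConformer()
    atoms: List[Atom] = []
    for rd_atom in mol.GetAtoms():
        if rd_atom.GetAtomicNum() == 1:  # hydrogens excluded everywhere
            continue
        element = rd_atom.GetSymbol()
        if element not in vocab:
            logger.warning(
                "dropping out-of-vocabulary %s atom %r from %s",
                origin,
                element,
                source,
            )
            continue
        idx = rd_atom.GetIdx()
        pos = conf.GetAtomPosition(idx)
        hyb = _HYB_MAP.get(str(rd_atom.GetHybridization()), 3)
        heavy = sum(1 for nb in rd_atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        hetero = sum(
            1 for nb in rd_atom.GetNeighbors() if nb.GetAtomicNum() not in (1, 6)
        )
        charge = rd_atom.GetDoubleProp("_GasteigerCharge") if rd_atom.HasProp(
            "_GasteigerCharge"
        ) else 0.0
        if not np.isfinite(charge):
            charge = 0.0
        flags = tuple(
            bool(
                rd_atom.GetIsAromatic()
                if name == "aromatic"
                else rd_atom.IsInRing()
                if name == "ring"
                else idx in flag_members.get(name, ())
            )
            for name in ("hydrophobic", "aromatic", "acceptor", "donor", "ring")
        )
        atoms.append(
            Atom(
                element=element,
                coord=np.array([pos.x, pos.y, pos.z]),
                hybridization=hyb,
                n_heavy_attached=heavy,
                n_hetero_attached=hetero,
                smarts_flags=flags,
                partial_charge=float(charge),
                origin=origin,
            )
        )
    return atoms


def _read_ligand(path: Path):
    Chem, _ = _load_rdkit()
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
        if mol is None:
            mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    elif suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
            mol = next((m for m in supplier if m is not None), None)
    else:
        raise ParseError(f"unsupported ligand format {suffix!r} for {path}")
    if mol is None:
        raise ParseError(f"could not parse ligand file {path}")
    return mol


def _read_protein(path: Path):
    Chem, _ = _load_rdkit()
    mol = Chem.MolFromPDBFile(str(path), removeHs=True, sanitize=True)
    if mol is None:
        mol = Chem.MolFromPDBFile(str(path), removeHs=True, sanitize=False)
    if mol is None:
        raise ParseError(f"could not parse protein file {path}")
    return mol


def read_complex(
    protein_path,
    ligand_path,
    affinity: Optional[float] = None,
    smarts: Optional[Dict[str, Optional[str]]] = None,
) -> MolecularComplex:
    """Read a protein (PDB) and ligand (mol2/SDF) into a complex.

    Raises :class:`ParseError` naming the offending file on unreadable
    input, and ``ValueError`` when no usable ligand atoms remain after
    hydrogen exclusion and vocabulary filtering.
    """
    protein_path, ligand_path = Path(protein_path), Path(ligand_path)
    for p in (protein_path, ligand_path):
        if not p.exists():
            raise ParseError(f"file does not exist: {p}")
    patterns = dict(DEFAULT_SMARTS, **(smarts or {}))

    ligand = _mol_atoms(
        _read_ligand(ligand_path), "ligand", patterns, str(ligand_path)
    )
    protein = _mol_atoms(
        _read_protein(protein_path), "protein", patterns, str(protein_path)
    )
    if not ligand:
        raise ValueError(f"no usable ligand atoms in {ligand_path}")
    if not protein:
        raise ValueError(f"no usable protein atoms in {protein_path}")
    return MolecularComplex(
        protein_atoms=protein,
        ligand_atoms=ligand,
        affinity=affinity,
        name=ligand_path.stem,
    )
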