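"""Reproducible synthetic protein-ligand complexes with known labels.

The generator emulates the geometry the interaction graph cares about —
a compact ligand atom cloud with a protein shell around it, a controlled
fraction of protein atoms in contact range — without any pretence of
chemical realism (no bonds, no secondary structure, no force field).
Labels are a deterministic function of geometry (a contact count plus a
mean inverse intermolecular distance, plus optional Gaussian noise) on a
pK_a-like scale clipped to [2, 12], so a geometry-aware model can learn
them and invariance tests have exact expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .complexes import Atom, LIGAND_ELEMENTS, MolecularComplex, PROTEIN_ELEMENTS

#: Minimum pairwise atom separation enforced by rejection sampling (A).
MIN_SEPARATION = 1.2
#: Distance (A) under which a protein atom counts as "in contact" with the
#: ligand, matching the default interaction-graph cutoff.
CONTACT_CUTOFF = 5.0

_LIGAND_FREQS = {
    "C": 0.60, "N": 0.12, "O": 0.12, "S": 0.06,
    "P": 0.03, "Cl": 0.03, "F": 0.02, "B": 0.01, "I": 0.01,
}
_PROTEIN_FREQS = {"C": 0.60, "N": 0.15, "O": 0.15, "S": 0.10}


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot place an atom."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic complex.

    ``contact_fraction`` is the probability that a protein atom is placed
    in contact range (< 5 A) of the ligand; the rest go in an outer shell.
    ``label_weights = (w1, w2)`` weight the contact count and the mean
    inverse intermolecular distance in the affinity label.
    """

    n_ligand: int = 10
    n_protein: int = 40
    box_size: float = 6.0
    contact_scale: float = 4.0
    contact_fraction: float = 0.5
    label_weights: Tuple[float, float] = (0.08, 10.0)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligand < 1 or self.n_protein < 1:
            raise ValueError("n_ligand and n_protein must be >= 1")
        if self.box_size <= 0:
            raise ValueError("box_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must lie in [0, 1]")


def _draw_elements(rng, freqs: Dict[str, float], n: int) -> List[str]:
    els = list(freqs)
    p = np.array([freqs[e] for e in els])
    return list(rng.choice(els, size=n, p=p / p.sum()))


def _draw_descriptors(rng) -> dict:
    return {
        "hybridization": int(rng.choice([1, 2, 3], p=[0.1, 0.3, 0.6])),
        "n_heavy_attached": int(rng.integers(0, 5)),
        "n_hetero_attached": int(rng.integers(0, 3)),
        "smarts_flags": tuple(bool(b) for b in rng.random(5) < 0.3),
        "partial_charge": float(rng.normal(0.0, 0.3)),
    }


def _place(rng, propose, placed: List[np.ndarray], max_tries: int = 500) -> np.ndarray:
    for _ in range(max_tries):
        pos = propose()
        if all(np.linalg.norm(pos - p) >= MIN_SEPARATION for p in placed):
            return pos
    raise GenerationError(
        "rejection sampling failed to place an atom; try a larger box_size"
    )


def generate_complex(spec: SyntheticSpec) -> MolecularComplex:
    """Generate one complex; identical specs yield identical complexes."""
    rng = np.random.default_rng(spec.seed)
    half = spec.box_size / 2.0

    lig_xyz: List[np.ndarray] = []
    for _ in range(spec.n_ligand):
        lig_xyz.append(_place(rng, lambda: rng.uniform(-half, half, 3), lig_xyz))
    lig_arr = np.array(lig_xyz)
    centroid = lig_arr.mean(axis=0)
    lig_radius = float(np.max(np.linalg.norm(lig_arr - centroid, axis=1)))

    all_xyz = list(lig_xyz)
    prot_xyz: List[np.ndarray] = []
    for _ in range(spec.n_protein):
        if rng.random() < spec.contact_fraction:
            def propose():
                anchor = lig_arr[rng.integers(0, spec.n_ligand)]
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                return anchor + u * rng.uniform(MIN_SEPARATION + 0.3, CONTACT_CUTOFF - 0.2)
        else:
            def propose():
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                r = lig_radius + rng.uniform(CONTACT_CUTOFF + 0.5, CONTACT_CUTOFF + 0.5 + spec.box_size)
                pos = centroid + u * r
                dmin = np.min(np.linalg.norm(lig_arr - pos, axis=1))
                # outer-shell atoms must genuinely stay out of contact range
                return pos if dmin > CONTACT_CUTOFF else None

            def propose_checked(_p=propose):
                while True:
                    pos = _p()
                    if pos is not None:
                        return pos

            propose = propose_checked
        pos = _place(rng, propose, all_xyz)
        prot_xyz.append(pos)
        all_xyz.append(pos)

    lig_els = _draw_elements(rng, _LIGAND_FREQS, spec.n_ligand)
    prot_els = _draw_elements(rng, _PROTEIN_FREQS, spec.n_protein)
    ligand = [
        Atom(element=e, coord=x, origin="ligand", **_draw_descriptors(rng))
        for e, x in zip(lig_els, lig_xyz)
    ]
    protein = [
        Atom(element=e, coord=x, origin="protein", **_draw_descriptors(rng))
        for e, x in zip(prot_els, prot_xyz)
    ]

    y = geometric_label(lig_arr, np.array(prot_xyz), spec)
    if spec.noise_sd > 0:
        y += float(rng.normal(0.0, spec.noise_sd))
    y = float(np.clip(y, 2.0, 12.0))
    return MolecularComplex(
        protein_atoms=protein,
        ligand_atoms=ligand,
        affinity=y,
        name=f"synth-{spec.seed}",
    )


def geometric_label(
    lig_xyz: np.ndarray, prot_xyz: np.ndarray, spec: SyntheticSpec
) -> float:
    """Noise-free label: w1 * contact count + w2 * mean inverse distance."""
    d = np.sqrt(
        np.sum((prot_xyz[:, None, :] - lig_xyz[None, :, :]) ** 2, axis=-1)
    )
    w1, w2 = spec.label_weights
    return float(w1 * np.sum(d < spec.contact_scale) + w2 * np.mean(1.0 / d))


# -- rigid motions -------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform(
    complex_: MolecularComplex,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> MolecularComplex:
    """Apply x -> R x + t to every coordinate; all other fields untouched."""
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    if rotation.shape != (3, 3) or not np.allclose(
        rotation.T @ rotation, np.eye(3), atol=1e-8
    ):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    move = lambda a: a.moved_to(rotation @ a.coord + translation)
    return MolecularComplex(
        protein_atoms=[move(a) for a in complex_.protein_atoms],
        ligand_atoms=[move(a) for a in complex_.ligand_atoms],
        affinity=complex_.affinity,
        name=complex_.name,
    )


# -- datasets ------------------------------------------------------------

def generate_specs(
    n: int, base: Optional[SyntheticSpec] = None, seed: int = 0
) -> List[SyntheticSpec]:
    """``n`` specs differing only by their per-complex seed."""
    base = base if base is not None else SyntheticSpec()
    return [replace(base, seed=seed + k) for k in range(n)]


def make_dataset(
    specs: Sequence[SyntheticSpec],
    split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> Dict[str, List[MolecularComplex]]:
    """Generate complexes and split them into disjoint train/val/test sets."""
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(specs)
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("every split must be non-empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    complexes = [generate_complex(s) for s in specs]
    return {
        "train": [complexes[i] for i in order[:n_train]],
        "val": [complexes[i] for i in order[n_train : n_train + n_val]],
        "test": [complexes[i] for i in order[n_train + n_val :]],
    }
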