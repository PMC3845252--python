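"""Per-protein curve families derived from one normal mode.

Two scalar profiles summarise how a protein moves in a mode:

* the **motion-magnitude curve**: for each residue, the mean Euclidean norm
  of its atoms' displacement vectors (one value per residue);
* the **rotation-angle curve**: for each link between consecutive residues,
  the angle between the equilibrium link vector and the link vector in the
  mode-deformed structure (one value per link, in [0, π] radians).

Magnitude curves are invariant to the overall displacement amplitude once
fed into (scale-invariant) Pearson correlation; rotation angles are not, so
the amplitude used is recorded on the curve.  The default amplitude policy
scales the unit eigenvector so the largest per-atom displacement is 1 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import MolecularStructure, ResidueSubset

__all__ = [
    "MagnitudeCurve",
    "AngleCurve",
    "magnitude_curve",
    "deform",
    "rotation_angle_curve",
    "scale_to_max_displacement",
]


@dataclass(frozen=True)
class MagnitudeCurve:
    """Per-residue mean displacement norms for one protein in one mode."""

    protein_id: str
    mode_number: int
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("motion magnitudes cannot be negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AngleCurve:
    """Per-link rotation angles (radians, [0, π]) for one protein in one mode."""

    protein_id: str
    mode_number: int
    values: np.ndarray
    amplitude_used: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > np.pi):
            raise ValueError("rotation angles must lie in [0, π]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def magnitude_curve(
    displacements: np.ndarray,
    structure: MolecularStructure,
    protein: ResidueSubset,
    mode_number: int = 0,
) -> MagnitudeCurve:
    """Mean per-residue displacement norm over the protein's residues.

    Each residue i with atoms j = 1..N_i contributes
    (1/N_i) Σ_j ‖d_ij‖ — the average of its own atoms' motion magnitudes.
    """
    displacements = np.asarray(displacements, dtype=float)
    if displacements.shape != (structure.n_atoms, 3):
        raise ValueError("need one 3-vector displacement per atom")
    norms = np.linalg.norm(displacements, axis=1)
    values = np.empty(protein.n_residues)
    for r, key in enumerate(protein.residue_keys):
        idx = structure.residue_atom_indices(key)
        if len(idx) == 0:
            raise ValueError(f"residue {key} has no atoms")
        values[r] = norms[idx].mean()
    return MagnitudeCurve(protein.label, mode_number, values)


def deform(
    structure: MolecularStructure, displacements: np.ndarray
) -> MolecularStructure:
    """Add one displacement per atom to the equilibrium coordinates."""
    displacements = np.asarray(displacements, dtype=float)
    if displacements.shape != (structure.n_atoms, 3):
        raise ValueError("need one 3-vector displacement per atom")
    return structure.with_positions(structure.coords() + displacements)


def _representatives(
    structure: MolecularStructure, protein: ResidueSubset, representative: str
) -> np.ndarray:
    coords = structure.coords()
    reps = np.empty((protein.n_residues, 3))
    for r, key in enumerate(protein.residue_keys):
        idx = structure.residue_atom_indices(key)
        if representative == "centroid":
            reps[r] = coords[idx].mean(axis=0)
        elif representative == "c-alpha":
            ca = [i for i in idx if structure.atoms[i].name.strip() == "CA"]
            if not ca:
                raise ValueError(f"residue {key} lacks a CA atom")
            reps[r] = coords[ca[0]]
        else:
            raise ValueError(f"unknown representative {representative!r}")
    return reps


def rotation_angle_curve(
    reference: MolecularStructure,
    deformed: MolecularStructure,
    protein: ResidueSubset,
    representative: str = "centroid",
    mode_number: int = 0,
    amplitude_used: float = float("nan"),
) -> AngleCurve:
    """Angles between corresponding inter-residue links before/after deformation.

    Residue k is reduced to a representative point (all-atom centroid by
    default, or its CA); the link vector runs from residue k to k+1 within
    the subset, in file order.  Each angle is arccos of the clamped
    normalised dot product; a zero-length link yields 0 with a warning.
    """
    if protein.n_residues < 2:
        raise ValueError("need at least 2 residues to form a link")
    ref = _representatives(reference, protein, representative)
    cur = _representatives(deformed, protein, representative)
    u = np.diff(ref, axis=0)
    v = np.diff(cur, axis=0)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    zero = (nu == 0) | (nv == 0)
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-length link(s) in {protein.label}; "
            "angle set to 0",
            stacklevel=2,
        )
    # atan2(|u×v|, u·v) == arccos of the clamped normalised dot product but
    # stays well-conditioned for nearly parallel links
    dots = np.einsum("ij,ij->i", u, v)
    crosses = np.linalg.norm(np.cross(u, v), axis=1)
    angles = np.where(zero, 0.0, np.arctan2(crosses, dots))
    return AngleCurve(protein.label, mode_number, angles, amplitude_used)


def scale_to_max_displacement(
    displacements: np.ndarray, max_displacement: float = 1.0
) -> np.ndarray:
    """Rescale a displacement field so the largest per-atom norm is given (Å)."""
    displacements = np.asarray(displacements, dtype=float)
    peak = np.linalg.norm(displacements, axis=1).max()
    if peak == 0:
        raise ValueError("cannot rescale an all-zero displacement field")
    return displacements * (max_displacement / peak)
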