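"""Elastic-network models and normal-mode analysis.

The complex is reduced to a network of nodes (all atoms, or one Cα per
residue) joined by identical springs between every node pair closer than a
cutoff γ_c.  Two Hessians are supported:

* **ANM** (anisotropic network model, the main model): 3N×3N, built from the
  potential V = (γ/2) Σ_{i<j, d⁰_ij ≤ γ_c} (d_ij − d⁰_ij)².  The off-diagonal
  3×3 super-block of a connected pair is −γ·r̂r̂ᵀ with r̂ the unit equilibrium
  bond vector; diagonal super-blocks are minus the row sums, which enforces
  translation invariance exactly.
* **GNM** (Gaussian network model): the N×N Kirchhoff (graph Laplacian)
  matrix γ·(D − A).

Diagonalisation yields the mode spectrum in ascending eigenvalue order.  For
a connected, non-collinear ANM network the first six modes are trivial
(rigid translations and rotations, eigenvalue 0); the *essential* modes are
the next ``n_essential`` — modes 7..16 by default — whose eigenvectors are
the collective motion directions analysed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError, DisconnectedNetworkError
from .structure_io import MolecularStructure

__all__ = [
    "ElasticNetwork",
    "HessianMatrix",
    "ModeSet",
    "build_network",
    "build_anm_hessian",
    "build_gnm_kirchhoff",
    "mass_weight",
    "compute_modes",
    "mode_displacements",
    "write_modes_tsv",
]

#: eigenvalues below this fraction of the largest count as trivial (zero)
ZERO_EIG_REL_TOL = 1e-8

#: above this many coordinates the solver switches to a partial eigensolver
DENSE_LIMIT = 9000


@dataclass
class ElasticNetwork:
    """Nodes, springs and the node→atom scatter map of one ENM."""

    node_positions: np.ndarray  # (N, 3), Å
    node_masses: np.ndarray  # (N,)
    cutoff: float  # γ_c, Å
    spring_constant: float  # γ
    pairs: np.ndarray  # (M, 2) int, springs (i < j)
    node_atom_groups: list[np.ndarray]  # atoms inheriting each node's motion
    granularity: str  # "all-atom" | "c-alpha"
    n_atoms: int  # atoms in the source structure
    connected: bool = True

    def __post_init__(self):
        if self.cutoff <= 0 or self.spring_constant <= 0:
            raise ValueError("cutoff and spring constant must be positive")
        if len(self.node_positions) < 2:
            raise ValueError("an elastic network needs at least 2 nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    def components(self) -> list[np.ndarray]:
        """Connected components of the spring graph, largest first."""
        n = self.n_nodes
        if len(self.pairs):
            a = sparse.coo_matrix(
                (np.ones(len(self.pairs)), (self.pairs[:, 0], self.pairs[:, 1])),
                shape=(n, n),
            )
            a = a + a.T
        else:
            a = sparse.coo_matrix((n, n))
        n_comp, labels = connected_components(a, directed=False)
        comps = [np.flatnonzero(labels == c) for c in range(n_comp)]
        return sorted(comps, key=len, reverse=True)


@dataclass
class HessianMatrix:
    """Symmetric second-derivative matrix of an ENM potential."""

    kind: str  # "anm" | "gnm"
    entries: np.ndarray

    def __post_init__(self):
        if self.kind not in ("anm", "gnm"):
            raise ValueError("kind must be 'anm' or 'gnm'")
        h = np.asarray(self.entries, dtype=float)
        # enforce exact symmetry rather than trusting accumulation order
        self.entries = (h + h.T) / 2.0


@dataclass
class ModeSet:
    """Ascending eigenpairs of an ENM Hessian; 1-based full-spectrum numbering."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns
    n_trivial: int
    n_essential: int
    kind: str = "anm"

    @property
    def essential_mode_numbers(self) -> list[int]:
        start = self.n_trivial + 1
        return list(range(start, start + self.n_essential))

    def _col(self, mode_number: int) -> int:
        if not 1 <= mode_number <= len(self.eigenvalues):
            raise ValueError(f"mode {mode_number} outside computed spectrum")
        return mode_number - 1

    def eigenvalue(self, mode_number: int) -> float:
        return float(self.eigenvalues[self._col(mode_number)])

    def vector(self, mode_number: int) -> np.ndarray:
        return self.eigenvectors[:, self._col(mode_number)]


def build_network(
    structure: MolecularStructure,
    cutoff: float = 10.0,
    gamma: float = 1.0,
    granularity: str = "all-atom",
) -> ElasticNetwork:
    """Turn a structure into nodes and springs.

    ``granularity='all-atom'`` takes every atom as a node; ``'c-alpha'``
    takes one CA atom per residue, with all atoms of the residue inheriting
    that node's motion.  Springs join node pairs within ``cutoff`` Å.
    """
    if granularity not in ("all-atom", "c-alpha"):
        raise ConfigurationError(f"unknown granularity {granularity!r}")
    if granularity == "all-atom":
        positions = structure.coords()
        masses = structure.masses()
        groups = [np.array([i]) for i in range(structure.n_atoms)]
    else:
        positions_l, masses_l, groups = [], [], []
        missing = []
        for key in structure.residue_keys:
            idx = structure.residue_atom_indices(key)
            ca = [i for i in idx if structure.atoms[i].name.strip() == "CA"]
            if not ca:
                missing.append(key)
                continue
            positions_l.append(structure.atoms[ca[0]].position)
            masses_l.append(sum(structure.atoms[i].mass for i in idx))
            groups.append(idx)
        if missing:
            raise ConfigurationError(
                "c-alpha granularity requires a CA atom in every residue; "
                f"missing in: {missing}"
            )
        positions = np.array(positions_l)
        masses = np.array(masses_l)

    tree = cKDTree(positions)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int).reshape(-1, 2)
    net = ElasticNetwork(
        node_positions=positions,
        node_masses=masses,
        cutoff=cutoff,
        spring_constant=gamma,
        pairs=pairs,
        node_atom_groups=groups,
        granularity=granularity,
        n_atoms=structure.n_atoms,
    )
    net.connected = len(net.components()) == 1
    return net


def build_anm_hessian(network: ElasticNetwork) -> HessianMatrix:
    """3N×3N ANM Hessian of the network's equilibrium geometry."""
    n = network.n_nodes
    gamma = network.spring_constant
    h = np.zeros((3 * n, 3 * n))
    pos = network.node_positions
    for i, j in network.pairs:
        d = pos[j] - pos[i]
        dist = np.linalg.norm(d)
        if dist == 0:
            raise ValueError(f"nodes {i} and {j} coincide; ANM undefined")
        u = d / dist
        block = gamma * np.outer(u, u)
        si, sj = 3 * i, 3 * j
        h[si : si + 3, sj : sj + 3] -= block
        h[sj : sj + 3, si : si + 3] -= block
        h[si : si + 3, si : si + 3] += block
        h[sj : sj + 3, sj : sj + 3] += block
    return HessianMatrix("anm", h)


def build_gnm_kirchhoff(network: ElasticNetwork) -> HessianMatrix:
    """N×N Kirchhoff matrix γ·(degree − adjacency)."""
    n = network.n_nodes
    gamma = network.spring_constant
    h = np.zeros((n, n))
    for i, j in network.pairs:
        h[i, j] -= gamma
        h[j, i] -= gamma
        h[i, i] += gamma
        h[j, j] += gamma
    return HessianMatrix("gnm", h)


def mass_weight(hessian: HessianMatrix, masses: np.ndarray) -> HessianMatrix:
    """Return M^{-1/2} H M^{-1/2} with M the diagonal per-coordinate masses."""
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    dim = hessian.entries.shape[0]
    per_coord = np.repeat(masses, 3) if hessian.kind == "anm" else masses
    if per_coord.shape[0] != dim:
        raise ValueError(
            f"got {len(masses)} masses for a {hessian.kind} Hessian of dim {dim}"
        )
    inv_sqrt = 1.0 / np.sqrt(per_coord)
    weighted = hessian.entries * np.outer(inv_sqrt, inv_sqrt)
    return HessianMatrix(hessian.kind, weighted)


def compute_modes(
    hessian: HessianMatrix,
    n_essential: int = 10,
    network: ElasticNetwork | None = None,
    solver: str = "auto",
) -> ModeSet:
    """Diagonalise and split the spectrum into trivial and essential modes.

    Below ``DENSE_LIMIT`` coordinates the full dense spectrum is computed;
    above, a shift-invert Lanczos solver returns only the low end.  An ANM
    network with more than 6 near-zero eigenvalues is disconnected and
    raises :class:`DisconnectedNetworkError`.
    """
    if n_essential < 1:
        raise ValueError("n_essential must be ≥ 1")
    h = hessian.entries
    dim = h.shape[0]
    if solver not in ("auto", "dense", "partial"):
        raise ValueError(f"unknown solver {solver!r}")
    use_dense = solver == "dense" or (solver == "auto" and dim <= DENSE_LIMIT)

    if use_dense:
        evals, evecs = eigh(h)
        lam_max = float(np.max(np.abs(evals)))
    else:
        k = min(dim - 1, 6 + n_essential + 4)
        hs = sparse.csr_matrix(h)
        evals, evecs = eigsh(hs, k=k, sigma=-1e-3, which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
        lam_max = float(eigsh(hs, k=1, which="LA", return_eigenvectors=False)[0])

    tol = ZERO_EIG_REL_TOL * max(lam_max, np.finfo(float).tiny)
    n_trivial = int(np.sum(evals < tol))
    if hessian.kind == "anm" and n_trivial > 6:
        comps = network.components() if network is not None else []
        detail = (
            f"; components (node counts): {[len(c) for c in comps]}"
            if comps
            else ""
        )
        raise DisconnectedNetworkError(
            f"{n_trivial} near-zero eigenvalues (> 6): network is "
            f"disconnected{detail}",
            components=comps,
        )
    if len(evals) < n_trivial + n_essential:
        raise ValueError(
            f"spectrum too small for {n_essential} essential modes "
            f"after {n_trivial} trivial ones"
        )
    return ModeSet(
        eigenvalues=np.asarray(evals, dtype=float),
        eigenvectors=np.asarray(evecs, dtype=float),
        n_trivial=n_trivial,
        n_essential=n_essential,
        kind=hessian.kind,
    )


def mode_displacements(
    modes: ModeSet,
    network: ElasticNetwork,
    mode_number: int,
    amplitude: float = 1.0,
    allow_trivial: bool = False,
) -> np.ndarray:
    """Per-atom 3-vectors: amplitude × the unit eigenvector, scattered to atoms.

    Under c-alpha granularity every atom of a residue inherits its CA node's
    displacement.  The concatenated node displacement has norm ``amplitude``.
    """
    if mode_number <= modes.n_trivial and not allow_trivial:
        raise ValueError(
            f"mode {mode_number} is trivial (rigid-body); pass "
            "allow_trivial=True to use it anyway"
        )
    vec = modes.vector(mode_number)
    node_disp = amplitude * vec.reshape(-1, 3)
    if len(node_disp) != network.n_nodes:
        raise ValueError("mode set and network dimensions disagree")
    out = np.zeros((network.n_atoms, 3))
    for node, group in enumerate(network.node_atom_groups):
        out[group] = node_disp[node]
    return out


def write_modes_tsv(modes: ModeSet, path: str | Path, mode_numbers=None) -> None:
    """Tabular mode output: mode_number, eigenvalue, then the 3N components."""
    if mode_numbers is None:
        mode_numbers = modes.essential_mode_numbers
    with open(path, "w") as fh:
        dim = modes.eigenvectors.shape[0]
        header = ["mode_number", "eigenvalue"] + [f"q{i}" for i in range(dim)]
        fh.write("\t".join(header) + "\n")
        for m in mode_numbers:
            row = [str(m), f"{modes.eigenvalue(m):.10g}"]
            row += [f"{v:.10g}" for v in modes.vector(m)]
            fh.write("\t".join(row) + "\n")
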