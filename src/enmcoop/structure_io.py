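"""Reading, writing and regrouping of multi-chain structures in PDB format.

A complex is held as a flat, file-ordered list of atoms plus an index of the
contiguous atom run of every residue.  Residue identity is the triple
``(chain_id, residue_seq, insertion_code)`` and residue order is file order,
never a numeric sort, so chain topology (and hence inter-residue link
vectors) is preserved.

Parsing and serialisation are delegated to :mod:`gemmi`; this module applies
the policies on top:

* only model 1 of a multi-model file is loaded,
* for alternate locations the first-listed conformer per atom name is kept,
* hydrogens are retained by default (a flag excludes them),
* atomic masses are assigned from the element, with a warning and a carbon
  default for unknown elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

from .exceptions import ConfigurationError, FormatError, InputError

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "ResidueSubset",
    "PairSpec",
    "SubunitSplit",
    "read_pdb",
    "write_pdb",
    "make_pairs",
]

#: fallback mass (u) when the element symbol is unknown
DEFAULT_MASS = 12.011

# fixed 8.3-column coordinate field of the PDB ATOM record
_COORD_MIN, _COORD_MAX = -999.999, 9999.999

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class AtomRecord:
    """One atom with chain/residue identity, position (Å) and mass (u)."""

    serial: int
    name: str
    element: str
    chain_id: str
    residue_seq: int
    residue_name: str
    position: np.ndarray
    mass: float
    insertion_code: str = ""
    alt_loc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.mass > 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_seq, self.insertion_code)


@dataclass
class MolecularStructure:
    """Ordered atoms with an index of residue runs and chain order."""

    atoms: list[AtomRecord]
    residue_index: dict[ResidueKey, tuple[int, int]] = field(default_factory=dict)
    chain_order: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_atoms(cls, atoms: Iterable[AtomRecord], metadata: dict | None = None):
        atoms = list(atoms)
        index: dict[ResidueKey, tuple[int, int]] = {}
        chains: list[str] = []
        for i, atom in enumerate(atoms):
            key = atom.residue_key
            if key in index:
                start, stop = index[key]
                if stop != i:
                    raise ValueError(f"residue {key} atoms are not contiguous")
                index[key] = (start, i + 1)
            else:
                index[key] = (i, i + 1)
            if atom.chain_id not in chains:
                chains.append(atom.chain_id)
        return cls(atoms, index, chains, metadata or {})

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All atom positions as an (n_atoms, 3) array, Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return list(self.residue_index)

    def chain_residues(self, chain_id: str) -> list[ResidueKey]:
        return [k for k in self.residue_index if k[0] == chain_id]

    def residue_atom_indices(self, key: ResidueKey) -> np.ndarray:
        start, stop = self.residue_index[key]
        return np.arange(start, stop)

    def with_positions(self, positions: np.ndarray) -> "MolecularStructure":
        """Copy of the structure with new coordinates, identity unchanged."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        atoms = [replace(a, position=p) for a, p in zip(self.atoms, positions)]
        return MolecularStructure(
            atoms, dict(self.residue_index), list(self.chain_order), dict(self.metadata)
        )


@dataclass(frozen=True)
class ResidueSubset:
    """A named, ordered set of residues (a whole chain or a subunit)."""

    label: str
    residue_keys: tuple[ResidueKey, ...]

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def atom_indices(self, structure: MolecularStructure) -> np.ndarray:
        parts = [structure.residue_atom_indices(k) for k in self.residue_keys]
        return np.concatenate(parts) if parts else np.empty(0, dtype=int)


@dataclass(frozen=True)
class PairSpec:
    """One of the two observed protein pairs (subunit or chain vs chain)."""

    pair_id: int
    protein_a: ResidueSubset
    protein_b: ResidueSubset

    def __post_init__(self):
        if self.pair_id not in (1, 2):
            raise ValueError("pair_id must be 1 or 2")
        if set(self.protein_a.residue_keys) & set(self.protein_b.residue_keys):
            raise ConfigurationError(
                f"pair {self.pair_id}: proteins share residues"
            )
        for prot in (self.protein_a, self.protein_b):
            if prot.n_residues < 2:
                raise ConfigurationError(
                    f"pair {self.pair_id}: protein '{prot.label}' has "
                    f"{prot.n_residues} residues (need ≥ 2)"
                )


@dataclass(frozen=True)
class SubunitSplit:
    """Residue-seq ranges (inclusive) splitting a POU chain into POUS/POUHD."""

    chain_id: str
    pou_s_range: tuple[int, int]
    pou_hd_range: tuple[int, int]

    def __post_init__(self):
        for lo, hi in (self.pou_s_range, self.pou_hd_range):
            if lo > hi:
                raise ConfigurationError(f"empty subunit range {lo}–{hi}")
        s_lo, s_hi = self.pou_s_range
        h_lo, h_hi = self.pou_hd_range
        if max(s_lo, h_lo) <= min(s_hi, h_hi):
            raise ConfigurationError(
                f"subunit ranges {self.pou_s_range} and {self.pou_hd_range} overlap"
            )


def _element_mass(symbol: str, serial: int) -> float:
    if symbol:
        el = gemmi.Element(symbol)
        if el.name != "X" and el.weight > 0:
            return el.weight
    warnings.warn(
        f"atom {serial}: unknown element {symbol!r}; using default mass "
        f"{DEFAULT_MASS} u",
        stacklevel=3,
    )
    return DEFAULT_MASS


def read_pdb(path: str | Path, include_hydrogens: bool = True) -> MolecularStructure:
    """Load model 1 of a PDB file.

    Keeps the first-listed alternate location per atom name within each
    residue.  Raises :class:`InputError` for an unreadable file and
    :class:`FormatError` when no atoms can be parsed.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read structure file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no model found")
    model = st[0]  # only the first model is used

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            seen: set[str] = set()
            for atom in res:
                if atom.name in seen:
                    continue  # later altloc of an already-kept atom name
                seen.add(atom.name)
                symbol = atom.element.name if atom.element else ""
                if include_hydrogens is False and atom.is_hydrogen():
                    continue
                serial += 1
                altloc = atom.altloc if atom.altloc not in ("\0",) else ""
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        element=symbol,
                        chain_id=chain.name,
                        residue_seq=res.seqid.num,
                        residue_name=res.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        mass=_element_mass(symbol, serial),
                        insertion_code=res.seqid.icode.strip(),
                        alt_loc=altloc,
                    )
                )
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records parsed")
    return MolecularStructure.from_atoms(atoms)


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    """Write fixed-column ATOM records; round-trips through :func:`read_pdb`.

    Coordinates outside the fixed 8.3 column range raise :class:`FormatError`
    rather than being truncated silently.
    """
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    coords = structure.coords()
    if coords.min() < _COORD_MIN or coords.max() > _COORD_MAX:
        raise FormatError(
            "coordinates exceed the fixed-column PDB range "
            f"[{_COORD_MIN}, {_COORD_MAX}] Å"
        )

    st = gemmi.Structure()
    st.name = "enmcoop"
    model = gemmi.Model("1")
    for chain_id in structure.chain_order:
        chain = gemmi.Chain(chain_id)
        for key in structure.chain_residues(chain_id):
            res = gemmi.Residue()
            first = structure.atoms[structure.residue_index[key][0]]
            res.name = first.residue_name
            res.seqid = gemmi.SeqId(key[1], key[2] or " ")
            res.het_flag = "A"
            for i in structure.residue_atom_indices(key):
                a = structure.atoms[i]
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element or "X")
                atom.pos = gemmi.Position(*a.position)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    try:
        st.write_pdb(str(path))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def _range_subset(
    structure: MolecularStructure, chain_id: str, lo: int, hi: int, label: str
) -> ResidueSubset:
    keys = tuple(
        k for k in structure.chain_residues(chain_id) if lo <= k[1] <= hi
    )
    if len(keys) < 2:
        raise ConfigurationError(
            f"{label}: range {lo}–{hi} of chain {chain_id} resolves to "
            f"{len(keys)} residues (need ≥ 2)"
        )
    return ResidueSubset(label, keys)


def make_pairs(
    structure: MolecularStructure, sox_chain: str, split: SubunitSplit
) -> tuple[PairSpec, PairSpec]:
    """Assemble pair 1 = (POUHD, Sox) and pair 2 = (POUS, Sox).

    The POU chain is split by ``split`` into its two DNA-binding subunits;
    the HMG (Sox) chain enters both pairs whole.  Residue order is file
    order in every subset.
    """
    if sox_chain == split.chain_id:
        raise ConfigurationError("Sox chain and POU chain must differ")
    for cid in (sox_chain, split.chain_id):
        if cid not in structure.chain_order:
            raise ConfigurationError(f"chain {cid!r} not present in structure")
    sox_keys = tuple(structure.chain_residues(sox_chain))
    if len(sox_keys) < 2:
        raise ConfigurationError(f"Sox chain {sox_chain} has fewer than 2 residues")
    sox = ResidueSubset("Sox", sox_keys)
    pou_hd = _range_subset(structure, split.chain_id, *split.pou_hd_range, "POUHD")
    pou_s = _range_subset(structure, split.chain_id, *split.pou_s_range, "POUS")
    return (
        PairSpec(1, pou_hd, sox),
        PairSpec(2, pou_s, sox),
    )
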