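"""Synthetic inputs for the whole pipeline: bead complexes, curve pairs with
a planted correlated window, and signed correlation tables.

The bead complexes emulate only the geometric features the elastic-network
pipeline consumes — three chains of helical bead "residues" spaced ~3.8 Å
(consecutive Cα distance in real proteins), close enough together that a
10 Å cutoff yields one connected network, with the first chain carrying a
two-subunit annotation separated by a lower-density linker.  No chemical or
sequence realism is attempted.

All generators are pure functions of their parameters and a seed (one
``numpy`` Generator stream per call; no global state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .enm_nma import build_network
from .segment_correlation import DEFAULT_P_GRID, CorrelationTable
from .structure_io import AtomRecord, MolecularStructure, SubunitSplit

__all__ = [
    "PlantedTruth",
    "gen_complex",
    "gen_curve_pair",
    "gen_corr_table",
]

_ELEMENTS = ("C", "N", "O")
_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999}


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a planted correlated window in a synthetic curve pair."""

    window_a_start: int
    window_b_start: int
    window_length: int
    target_corr: float
    seed: int

    def __post_init__(self):
        if not 0 < self.target_corr <= 1:
            raise ValueError("target_corr must be in (0, 1]")
        if self.window_length < 2:
            raise ValueError("window_length must be ≥ 2")
        if self.window_a_start < 0 or self.window_b_start < 0:
            raise ValueError("window starts must be non-negative")


def _helix_chain(
    n_res: int,
    rng: np.random.Generator,
    offset: np.ndarray,
    linker_after: int | None = None,
) -> np.ndarray:
    """Perturbed helical bead positions with ~3.8 Å consecutive spacing."""
    k = np.arange(n_res)
    omega = np.deg2rad(100.0)  # per-residue twist; with r=2.3, rise=1.5 → ~3.83 Å
    xyz = np.column_stack(
        [2.3 * np.cos(omega * k), 2.3 * np.sin(omega * k), 1.5 * k]
    )
    if linker_after is not None:
        # stretch the two linker links so the subunits read as low density
        xyz[linker_after:, 2] += 1.2
        xyz[linker_after + 1 :, 2] += 1.2
    xyz[:, 2] -= xyz[:, 2].mean()  # centre chains on a common z so they overlap
    return xyz + offset + rng.normal(0.0, 0.15, size=xyz.shape)


def gen_complex(
    n_res: tuple[int, int, int] = (60, 40, 30),
    atoms_per_res: int = 1,
    seed: int = 0,
    cutoff: float = 10.0,
    max_attempts: int = 5,
) -> MolecularStructure:
    """A three-chain bead complex: POU-like (A), Sox-like (B), DNA-like (C).

    Chain A carries the two-subunit annotation in
    ``metadata['subunit_split']`` (a :class:`SubunitSplit` with a 2-residue
    linker excluded from both subunits); ``metadata['sox_chain']`` and
    ``metadata['dna_chain']`` name the other chains.  If the jittered
    geometry happens to disconnect at the given cutoff the structure is
    regenerated (with a warning), at most ``max_attempts`` times.
    """
    if any(n < 3 for n in n_res):
        raise ValueError("each chain needs at least 3 residues")
    if atoms_per_res < 1:
        raise ValueError("atoms_per_res must be ≥ 1")
    n_pou, n_sox, n_dna = n_res
    split_at = max(3, round(0.4 * n_pou))
    if split_at + 3 > n_pou - 1:
        raise ValueError("POU chain too short for a two-subunit split")
    rng = np.random.default_rng(seed)
    # fixed local atom offsets shared by every residue (bead "side chain")
    local = np.array(
        [[0.0, 0.0, 0.0], [0.65, 0.45, 0.0], [-0.3, 0.55, 0.45], [0.2, -0.6, 0.5]]
    )
    if atoms_per_res > len(local):
        extra = rng.normal(0.0, 0.5, size=(atoms_per_res - len(local), 3))
        local = np.vstack([local, extra])

    chain_layout = [
        ("A", n_pou, np.array([0.0, 0.0, 0.0]), split_at),
        ("B", n_sox, np.array([7.0, 0.0, 0.0]), None),
        ("C", n_dna, np.array([3.5, 6.0, 0.0]), None),
    ]
    for attempt in range(max_attempts):
        atoms: list[AtomRecord] = []
        serial = 0
        for chain_id, n, offset, linker in chain_layout:
            nodes = _helix_chain(n, rng, offset, linker_after=linker)
            res_name = "DA" if chain_id == "C" else "ALA"
            for r in range(n):
                for a in range(atoms_per_res):
                    serial += 1
                    element = "C" if a == 0 else _ELEMENTS[a % len(_ELEMENTS)]
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            name="CA" if a == 0 else f"B{a}",
                            element=element,
                            chain_id=chain_id,
                            residue_seq=r + 1,
                            residue_name=res_name,
                            position=nodes[r] + local[a],
                            mass=_MASSES.get(element, 12.011),
                        )
                    )
        structure = MolecularStructure.from_atoms(
            atoms,
            metadata={
                "subunit_split": SubunitSplit(
                    chain_id="A",
                    pou_s_range=(1, split_at),
                    pou_hd_range=(split_at + 3, n_pou),
                ),
                "sox_chain": "B",
                "dna_chain": "C",
                "seed": seed,
            },
        )
        if build_network(structure, cutoff=cutoff).connected:
            return structure
        warnings.warn(
            f"synthetic complex disconnected at cutoff {cutoff} Å "
            f"(attempt {attempt + 1}); regenerating",
            stacklevel=2,
        )
    raise RuntimeError(
        f"could not generate a connected complex in {max_attempts} attempts"
    )


def gen_curve_pair(
    len_a: int,
    len_b: int,
    truth: PlantedTruth,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, PlantedTruth]:
    """Two positive curves sharing a latent signal inside the planted windows.

    Inside the windows both curves are affine maps of one smooth latent
    signal plus independent noise whose scale is calibrated so the expected
    within-window correlation is ≈ ``truth.target_corr`` when
    ``noise_sd=1``; ``noise_sd`` multiplies that calibrated scale, so 0
    gives an exactly affine (|corr| = 1) planted pair.  Outside the windows
    the curves are independent positive noise.
    """
    if len_a > len_b:
        raise ValueError("len_a must not exceed len_b")
    lam = truth.window_length
    if truth.window_a_start + lam > len_a or truth.window_b_start + lam > len_b:
        raise ValueError("planted window does not fit inside the curves")
    rng = np.random.default_rng(truth.seed)

    # independent positive background (these are magnitude-like curves)
    curve_a = rng.gamma(shape=3.0, scale=1.0, size=len_a)
    curve_b = rng.gamma(shape=3.0, scale=1.0, size=len_b)

    # smooth latent signal, standardised to zero mean / unit sd
    t = np.arange(lam) / lam
    g = np.sin(2 * np.pi * (1.5 * t + rng.uniform(0, 1)))
    g = (g - g.mean()) / g.std()

    # corr(g+e1, g+e2) = 1/(1+σ²) for independent noise of sd σ on unit-sd g
    rho = truth.target_corr
    sigma = noise_sd * np.sqrt((1.0 - rho) / rho)
    wa = 3.0 + 1.0 * (g + rng.normal(0.0, sigma, lam))
    wb = 3.0 + 0.8 * (g + rng.normal(0.0, sigma, lam))
    sa, sb = truth.window_a_start, truth.window_b_start
    curve_a[sa : sa + lam] = wa
    curve_b[sb : sb + lam] = wb
    np.clip(curve_a, 0.01, None, out=curve_a)
    np.clip(curve_b, 0.01, None, out=curve_b)
    return curve_a, curve_b, truth


def gen_corr_table(
    sign_pattern="random",
    distinct_rows: bool = True,
    seed: int = 0,
    pair_id: int = 1,
    p_grid=DEFAULT_P_GRID,
    mode_numbers=tuple(range(7, 17)),
) -> CorrelationTable:
    """A signed correlation table with controlled sign structure.

    ``sign_pattern`` is either ``"random"`` or a ±1 array of the table's
    shape.  With ``distinct_rows`` every row's absolute values are pairwise
    distinct (by at least 1e-4), which is the regime in which the median /
    tertile / quartile per-row counts are exact.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = len(p_grid), len(mode_numbers)
    rows = []
    for _ in range(n_rows):
        for _try in range(100):
            row = rng.uniform(0.02, 0.98, n_cols)
            if not distinct_rows:
                break
            diffs = np.abs(row[:, None] - row[None, :])
            if np.min(diffs[np.triu_indices(n_cols, 1)]) > 1e-4:
                break
        else:
            raise RuntimeError("failed to draw a distinct row")
        rows.append(row)
    magnitudes = np.array(rows)
    if isinstance(sign_pattern, str):
        if sign_pattern != "random":
            raise ValueError("sign_pattern must be 'random' or a ±1 array")
        signs = rng.choice([-1.0, 1.0], size=(n_rows, n_cols))
    else:
        signs = np.asarray(sign_pattern, dtype=float)
        if signs.shape != (n_rows, n_cols) or not np.all(np.abs(signs) == 1):
            raise ValueError("sign_pattern must be a ±1 array of the table shape")
    return CorrelationTable(
        pair_id=pair_id,
        p_grid=tuple(p_grid),
        mode_numbers=tuple(mode_numbers),
        values=signs * magnitudes,
    )
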