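import numpy as np
import pytest

from enmcoop.structure_io import AtomRecord, MolecularStructure
from enmcoop.synthetic_data import gen_complex


def structure_from_points(points, chain_id="A"):
    """One-atom-per-residue bead structure from raw coordinates."""
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            chain_id=chain_id,
            residue_seq=i + 1,
            residue_name="ALA",
            position=np.asarray(p, dtype=float),
            mass=12.011,
        )
        for i, p in enumerate(points)
    ]
    return MolecularStructure.from_atoms(atoms)


def random_walk_points(rng, n, step_lo=3.0, step_hi=4.5):
    """Self-avoiding-ish random walk; consecutive spacing < cutoff keeps the
    chain connected, so the resulting ENM has exactly one component."""
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + d * rng.uniform(step_lo, step_hi))
    return np.array(pts)


def random_cluster_points(rng, n, volume_per_node=60.0, cutoff=10.0):
    """Compact random blob: dense enough that the ANM spectrum has exactly
    the six rigid-body zero modes (a bare chain can have soft hinge modes)."""
    from scipy.spatial import cKDTree

    from enmcoop.enm_nma import build_network

    side = (n * volume_per_node) ** (1.0 / 3.0)
    while True:
        pts = rng.uniform(0, side, size=(n, 3))
        if cKDTree(pts).query_pairs(1.5):
            continue  # avoid near-coincident beads
        if build_network(structure_from_points(pts), cutoff=cutoff).connected:
            return pts


@pytest.fixture(scope="session")
def small_complex():
    return gen_complex((12, 10, 8), atoms_per_res=2, seed=11)


@pytest.fixture(scope="session")
def default_complex():
    return gen_complex(seed=5)
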