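import numpy as np
import pytest

from enmcoop.enm_nma import (
    build_anm_hessian,
    build_gnm_kirchhoff,
    build_network,
    compute_modes,
    mass_weight,
    mode_displacements,
)
from enmcoop.exceptions import DisconnectedNetworkError

from conftest import random_cluster_points, random_walk_points, structure_from_points
from oracles import finite_difference_hessian


def _network(points, cutoff=10.0, gamma=1.0):
    return build_network(structure_from_points(points), cutoff=cutoff, gamma=gamma)


class TestBuildNetwork:
    def test_two_atoms_within_cutoff_share_one_spring(self):
        net = _network([[0, 0, 0], [1, 0, 0]])
        assert len(net.pairs) == 1 and net.connected

    def test_two_atoms_beyond_cutoff_flagged_disconnected(self):
        net = _network([[0, 0, 0], [12, 0, 0]])
        assert len(net.pairs) == 0 and not net.connected

    def test_spring_count_matches_brute_force_pair_scan(self, small_complex):
        net = build_network(small_complex, cutoff=10.0)
        pos = small_complex.coords()
        expected = sum(
            np.linalg.norm(pos[i] - pos[j]) <= 10.0
            for i in range(len(pos))
            for j in range(i + 1, len(pos))
        )
        assert len(net.pairs) == expected


class TestAnmHessian:
    def test_single_bond_along_x(self):
        net = _network([[0, 0, 0], [1, 0, 0]])
        h = build_anm_hessian(net).entries
        expected = np.zeros((6, 6))
        expected[0, 0] = expected[3, 3] = 1.0
        expected[0, 3] = expected[3, 0] = -1.0
        assert np.allclose(h, expected)
        evals = np.linalg.eigvalsh(h)
        assert np.allclose(sorted(evals), [0, 0, 0, 0, 0, 2], atol=1e-12)

    def test_disconnected_pair_gives_zero_matrix(self):
        net = _network([[0, 0, 0], [12, 0, 0]])
        assert not build_anm_hessian(net).entries.any()

    def test_matches_finite_differences_of_spring_potential(self):
        rng = np.random.default_rng(42)
        pts = random_walk_points(rng, 10)
        net = _network(pts, gamma=1.3)
        h = build_anm_hessian(net).entries
        h_fd = finite_difference_hessian(pts, net.pairs, 1.3)
        assert np.allclose(h, h_fd, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_translation_and_rotation_null_space(self, seed):
        rng = np.random.default_rng(seed)
        pts = random_walk_points(rng, 15)
        net = _network(pts)
        h = build_anm_hessian(net).entries
        n = len(pts)
        centred = pts - pts.mean(axis=0)
        for axis in np.eye(3):
            t = np.tile(axis, n)
            assert np.linalg.norm(h @ t) < 1e-8 * np.linalg.norm(h)
            r = np.cross(np.tile(axis, (n, 1)), centred).ravel()
            assert np.linalg.norm(h @ r) < 1e-6 * np.linalg.norm(h) * np.linalg.norm(r)


class TestGnmKirchhoff:
    def test_two_connected_nodes(self):
        net = _network([[0, 0, 0], [1, 0, 0]], gamma=2.0)
        h = build_gnm_kirchhoff(net).entries
        assert np.allclose(h, 2.0 * np.array([[1, -1], [-1, 1]]))
        assert np.allclose(np.linalg.eigvalsh(h), [0, 4.0])  # {0, 2γ}

    def test_three_node_path_graph(self):
        net = _network([[0, 0, 0], [8, 0, 0], [16, 0, 0]])
        h = build_gnm_kirchhoff(net).entries
        assert np.allclose(h, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_equals_degree_minus_adjacency(self, small_complex):
        net = build_network(small_complex)
        h = build_gnm_kirchhoff(net).entries
        n = net.n_nodes
        adj = np.zeros((n, n))
        for i, j in net.pairs:
            adj[i, j] = adj[j, i] = 1.0
        assert np.allclose(h, np.diag(adj.sum(axis=1)) - adj)

    def test_zero_eigenvalue_multiplicity_counts_components(self):
        # two separated dimers -> two components -> eigenvalue 0 twice
        net = _network([[0, 0, 0], [3, 0, 0], [50, 0, 0], [53, 0, 0]])
        evals = np.linalg.eigvalsh(build_gnm_kirchhoff(net).entries)
        assert np.sum(np.abs(evals) < 1e-10) == 2


class TestMassWeight:
    def test_unit_masses_identity(self):
        net = _network([[0, 0, 0], [1, 0, 0]])
        h = build_anm_hessian(net)
        assert np.allclose(mass_weight(h, np.ones(2)).entries, h.entries)

    def test_two_node_hand_computed_blocks(self):
        net = _network([[0, 0, 0], [1, 0, 0]])
        h = mass_weight(build_anm_hessian(net), np.array([4.0, 1.0]))
        xx = h.entries[np.ix_([0, 3], [0, 3])]
        assert np.allclose(xx, [[0.25, -0.5], [-0.5, 1.0]])
        assert np.min(np.linalg.eigvalsh(h.entries)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_preserved_and_positive_masses_required(self):
        rng = np.random.default_rng(0)
        net = _network(random_walk_points(rng, 8))
        h = build_anm_hessian(net)
        masses = rng.uniform(1, 20, 8)
        hw = mass_weight(h, masses).entries
        assert np.array_equal(hw, hw.T)
        with pytest.raises(ValueError):
            mass_weight(h, np.array([1.0] * 7 + [0.0]))


class TestComputeModes:
    def test_two_node_network_has_five_zero_modes(self):
        net = _network([[0, 0, 0], [1, 0, 0]])
        modes = compute_modes(build_anm_hessian(net), n_essential=1)
        assert modes.n_trivial == 5
        assert modes.eigenvalue(6) == pytest.approx(2.0)

    def test_connected_network_six_trivial_and_essential_numbering(self):
        rng = np.random.default_rng(7)
        net = _network(random_cluster_points(rng, 30))
        modes = compute_modes(build_anm_hessian(net), n_essential=10, network=net)
        assert modes.n_trivial == 6
        assert modes.essential_mode_numbers == list(range(7, 17))
        # orthonormal eigenvector columns
        v = modes.eigenvectors
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_disconnected_network_raises_with_components(self):
        pts = np.vstack(
            [random_walk_points(np.random.default_rng(1), 5),
             random_walk_points(np.random.default_rng(2), 5) + 100.0]
        )
        net = _network(pts)
        with pytest.raises(DisconnectedNetworkError) as err:
            compute_modes(build_anm_hessian(net), n_essential=3, network=net)
        assert sorted(len(c) for c in err.value.components) == [5, 5]

    def test_partial_solver_agrees_with_dense(self):
        rng = np.random.default_rng(3)
        net = _network(random_cluster_points(rng, 20))
        h = build_anm_hessian(net)
        dense = compute_modes(h, n_essential=10, solver="dense")
        partial = compute_modes(h, n_essential=10, solver="partial")
        for m in range(7, 17):
            assert partial.eigenvalue(m) == pytest.approx(
                dense.eigenvalue(m), rel=1e-6
            )


@pytest.fixture(scope="module")
def modeset():
    rng = np.random.default_rng(9)
    net = _network(random_cluster_points(rng, 12))
    return net, compute_modes(build_anm_hessian(net), n_essential=5)


class TestModeDisplacements:

    def test_norm_equals_amplitude_and_linearity(self, modeset):
        net, modes = modeset
        d1 = mode_displacements(modes, net, 7, amplitude=1.0)
        d2 = mode_displacements(modes, net, 7, amplitude=2.0)
        assert np.linalg.norm(d1) == pytest.approx(1.0)
        assert np.allclose(d2, 2 * d1)
        assert not mode_displacements(modes, net, 7, amplitude=0.0).any()

    def test_trivial_mode_needs_explicit_permission(self, modeset):
        net, modes = modeset
        with pytest.raises(ValueError):
            mode_displacements(modes, net, 3)
        assert mode_displacements(modes, net, 3, allow_trivial=True).shape == (12, 3)

    def test_calpha_scatter_gives_whole_residue_one_vector(self, small_complex):
        net = build_network(small_complex, granularity="c-alpha")
        modes = compute_modes(build_anm_hessian(net), n_essential=3, network=net)
        disp = mode_displacements(modes, net, 7)
        for group in net.node_atom_groups:
            assert np.allclose(disp[group], disp[group[0]])
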