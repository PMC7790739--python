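"""Tests of the cell-centre mechanics on the periodic band."""

import numpy as np
import pytest

from cryptdyn.mechanics import (CryptDomain, MechParams, cell_velocity,
                                cell_volumes, neighbour_graph,
                                spring_forces, step_positions, tessellate)


@pytest.fixture
def domain():
    return CryptDomain(width=8.0, height=10.0)


def hex_lattice(domain, spacing=1.0):
    n_rows = int(round(domain.height / (spacing * np.sqrt(3) / 2)))
    n_cols = int(round(domain.width / spacing))
    return np.array([((c + 0.5 * (r % 2)) * spacing % domain.width,
                      r * spacing * np.sqrt(3) / 2)
                     for r in range(n_rows) for c in range(n_cols)])


class TestNeighbourGraph:
    def test_triangle_has_three_edges(self, domain):
        pts = np.array([[3.0, 4.0], [4.0, 4.0], [3.5, 4.9],
                        # far-away padding so all regions close
                        [1.0, 2.0], [6.0, 2.0], [1.0, 7.0], [6.0, 7.0]])
        edges = neighbour_graph(pts, domain, cutoff=1.5)
        tri = {(a, b) for a, b in edges if a < 3 and b < 3}
        assert tri == {(0, 1), (0, 2), (1, 2)}

    def test_square_lattice_interior_degree_four(self):
        # brute-force expectation: after pruning sqrt(2) diagonals at a
        # cutoff of 1.2, interior cells keep their 4 axis neighbours
        dom = CryptDomain(width=6.0, height=6.0)
        pts = np.array([[x + 0.5, y + 0.5] for y in range(6)
                        for x in range(6)], dtype=float)
        pts += np.random.default_rng(3).normal(0, 1e-4, pts.shape)
        edges = neighbour_graph(pts, dom, cutoff=1.2)
        deg = np.zeros(len(pts), int)
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        interior = [i for i, (x, y) in enumerate(pts)
                    if 1.4 < x < 4.6 and 1.4 < y < 4.6]
        assert all(deg[i] == 4 for i in interior)

    def test_connected_across_x_wrap(self, domain):
        pts = np.vstack([[[0.1, 5.0], [7.9, 5.0]],
                         hex_lattice(domain)[::3] + 0.05])
        edges = neighbour_graph(pts, domain, cutoff=1.5)
        assert any((a, b) == (0, 1) for a, b in edges)


class TestCellVolumes:
    def test_hexagonal_lattice_interior_area(self, domain):
        pts = hex_lattice(domain)
        vols = cell_volumes(pts, domain)
        interior = (pts[:, 1] > 1.5) & (pts[:, 1] < domain.height - 1.5)
        np.testing.assert_allclose(vols[interior], np.sqrt(3) / 2,
                                   rtol=1e-9)

    def test_square_lattice_interior_area(self):
        dom = CryptDomain(width=6.0, height=6.0)
        rng = np.random.default_rng(0)
        pts = np.array([[x + 0.5, y + 0.5] for y in range(6)
                        for x in range(6)], dtype=float)
        pts += rng.normal(0, 1e-9, pts.shape)  # break exact degeneracy
        vols = cell_volumes(pts, dom)
        interior = [i for i, (x, y) in enumerate(pts) if 1.4 < y < 4.6]
        np.testing.assert_allclose(vols[interior], 1.0, rtol=1e-6)

    def test_areas_partition_the_band(self, domain):
        rng = np.random.default_rng(1)
        pts = hex_lattice(domain) + rng.normal(0, 0.05, 2 * len(hex_lattice(domain))).reshape(-1, 2)
        pts[:, 0] = domain.wrap_x(pts[:, 0])
        pts[:, 1] = np.abs(pts[:, 1])
        vols = cell_volumes(pts, domain)
        assert vols.sum() == pytest.approx(domain.width * domain.y_clip,
                                           rel=1e-5)
        assert np.all(vols > 0)


class TestSpringForces:
    def test_rest_length_pair_feels_no_force(self, domain):
        pts = np.array([[2.0, 5.0], [3.0, 5.0]])
        f = spring_forces(pts, np.array([[0, 1]]), 1.0, 15.0, domain)
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_compressed_pair_repels_with_hooke_magnitude(self, domain):
        pts = np.array([[2.0, 5.0], [2.8, 5.0]])
        f = spring_forces(pts, np.array([[0, 1]]), 1.0, 15.0, domain)
        assert f[0, 0] == pytest.approx(-15.0 * 0.2)  # pushed left
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_equals_negative_energy_gradient(self, domain):
        """Finite-difference oracle on a random 20-cell configuration."""
        rng = np.random.default_rng(7)
        pts = rng.uniform([0, 1], [8, 9], (20, 2))
        edges, _ = tessellate(pts, domain, cutoff=1.5)
        mu, rest = 15.0, 1.0

        def energy(p):
            d = p[edges[:, 1]] - p[edges[:, 0]]
            d[:, 0] = domain.min_image_dx(d[:, 0])
            sep = np.hypot(d[:, 0], d[:, 1])
            return 0.5 * mu * np.sum((sep - rest) ** 2)

        f = spring_forces(pts, edges, rest, mu, domain)
        num = np.zeros_like(pts)
        h = 1e-6
        for i in range(len(pts)):
            for k in range(2):
                up, dn = pts.copy(), pts.copy()
                up[i, k] += h
                dn[i, k] -= h
                num[i, k] = -(energy(up) - energy(dn)) / (2 * h)
        np.testing.assert_allclose(f, num, atol=1e-6)

    def test_coincident_positions_rejected(self, domain):
        pts = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            spring_forces(pts, np.array([[0, 1]]), 1.0, 15.0, domain)


class TestStepPositions:
    def test_zero_force_identity(self, domain):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        new = step_positions(pts, np.zeros_like(pts), 1.0, 0.005, domain)
        np.testing.assert_array_equal(new, pts)

    def test_base_clamp(self, domain):
        pts = np.array([[1.0, 0.01]])
        f = np.array([[0.0, -10.0]])
        new = step_positions(pts, f, 1.0, 0.005, domain)
        assert new[0, 1] == 0.0

    def test_pair_relaxes_exponentially_toward_rest_length(self, domain):
        """Two-cell closed form: extension decays as exp(-2 mu t / eta)."""
        mu, eta, dt = 15.0, 1.0, 1.0 / 240.0
        pts = np.array([[2.0, 5.0], [2.6, 5.0]])
        edges = np.array([[0, 1]])
        sep0 = 0.6
        t = 0.0
        for _ in range(120):
            f = spring_forces(pts, edges, 1.0, mu, domain)
            pts = step_positions(pts, f, eta, dt, domain)
            t += dt
        sep = pts[1, 0] - pts[0, 0]
        expected = 1.0 + (sep0 - 1.0) * np.exp(-2 * mu * t / eta)
        assert sep == pytest.approx(expected, abs=5e-3)

    def test_instability_detected(self, domain):
        pts = np.array([[1.0, 5.0]])
        f = np.array([[500.0, 0.0]])
        with pytest.raises(RuntimeError):
            step_positions(pts, f, 1.0, 0.005, domain)


class TestCellVelocity:
    def test_stationary_and_uniform_drift(self, domain):
        hist = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert cell_velocity(hist, np.array([0.0, 1.0]), domain) == 0.0
        hist = np.array([[1.0, 2.0], [1.0, 3.5]])
        assert cell_velocity(hist, np.array([0.0, 1.0]),
                             domain) == pytest.approx(1.5)

    def test_wrap_crossing_uses_minimum_image(self, domain):
        # hand-computed: 7.9 -> 0.1 across the seam is 0.2, not 7.8
        hist = np.array([[7.9, 5.0], [0.1, 5.0]])
        v = cell_velocity(hist, np.array([0.0, 1.0]), domain)
        assert v == pytest.approx(0.2)

    def test_needs_two_samples(self, domain):
        with pytest.raises(ValueError):
            cell_velocity(np.array([[1.0, 2.0]]), np.array([0.0]), domain)


def test_energy_non_increasing_under_overdamped_steps(domain):
    rng = np.random.default_rng(11)
    pts = hex_lattice(domain) + rng.normal(0, 0.15, 2 * len(hex_lattice(domain))).reshape(-1, 2)
    pts[:, 0] = domain.wrap_x(pts[:, 0])
    pts[:, 1] = np.abs(pts[:, 1])
    mech = MechParams()
    edges, _ = tessellate(pts, domain, cutoff=mech.cutoff)

    def energy(p):
        d = p[edges[:, 1]] - p[edges[:, 0]]
        d[:, 0] = domain.min_image_dx(d[:, 0])
        sep = np.hypot(d[:, 0], d[:, 1])
        return 0.5 * mech.mu * np.sum((sep - 1.0) ** 2)

    energies = [energy(pts)]
    for _ in range(40):
        f = spring_forces(pts, edges, 1.0, mech.mu, domain)
        pts = step_positions(pts, f, mech.eta, mech.dt, domain)
        energies.append(energy(pts))
    assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))
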