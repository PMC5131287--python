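"""Lattice DPBL solver, density functional, greedy water placement."""

import numpy as np
import pytest

from aquabridge import io as aio
from aquabridge.dpbl import (
    DensityGrid,
    Lattice,
    LatticeModel,
    build_lattice,
    langevin,
    next_grid_dim,
    place_waters,
    relative_density,
    solve,
    water_density,
)
from aquabridge.errors import ConvergenceError, GridError
from aquabridge.synthetic import gaussian_density_grid
from oracles import place_waters_brute


def point_charge_lattice(dims=(33, 33, 33), spacing=1.0, q=1.0, **kw):
    lat = build_lattice(None, dims=dims, spacing=spacing, **kw)
    c = tuple((np.array(dims) - 1) // 2)
    lat.charge[c] = q
    lat.total_charge = q
    lat.charge_center = lat.model.origin + lat.model.spacing * np.array(c)
    return lat


class TestBuildLattice:
    def write_pqr(self, tmp_path, atoms):
        lines = [
            f"ATOM  {i + 1:>5d}  C   GLY A{i + 1:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f} {q:8.4f} {r:6.4f}"
            for i, (x, y, z, q, r) in enumerate(atoms)
        ]
        p = tmp_path / "in.pqr"
        p.write_text("\n".join(lines) + "\n")
        return aio.read_pqr(p)

    def test_charge_conservation_single_atom(self, tmp_path):
        st = self.write_pqr(tmp_path, [(0.37, -1.2, 2.05, 1.0, 1.5)])
        lat = build_lattice(st, dims=(17, 17, 17))
        assert lat.charge.sum() == pytest.approx(1.0, abs=1e-9)

    def test_charge_conservation_many(self, tmp_path):
        rng = np.random.default_rng(0)
        atoms = [(x, y, z, q, 1.5) for (x, y, z), q in
                 zip(rng.uniform(-5, 5, (20, 3)), rng.normal(size=20))]
        st = self.write_pqr(tmp_path, atoms)
        lat = build_lattice(st, dims=(33, 33, 33))
        # grid total equals the net charge of the atoms actually spread
        assert lat.charge.sum() == pytest.approx(aio.net_charge(st), abs=1e-9)

    def test_empty_structure_uniform(self):
        lat = build_lattice(None, dims=(17, 17, 17), spacing=1.0)
        assert lat.charge.sum() == 0.0
        assert not lat.exclusion.any()

    def test_exclusion_matches_brute_force(self, tmp_path):
        rng = np.random.default_rng(1)
        atoms = [(x, y, z, 0.1, r) for (x, y, z), r in
                 zip(rng.uniform(-4, 4, (10, 3)), rng.uniform(1.0, 2.0, 10))]
        st = self.write_pqr(tmp_path, atoms)
        lat = build_lattice(st, dims=(33, 33, 33), padding=6.0)
        nodes = lat.model.node_coords().reshape(-1, 3)
        brute = np.zeros(nodes.shape[0], bool)
        for x, y, z, _, r in atoms:
            brute |= ((nodes - [x, y, z]) ** 2).sum(1) <= r * r
        np.testing.assert_array_equal(lat.exclusion.ravel(), brute)

    def test_structure_too_big_names_required_dims(self, tmp_path):
        st = self.write_pqr(tmp_path, [(0, 0, 0, 1.0, 1.5), (100.0, 0, 0, -1.0, 1.5)])
        with pytest.raises(GridError, match="need dims"):
            build_lattice(st, dims=(17, 17, 17), spacing=1.0)

    def test_bad_dims_rejected(self):
        with pytest.raises(GridError):
            build_lattice(None, dims=(16, 16, 16))

    def test_next_grid_dim(self):
        assert [next_grid_dim(n) for n in (3, 4, 5, 100)] == [3, 5, 5, 129]


class TestSolve:
    def test_zero_charges_zero_potential(self):
        lat = build_lattice(None, dims=(17, 17, 17), spacing=1.0)
        sol = solve(lat, mode="uniform", eps_uniform=80.0)
        assert np.allclose(sol.phi, 0.0)

    def test_coulomb_limit(self):
        """Uniform-ε point charge vs q·λ_B0/(ε r) within 5% in a 5-20 Å shell."""
        lat = point_charge_lattice(dims=(65, 65, 65), spacing=1.25)
        sol = solve(lat, mode="uniform", eps_uniform=80.0)
        r = np.linalg.norm(lat.model.node_coords() - lat.charge_center, axis=-1)
        mask = (r >= 5.0) & (r <= 20.0)
        exact = lat.model.bjerrum0 / (80.0 * r[mask])
        rel = np.abs(sol.phi[mask] - exact) / exact
        assert rel.max() < 0.05

    def test_debye_huckel_limit(self):
        lat = point_charge_lattice(dims=(65, 65, 65), spacing=1.25, ion_molar=0.15)
        sol = solve(lat, mode="uniform", eps_uniform=80.0)
        kappa = np.sqrt(lat.model.kappa_bar2 / 80.0)
        r = np.linalg.norm(lat.model.node_coords() - lat.charge_center, axis=-1)
        mask = (r >= 5.0) & (r <= 20.0)
        exact = lat.model.bjerrum0 * np.exp(-kappa * r[mask]) / (80.0 * r[mask])
        rel = np.abs(sol.phi[mask] - exact) / exact
        assert rel.max() < 0.05

    def test_nonlinear_converges_and_field_finite(self):
        lat = point_charge_lattice(dims=(33, 33, 33), spacing=1.0)
        sol = solve(lat, mode="nonlinear", tol=1e-3)
        assert sol.converged and np.all(np.isfinite(sol.phi))
        assert sol.iterations <= 50

    def test_nonconvergence_raises_with_residuals(self):
        lat = point_charge_lattice(dims=(17, 17, 17), spacing=1.0)
        with pytest.raises(ConvergenceError) as exc:
            solve(lat, mode="nonlinear", tol=1e-12, max_iter=2)
        assert len(exc.value.residuals) == 2


class TestWaterDensity:
    def test_langevin_function_limits(self):
        assert langevin(np.array([1e-8]))[0] == pytest.approx(1e-8 / 3, rel=1e-3)
        assert langevin(np.array([50.0]))[0] == pytest.approx(1.0 - 1.0 / 50.0)

    def test_zero_field_gives_bulk(self):
        lat = build_lattice(None, dims=(17, 17, 17), spacing=1.0)
        sol = solve(lat, mode="uniform", eps_uniform=80.0)
        dens = water_density(sol, lat)
        assert np.allclose(dens.values, 1.0)

    def test_exclusion_zeroed(self):
        lat = build_lattice(None, dims=(17, 17, 17), spacing=1.0)
        lat.exclusion[8, 8, 8] = True
        sol = solve(lat, mode="uniform", eps_uniform=80.0)
        dens = water_density(sol, lat)
        assert dens.values[8, 8, 8] == 0.0

    def test_pointwise_formula(self):
        """Density of a synthetic radial field equals the scalar closure."""
        lat = point_charge_lattice(dims=(33, 33, 33), spacing=1.0)
        sol = solve(lat, mode="nonlinear", tol=1e-3)
        dens = water_density(sol, lat)
        from aquabridge.dpbl import _grad_magnitude

        u = lat.model.dipole_eA * _grad_magnitude(sol.phi, lat.model.spacing)
        phi_b = lat.model.conc_per_A3 * lat.model.solvent_lattice_a**3
        np.testing.assert_allclose(dens.values, relative_density(u, phi_b), atol=1e-12)

    def test_monotone_in_field(self):
        u = np.linspace(0, 20, 200)
        d = relative_density(u, 0.7)
        assert np.all(np.diff(d) >= 0)
        assert d[0] == pytest.approx(1.0)

    def test_unconverged_rejected(self):
        lat = build_lattice(None, dims=(17, 17, 17), spacing=1.0)
        from aquabridge.dpbl import FieldSolution

        bad = FieldSolution(np.zeros(lat.model.dims), "nonlinear", 3, [1.0], False)
        with pytest.raises(ValueError):
            water_density(bad, lat)

    def test_yukawa_zero_coupling_identical(self):
        lat = point_charge_lattice(dims=(33, 33, 33), spacing=1.0,
                                   yukawa=True, yukawa_amplitude=0.0)
        lat_plain = point_charge_lattice(dims=(33, 33, 33), spacing=1.0)
        sol = solve(lat, mode="nonlinear", tol=1e-3)
        d_y = water_density(sol, lat)
        d_p = water_density(
            solve(lat_plain, mode="nonlinear", tol=1e-3), lat_plain
        )
        np.testing.assert_array_equal(d_y.values, d_p.values)
        p_y = place_waters(d_y)
        p_p = place_waters(d_p)
        np.testing.assert_array_equal(p_y, p_p)

    def test_yukawa_attenuates_peaks(self):
        lat = point_charge_lattice(dims=(33, 33, 33), spacing=1.0,
                                   yukawa=True, yukawa_amplitude=0.5)
        sol = solve(lat, mode="nonlinear", tol=1e-3)
        d_y = water_density(sol, lat).values
        lat2 = point_charge_lattice(dims=(33, 33, 33), spacing=1.0)
        d_p = water_density(solve(lat2, mode="nonlinear", tol=1e-3), lat2).values
        assert d_y.max() <= d_p.max() + 1e-12


class TestPlacement:
    def test_single_peak(self):
        sd = gaussian_density_grid([((0.0, 0.0, 0.0), 1.0, 1.2)])
        placed = place_waters(sd.grid)
        assert placed.shape == (1, 3)
        np.testing.assert_allclose(placed[0], sd.peak_nodes[0])

    @pytest.mark.parametrize("sep,expected", [(2.9, 1), (3.1, 2)])
    def test_exclusion_boundary(self, sep, expected):
        # 0.05 Å spacing puts the peak centres exactly on grid nodes, so the
        # node separation equals the nominal peak separation
        sd = gaussian_density_grid(
            [((-sep / 2, 0, 0), 1.0, 0.03), ((sep / 2, 0, 0), 0.9, 0.03)],
            dims=(129, 33, 33),
            spacing=0.05,
        )
        placed = place_waters(sd.grid, exclusion_radius=3.0)
        assert len(placed) == expected

    def test_five_supra_three_sub(self):
        peaks = [((float(8 * k - 16), 0.0, 8.0), 0.8 + 0.05 * k, 1.0) for k in range(5)]
        peaks += [((float(8 * k - 8), 0.0, -8.0), 0.2, 1.0) for k in range(3)]
        sd = gaussian_density_grid(peaks, dims=(65, 65, 65), spacing=0.8)
        placed = place_waters(sd.grid)
        assert len(placed) == 5

    def test_matches_brute_force_rescan(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.0, 2.0, (22, 22, 22))  # ~1e4 nodes
        grid = DensityGrid(values=vals, origin=np.zeros(3), spacing=np.full(3, 1.5),
                           bulk_density=0.033)
        got = place_waters(grid, exclusion_radius=3.0, stop=1.0)
        want = place_waters_brute(vals, grid.node_coords_flat(), 3.0, 1.0)
        np.testing.assert_allclose(got, want)

    def test_pairwise_separation_invariant(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 1.5, (20, 20, 20))
        grid = DensityGrid(values=vals, origin=np.zeros(3), spacing=np.ones(3),
                           bulk_density=0.033)
        placed = place_waters(grid, exclusion_radius=3.0)
        if len(placed) > 1:
            from scipy.spatial.distance import pdist

            assert pdist(placed).min() >= 3.0

    def test_layout_independence(self):
        """Placement depends only on values, not storage order."""
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.5, 1.5, (15, 15, 15))
        grid_c = DensityGrid(values=np.ascontiguousarray(vals), origin=np.zeros(3),
                             spacing=np.ones(3), bulk_density=0.033)
        grid_f = DensityGrid(values=np.asfortranarray(vals), origin=np.zeros(3),
                             spacing=np.ones(3), bulk_density=0.033)
        np.testing.assert_array_equal(place_waters(grid_c), place_waters(grid_f))

    def test_empty_grid(self):
        grid = DensityGrid(values=np.zeros((9, 9, 9)), origin=np.zeros(3),
                           spacing=np.ones(3), bulk_density=0.033)
        assert place_waters(grid).shape == (0, 3)


def test_dx_roundtrip(tmp_path):
    sd = gaussian_density_grid([((0.0, 0.0, 0.0), 1.0, 1.5)], dims=(17, 17, 17))
    p = tmp_path / "dens.dx"
    sd.grid.to_dx(p)
    back = DensityGrid.from_dx(p, bulk_density=sd.grid.bulk_density)
    np.testing.assert_allclose(back.values, sd.grid.values, rtol=1e-6)
    np.testing.assert_allclose(back.origin, sd.grid.origin)
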