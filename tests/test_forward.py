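"""Forward model: potential solve, current density, Biot-Savart operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcdi import (
    ConductivityVector,
    assign_conductivity,
    bz_from_current_direct,
    bz_from_current_fft,
    bz_from_wire,
    current_density,
    make_wire_loop,
    montage_rl,
    simulate_montage,
    solve_potential,
)
from mrcdi.forward import (
    MU0,
    CurrentDensityField,
    SolverConfig,
    SolverError,
    plane_current,
)
from mrcdi.grid import GridGeometry


def _slab(nx=12, ny=8, nz=8, voxel=5.0):
    """Homogeneous cuboid with full-face electrodes on the x ends."""
    grid = GridGeometry.centered((nx, ny, nz), voxel)
    sigma = np.ones(grid.shape)
    anode = np.zeros(grid.shape, bool)
    cathode = np.zeros(grid.shape, bool)
    anode[0] = True
    cathode[-1] = True
    return grid, sigma, anode, cathode


class TestSolvePotential:
    def test_homogeneous_slab_linear_potential(self):
        grid, sigma, anode, cathode = _slab()
        phi = solve_potential(sigma, grid, anode, cathode, 1e-3)
        prof = phi.phi.mean(axis=(1, 2))
        # linear along x: second differences vanish
        assert np.max(np.abs(np.diff(prof, 2))) < 1e-7 * np.ptp(prof)
        J = current_density(phi, sigma)
        area = (8 * 5e-3) * (8 * 5e-3)
        # anode at low x: current flows in +x with uniform density I/A
        jx_interior = J.J[1:-1, :, :, 0]
        assert jx_interior == pytest.approx(1e-3 / area, rel=0.01)

    def test_two_layer_slab_series_resistors(self):
        """Potential drops split as d1/sigma1 : d2/sigma2 across the layers."""
        grid, sigma, anode, cathode = _slab(nx=16)
        sigma[:8] = 2.0   # layer 1 (anode side)
        sigma[8:] = 0.5   # layer 2
        phi = solve_potential(sigma, grid, anode, cathode, 1e-3)
        prof = phi.phi.mean(axis=(1, 2))
        drop1 = prof[0] - prof[7]    # 7 voxel spacings inside layer 1
        drop2 = prof[8] - prof[15]   # 7 voxel spacings inside layer 2
        assert drop2 / drop1 == pytest.approx(2.0 / 0.5, rel=0.01)
        # total resistance between the electrode-cell centres: series formula
        area = (8 * 5e-3) ** 2
        d1 = d2 = 7.5 * 5e-3
        r_expected = (d1 / 2.0 + d2 / 0.5) / area
        assert (prof[0] - prof[15]) / 1e-3 == pytest.approx(r_expected, rel=0.01)

    def test_current_linearity(self, small_vol):
        cond = ConductivityVector.ground_truth()
        sigma = assign_conductivity(small_vol, cond)
        from mrcdi import place_electrodes

        anode, cathode = place_electrodes(small_vol, montage_rl())
        p1 = solve_potential(sigma, small_vol.grid, anode, cathode, 1e-3)
        p3 = solve_potential(sigma, small_vol.grid, anode, cathode, 3e-3)
        assert np.allclose(p3.phi, 3 * p1.phi, rtol=1e-12, atol=0)

    def test_disconnected_patches_raise(self):
        grid, sigma, anode, cathode = _slab()
        sigma[6] = 0.0  # insulating wall between the electrodes
        with pytest.raises(SolverError, match="connected"):
            solve_potential(sigma, grid, anode, cathode, 1e-3)

    def test_charge_conservation_on_phantom(self, small_vol, rl_forward):
        """Net current through every electrode-separating plane is the injected 1 mA."""
        phi, _, _ = rl_forward
        sigma = assign_conductivity(small_vol, ConductivityVector.ground_truth())
        for index in (8, 12, 15, 19, 23):
            current = plane_current(phi, sigma, axis=0, index=index)
            assert abs(current) == pytest.approx(1e-3, rel=5e-3)

    def test_background_current_is_zero(self, small_vol, rl_forward):
        _, J, _ = rl_forward
        sigma = assign_conductivity(small_vol, ConductivityVector.ground_truth())
        assert np.all(J.J[sigma == 0] == 0)

    def test_electrode_swap_negates_fields(self, small_vol, rl_forward):
        from mrcdi.phantom import ElectrodeMontage

        phi, J, bz = rl_forward
        swapped = ElectrodeMontage("RL", ((-1, 0, 0), (1, 0, 0)))
        phi2, J2, bz2 = simulate_montage(
            small_vol, ConductivityVector.ground_truth(), swapped
        )
        assert np.allclose(phi2.phi, -phi.phi, atol=1e-12)
        assert np.allclose(bz2.bz, -bz.bz, atol=1e-22)

    def test_global_conductivity_scaling_degeneracy(self, small_vol, rl_forward):
        """sigma -> c*sigma at fixed current leaves J and B_z unchanged."""
        _, J, bz = rl_forward
        scaled = ConductivityVector.ground_truth().scaled(2.5)
        _, J2, bz2 = simulate_montage(small_vol, scaled, montage_rl())
        assert np.max(np.abs(J2.J - J.J)) <= 1e-6 * np.max(np.abs(J.J))
        assert np.max(np.abs(bz2.bz - bz.bz)) <= 1e-6 * np.max(np.abs(bz.bz))

    def test_maximum_principle(self, rl_forward):
        """The potential attains its extrema on the electrode patches."""
        phi = rl_forward[0].phi
        assert np.abs(phi).max() == pytest.approx(np.abs(phi.max()), rel=1e-12)
        assert phi.max() <= abs(rl_forward[0].scale) + 1e-12


class TestAssignConductivity:
    def test_literature_wm_value(self, small_vol):
        sigma = assign_conductivity(small_vol, ConductivityVector.literature())
        assert np.all(sigma[small_vol.labels == 5] == 0.126)

    def test_histogram_is_label_histogram(self, small_vol):
        cond = ConductivityVector.ground_truth()
        sigma = assign_conductivity(small_vol, cond)
        counts = small_vol.counts()
        for tissue, value in cond.sigma.items():
            n = int((sigma == value).sum())
            expected = sum(c for t, c in counts.items() if cond.sigma.get(t) == value)
            assert n == expected

    def test_missing_tissue_raises(self, small_vol):
        incomplete = ConductivityVector(sigma={"wm": 0.1})
        with pytest.raises(KeyError, match="gm|scalp|skull|ccsf|vcsf"):
            assign_conductivity(small_vol, incomplete)


class TestBiotSavartVolume:
    def test_fft_matches_direct_sum(self, tiny_grid, rng):
        J = CurrentDensityField(
            J=rng.standard_normal(tuple(tiny_grid.shape) + (3,)), grid=tiny_grid
        )
        b_fft = bz_from_current_fft(J).bz
        b_dir = bz_from_current_direct(J).reshape(tiny_grid.shape)
        assert np.max(np.abs(b_fft - b_dir)) <= 1e-3 * np.max(np.abs(b_fft))

    def test_zero_current_zero_field(self, tiny_grid):
        J = CurrentDensityField(J=np.zeros(tuple(tiny_grid.shape) + (3,)), grid=tiny_grid)
        assert np.all(bz_from_current_fft(J).bz == 0)

    def test_linearity(self, tiny_grid, rng):
        J1 = rng.standard_normal(tuple(tiny_grid.shape) + (3,))
        b1 = bz_from_current_fft(CurrentDensityField(J=J1, grid=tiny_grid)).bz
        b2 = bz_from_current_fft(CurrentDensityField(J=2 * J1, grid=tiny_grid)).bz
        assert np.allclose(b2, 2 * b1, rtol=1e-12, atol=0)

    def test_single_voxel_kernel_antisymmetry(self, tiny_grid):
        """A lone J_x source gives B_z odd in y and zero along the x axis."""
        J = np.zeros(tuple(tiny_grid.shape) + (3,))
        J[8, 8, 8, 0] = 1.0
        b = bz_from_current_direct(CurrentDensityField(J=J, grid=tiny_grid)).reshape(
            tiny_grid.shape
        )
        # odd in y about the source plane
        assert np.allclose(b[:, 9, :], -b[:, 7, :], atol=1e-25)
        # zero on the x axis through the source
        assert np.allclose(b[:, 8, 8], 0.0, atol=1e-25)

    def test_superposition(self, tiny_grid):
        J1 = np.zeros(tuple(tiny_grid.shape) + (3,))
        J2 = np.zeros_like(J1)
        J1[4, 4, 4, 0] = 1.0
        J2[10, 10, 10, 1] = 1.0
        b1 = bz_from_current_direct(CurrentDensityField(J=J1, grid=tiny_grid))
        b2 = bz_from_current_direct(CurrentDensityField(J=J2, grid=tiny_grid))
        b12 = bz_from_current_direct(CurrentDensityField(J=J1 + J2, grid=tiny_grid))
        assert np.allclose(b12, b1 + b2, rtol=1e-12)

    def test_insufficient_padding_rejected(self):
        with pytest.raises(ValueError, match="padding"):
            SolverConfig(padding_factor=1)


class TestBiotSavartWire:
    def test_polygon_loop_matches_onaxis_closed_form(self):
        loop = make_wire_loop((0, 0, 0), 100.0, 360, 0.002)
        a = 0.1
        for z_mm in (0.0, 30.0, 80.0, 150.0):
            z = z_mm * 1e-3
            closed = MU0 * 0.002 * a**2 / (2 * (a**2 + z**2) ** 1.5)
            b = bz_from_wire(loop, np.array([[0.0, 0.0, z_mm]]))[0]
            assert b == pytest.approx(closed, rel=5e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        radius=st.floats(50.0, 200.0),
        current=st.floats(-5e-3, 5e-3).filter(lambda c: abs(c) > 1e-5),
        z=st.floats(-100.0, 100.0),
    )
    def test_current_reversal_negates_field(self, radius, current, z):
        pts = np.array([[10.0, -20.0, z]])
        fwd = bz_from_wire(make_wire_loop((0, 0, 0), radius, 64, current), pts)
        rev = bz_from_wire(make_wire_loop((0, 0, 0), radius, 64, -current), pts)
        assert rev[0] == pytest.approx(-fwd[0], rel=1e-12)

    def test_point_on_segment_regularized(self):
        from mrcdi.phantom import WirePath

        wire = WirePath(points=np.array([[0, 0, 0], [100, 0, 0]]), current_A=1e-3)
        with pytest.warns(UserWarning, match="regularized"):
            b = bz_from_wire(wire, np.array([[50.0, 0.0, 0.0]]))
        assert np.isfinite(b).all()
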