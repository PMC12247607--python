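"""Phase-series simulation and B_z reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcdi import (
    BzField,
    NoiseModel,
    apply_mask,
    combine_echoes,
    extract_slices,
    make_wire_loop,
    physiological_noise_field,
    reconstruct,
    reconstruct_bz_per_echo,
    simulate_echo_series,
    subtract_stray_field,
)
from mrcdi.forward import bz_wire_on_grid
from mrcdi.grid import GridGeometry
from mrcdi.recon import (
    EPI_TE_S,
    GAMMA_PROTON,
    MaskError,
    estimate_echo_variance,
)


@pytest.fixture(scope="module")
def grid16():
    return GridGeometry.centered(16, 6.0)


def _uniform_field(grid, value_T=1e-9):
    return BzField(bz=np.full(grid.shape, value_T), grid=grid)


class TestSimulateEchoSeries:
    def test_noiseless_phase_matches_closed_form(self, grid16):
        bz = _uniform_field(grid16, 1e-9)
        series = simulate_echo_series(
            bz, te_s=(25.6e-3,), n_repeats=8, tsnr=40.0,
            noise=NoiseModel(thermal_sd=0.0),
            baseline_phase=np.zeros(grid16.shape),
        )
        expected = GAMMA_PROTON * 25.6e-3 * 1e-9
        assert series.phase[0, 0] == pytest.approx(expected, rel=1e-12)
        assert series.phase[1, 0] == pytest.approx(-expected, rel=1e-12)

    def test_seed_determinism(self, grid16):
        bz = _uniform_field(grid16)
        kwargs = dict(n_repeats=8, tsnr=40.0, noise=NoiseModel(thermal_sd=1.0, seed=3))
        a = simulate_echo_series(bz, **kwargs)
        b = simulate_echo_series(bz, **kwargs)
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.magnitude, b.magnitude)

    def test_epi_echo_times_default(self, grid16):
        series = simulate_echo_series(_uniform_field(grid16), n_repeats=8)
        assert series.te_s == (25.6e-3, 63.48e-3)

    def test_odd_repeats_rejected(self, grid16):
        with pytest.raises(ValueError, match="even"):
            simulate_echo_series(_uniform_field(grid16), n_repeats=7)

    def test_wrap_warning_for_huge_field(self, grid16):
        with pytest.warns(UserWarning, match="wrap"):
            simulate_echo_series(_uniform_field(grid16, 1e-6), n_repeats=8)


class TestReconstruction:
    def test_roundtrip_identity_noiseless(self, grid16, rng):
        """simulate -> reconstruct recovers B_z to 1e-12 T without noise."""
        field = rng.uniform(-2e-9, 2e-9, size=grid16.shape)
        bz = BzField(bz=field, grid=grid16)
        series = simulate_echo_series(
            bz, n_repeats=8, tsnr=40.0, noise=NoiseModel(thermal_sd=0.0)
        )
        rec = reconstruct(series)
        assert np.max(np.abs(rec.bz_combined.bz - field)) < 1e-12

    def test_polarity_antisymmetry(self, grid16, rng):
        field = rng.uniform(-2e-9, 2e-9, size=grid16.shape)
        common = dict(n_repeats=8, tsnr=40.0, noise=NoiseModel(thermal_sd=0.0))
        pos = reconstruct(simulate_echo_series(BzField(bz=field, grid=grid16), **common))
        neg = reconstruct(simulate_echo_series(BzField(bz=-field, grid=grid16), **common))
        assert np.allclose(neg.bz_combined.bz, -pos.bz_combined.bz, atol=1e-15)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(amplitude=st.floats(0.0, 10.0), tilt=st.floats(-5.0, 5.0))
    def test_common_mode_phase_rejected(self, amplitude, tilt):
        """Any polarity-independent baseline phase cancels exactly."""
        grid = GridGeometry.centered(8, 8.0)
        field = np.full(grid.shape, 1.5e-9)
        x = grid.coordinate_grids()[0]
        baseline = amplitude * np.sin(x / 20.0) + tilt * x / x.max()
        rec = reconstruct(
            simulate_echo_series(
                BzField(bz=field, grid=grid), n_repeats=8, tsnr=40.0,
                noise=NoiseModel(thermal_sd=0.0), baseline_phase=baseline,
            )
        )
        assert np.max(np.abs(rec.bz_combined.bz - field)) < 1e-12

    def test_single_polarity_rejected(self, grid16):
        series = simulate_echo_series(_uniform_field(grid16), n_repeats=8)
        series.polarity[:] = 1.0
        with pytest.raises(ValueError, match="polarit"):
            reconstruct_bz_per_echo(series)

    def test_noise_scales_inversely_with_te(self, grid16):
        """With thermal noise only, the per-echo estimate sd goes as 1/TE."""
        zero = BzField(bz=np.zeros(grid16.shape), grid=grid16)
        series = simulate_echo_series(
            zero, te_s=(20e-3, 80e-3), n_repeats=64, tsnr=50.0,
            noise=NoiseModel(thermal_sd=1.0, seed=0),
        )
        bz_e, _ = reconstruct_bz_per_echo(series)
        sd = [float(np.std(b.bz)) for b in bz_e]
        assert sd[0] / sd[1] == pytest.approx(80.0 / 20.0, rel=0.15)


class TestEchoVariance:
    def test_variance_formula_scalings(self, rng):
        mag = 1.0 + 0.02 * rng.standard_normal((32, 6, 6, 6))
        v1 = estimate_echo_variance(mag, 20e-3)
        v2 = estimate_echo_variance(mag, 40e-3)
        assert np.allclose(v2, v1 / 4.0)

    def test_montecarlo_variance_matches_formula(self, rng):
        """Empirical variance of reconstructed B_z within 20% of the tSNR formula."""
        grid = GridGeometry.centered(8, 8.0)
        zero = BzField(bz=np.zeros(grid.shape), grid=grid)
        series = simulate_echo_series(
            zero, te_s=(25.6e-3,), n_repeats=100, tsnr=50.0,
            noise=NoiseModel(thermal_sd=1.0, seed=9),
        )
        bz_e, var_e = reconstruct_bz_per_echo(series)
        empirical = float(np.var(bz_e[0].bz))
        predicted = float(np.median(var_e[0]))
        assert empirical == pytest.approx(predicted, rel=0.2)

    def test_too_few_repeats_rejected(self, rng):
        with pytest.raises(ValueError, match="repeats"):
            estimate_echo_variance(rng.standard_normal((4, 3, 3, 3)) + 10, 20e-3)


class TestCombineEchoes:
    def test_equal_variances_give_mean(self, grid16):
        b1 = BzField(bz=np.full(grid16.shape, 1e-9), grid=grid16)
        b2 = BzField(bz=np.full(grid16.shape, 3e-9), grid=grid16)
        v = np.full(grid16.shape, 1e-20)
        combined, var_c = combine_echoes([b1, b2], [v, v])
        assert np.allclose(combined.bz, 2e-9)
        assert np.allclose(var_c, 0.5e-20)

    def test_infinite_variance_echo_ignored(self, grid16):
        b1 = BzField(bz=np.full(grid16.shape, 1e-9), grid=grid16)
        b2 = BzField(bz=np.full(grid16.shape, 5e-9), grid=grid16)
        v1 = np.full(grid16.shape, 1e-20)
        v2 = np.full(grid16.shape, 1e20)
        combined, _ = combine_echoes([b1, b2], [v1, v2])
        assert np.allclose(combined.bz, 1e-9, rtol=1e-6)

    def test_combined_variance_never_exceeds_best_echo(self, grid16, rng):
        vs = [10 ** rng.uniform(-20, -18, size=grid16.shape) for _ in range(3)]
        bs = [BzField(bz=rng.standard_normal(grid16.shape), grid=grid16) for _ in range(3)]
        _, var_c = combine_echoes(bs, vs)
        assert np.all(var_c <= np.minimum.reduce(vs) + 1e-40)

    def test_shape_mismatch_rejected(self, grid16):
        b = BzField(bz=np.zeros(grid16.shape), grid=grid16)
        with pytest.raises(ValueError, match="shape"):
            combine_echoes([b], [np.zeros((4, 4, 4))])


class TestPhysiologicalNoise:
    def test_zero_amplitude_zero_field(self, grid16):
        f = physiological_noise_field(grid16, 0.0, 30.0, 0)
        assert np.all(f == 0)

    def test_rms_normalization(self, grid16):
        f = physiological_noise_field(grid16, 2e-9, 30.0, 1)
        assert np.sqrt(np.mean(f**2)) == pytest.approx(2e-9, rel=1e-6)

    def test_nonpositive_corr_length_rejected(self, grid16):
        with pytest.raises(ValueError):
            physiological_noise_field(grid16, 1e-9, 0.0, 0)

    def test_autocorrelation_length(self):
        """Empirical e^{-1/2} decay distance near the requested correlation length."""
        grid = GridGeometry.centered(48, 4.0)
        target = 24.0
        lengths = []
        for seed in range(20):
            f = physiological_noise_field(grid, 1e-9, target, seed)
            fh = np.fft.fftn(f)
            acf = np.real(np.fft.ifftn(fh * np.conj(fh)))
            acf_x = acf[:, 0, 0] / acf[0, 0, 0]
            d = np.arange(len(acf_x)) * 4.0
            below = np.where(acf_x < np.exp(-0.5))[0][0]
            # linear interpolation to the crossing
            x0, x1 = d[below - 1], d[below]
            y0, y1 = acf_x[below - 1], acf_x[below]
            lengths.append(x0 + (np.exp(-0.5) - y0) * (x1 - x0) / (y1 - y0))
        assert np.mean(lengths) == pytest.approx(target, rel=0.15)


class TestStrayFieldAndMasking:
    def test_subtracting_own_field_gives_zero(self, grid16):
        loop = make_wire_loop((0, 0, 120.0), 100.0, 90, 0.002)
        stray = bz_wire_on_grid(loop, grid16)
        residual = subtract_stray_field(stray, loop)
        assert np.max(np.abs(residual.bz)) < 1e-20

    def test_tracking_error_leaves_structured_residual(self, grid16):
        loop = make_wire_loop((0, 0, 120.0), 100.0, 90, 0.002)
        tracked = make_wire_loop((0, 0, 120.0), 101.0, 90, 0.002)  # 1 mm radial bias
        stray = bz_wire_on_grid(loop, grid16)
        residual = subtract_stray_field(stray, tracked)
        assert np.sqrt(np.mean(residual.bz**2)) > 1e-12

    def test_mask_counts_label_voxels(self, small_vol):
        field = BzField(bz=np.ones(small_vol.grid.shape), grid=small_vol.grid)
        _, mask = apply_mask(field, small_vol, ("gm",))
        assert int(mask.sum()) == int((small_vol.labels == 4).sum())

    def test_empty_mask_rejected(self, small_vol):
        field = BzField(bz=np.ones(small_vol.grid.shape), grid=small_vol.grid)
        bad = small_vol.labels.copy()
        from mrcdi.phantom import TissueLabelVolume

        vol = TissueLabelVolume(labels=np.where(bad == 6, 5, bad), grid=small_vol.grid)
        with pytest.raises(MaskError):
            apply_mask(field, vol, ("vcsf",))


class TestExtractSlices:
    def test_single_voxel_thickness_is_plane(self, grid16, rng):
        data = rng.standard_normal(grid16.shape)
        field = BzField(bz=data, grid=grid16)
        z = grid16.axes()[2]
        [sl] = extract_slices(field, [z[5]], thickness_mm=grid16.voxel_size[2] * 0.99)
        assert np.array_equal(sl, data[:, :, 5])

    def test_five_slices_ten_mm_apart(self, small_vol, rng):
        field = BzField(bz=rng.standard_normal(small_vol.grid.shape), grid=small_vol.grid)
        slices = extract_slices(field, (-20, -10, 0, 10, 20), thickness_mm=3.0)
        assert len(slices) == 5

    def test_slab_mean_matches_bruteforce(self, grid16, rng):
        data = rng.standard_normal(grid16.shape)
        field = BzField(bz=data, grid=grid16)
        z = grid16.axes()[2]
        [sl] = extract_slices(field, [z[8]], thickness_mm=2.1 * grid16.voxel_size[2])
        assert np.allclose(sl, data[:, :, 7:10].mean(axis=2))

    def test_out_of_range_position_rejected(self, grid16):
        field = BzField(bz=np.zeros(grid16.shape), grid=grid16)
        with pytest.raises(ValueError, match="outside"):
            extract_slices(field, [500.0], thickness_mm=3.0)
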