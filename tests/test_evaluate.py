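import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from protobeam.evaluate import (GammaCriteria, ImagingScene, bandwidth_resolution,
                                gamma_index, line_spread_resolution,
                                localize_bragg_peak, max_frame_rate,
                                spot_tracking)
from protobeam.acoustic import (MediumProperties, PulseShape, TransducerResponse,
                                matrix_array)
from protobeam.beam_dose import BeamSpec, bragg_depth_dose, scan_pattern
from protobeam.volume import GridSpec, Volume


class TestBandwidthResolution:
    def test_matches_hand_arithmetic(self):
        """0.88 * 1500 m/s / 1.3 MHz = 1.015 mm (the ~1.01 mm regime of a
        1 MHz, 60%-bandwidth receiver in water-like media)."""
        r = bandwidth_resolution(1500.0, 1.3e6)
        assert r == pytest.approx(0.88 * 1500.0 / 1.3e6 * 1000.0, rel=1e-12)
        assert round(r, 2) == 1.02

    def test_inverse_proportionality_in_f_max(self):
        assert bandwidth_resolution(1500.0, 2.6e6) == \
            pytest.approx(bandwidth_resolution(1500.0, 1.3e6) / 2.0)

    def test_unit_conversion(self):
        assert bandwidth_resolution(0.88, 0.88) == pytest.approx(1000.0 * 0.88)

    @pytest.mark.parametrize("vs,f", [(0.0, 1e6), (1500.0, 0.0), (-1.0, 1e6)])
    def test_domain_errors(self, vs, f):
        with pytest.raises(ValueError):
            bandwidth_resolution(vs, f)


class TestFrameRate:
    def test_750_hz_with_10_averages_is_75_fps(self):
        assert max_frame_rate(750.0, 10) == 75.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            max_frame_rate(-1.0, 10)
        with pytest.raises(ValueError):
            max_frame_rate(750.0, 0)


def gaussian_blob(grid: GridSpec, center, sigma=1.5) -> Volume:
    c = grid.voxel_centers()
    r2 = np.sum((c - np.asarray(center)) ** 2, axis=-1)
    return Volume(np.exp(-r2 / (2 * sigma**2)), grid)


class TestLocalizeBraggPeak:
    grid = GridSpec.isotropic((21, 21, 21), 0.5, (-5.0, -5.0, -5.0))

    def test_argmax_subvoxel_on_symmetric_blob(self):
        vol = gaussian_blob(self.grid, (0.3, -0.2, 0.1))
        loc = localize_bragg_peak(vol, method="argmax")
        assert np.linalg.norm(loc.position_mm - [0.3, -0.2, 0.1]) < 0.05

    def test_shift_equivariance(self):
        l0 = localize_bragg_peak(gaussian_blob(self.grid, (0.0, 0.0, 0.0)))
        l1 = localize_bragg_peak(gaussian_blob(self.grid, (0.5, 0.0, 0.0)))
        np.testing.assert_allclose(l1.position_mm - l0.position_mm,
                                   [0.5, 0.0, 0.0], atol=1e-9)

    def test_centroid_method(self):
        vol = gaussian_blob(self.grid, (0.5, 0.5, -0.5))
        loc = localize_bragg_peak(vol, method="centroid")
        assert np.linalg.norm(loc.position_mm - [0.5, 0.5, -0.5]) < 0.2

    def test_distal80_matches_fine_grid_oracle(self):
        """Distal-80% depth on an asymmetric Bragg-like profile agrees with a
        dense 1D scan of the same analytic curve to < 0.05 mm."""
        grid = GridSpec((9, 9, 161), (0.5, 0.5, 0.25), (-2.0, -2.0, 0.0))
        z = grid.axis_coords(2)
        prof = bragg_depth_dose(40.0, z)
        vals = np.tile(prof, (9, 9, 1))
        # taper laterally so the peak is interior
        x = grid.axis_coords(0)[:, None, None]
        y = grid.axis_coords(1)[None, :, None]
        vals = vals * np.exp(-(x**2 + y**2) / 8.0)
        vol = Volume(vals, grid)
        loc = localize_bragg_peak(vol, beam_axis=(0, 0, 1), method="distal80")

        zf = np.arange(0.0, 40.0, 0.001)
        pf = bragg_depth_dose(40.0, zf)
        i_pk = np.argmax(pf)
        j = i_pk + np.argmax(pf[i_pk:] < 0.8 * pf.max())
        assert abs(loc.position_mm[2] - zf[j]) < 0.05

    def test_all_zero_volume_rejected(self):
        vol = Volume(np.zeros(self.grid.shape), self.grid)
        with pytest.raises(ValueError, match="no peak"):
            localize_bragg_peak(vol)


def brute_force_gamma(measured: Volume, reference: Volume, crit: GammaCriteria,
                      search_factor=2.0, subdivision=5):
    """Independent exhaustive gamma search: plain loops over every offset on
    the sub-voxel lattice, SciPy grid interpolation of the reference."""
    interp = RegularGridInterpolator(
        tuple(reference.grid.axis_coords(a) for a in range(3)),
        reference.values, bounds_error=False, fill_value=None, method="linear")
    sp = np.asarray(measured.grid.spacing)
    dd = crit.dose_tol_pct / 100.0 * reference.values.max()
    dta = crit.distance_tol_mm
    radius = search_factor * dta
    axes = [np.arange(-np.floor(radius / (s / subdivision)),
                      np.floor(radius / (s / subdivision)) + 1) * (s / subdivision)
            for s in sp]
    offs = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    offs = offs[np.einsum("ij,ij->i", offs, offs) <= radius**2]

    dist2 = np.einsum("ij,ij->i", offs, offs)
    lo = np.asarray(reference.grid.origin)
    hi = lo + (np.asarray(reference.grid.shape) - 1) * sp

    thr = crit.low_dose_threshold_pct / 100.0 * measured.values.max()
    out = np.full(measured.values.shape, np.nan)
    for idx in np.argwhere(measured.values >= thr):
        r = measured.grid.index_to_world(idx.astype(float))
        m = measured.values[tuple(idx)]
        # clamp to the raster edge, matching nearest-mode interpolation
        pts = np.clip(r + offs, lo, hi)
        g2 = dist2 / dta**2 + ((m - interp(pts)) / dd) ** 2
        out[tuple(idx)] = np.sqrt(g2.min())
    return out


class TestGammaIndex:
    def small_volumes(self):
        grid = GridSpec.isotropic((12, 12, 12), 1.0)
        c = grid.voxel_centers()
        ref = Volume(np.exp(-np.sum((c - 5.5) ** 2, axis=-1) / (2 * 9.0)), grid)
        return grid, ref

    def test_identity_gives_all_zero_and_full_pass(self):
        _, ref = self.small_volumes()
        res = gamma_index(ref, ref, GammaCriteria(5.0, 5.0, 10.0))
        assert res.pass_rate_pct == 100.0
        assert np.nanmax(res.gamma.values) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_5pct_offset_saturates_dose_term(self):
        """Measured = reference + 5% of max: gamma <= 1 everywhere under the
        5%/5 mm criterion (dose-term boundary case)."""
        grid, ref = self.small_volumes()
        meas = Volume(ref.values + 0.05 * ref.values.max(), grid)
        res = gamma_index(meas, ref, GammaCriteria(5.0, 5.0, 10.0))
        assert np.nanmax(res.gamma.values) <= 1.0 + 1e-9
        assert res.pass_rate_pct == 100.0

    def test_shift_by_dta_passes_shift_by_2dta_fails_on_ramp(self):
        """A ramp shifted by exactly the distance tolerance has gamma <= 1
        (distance term alone); twice the tolerance exceeds 1 on the
        flat-gradient interior."""
        # Gradient g = 0.04/mm, dd = 5% of ref max = 0.068: a shift s exceeds
        # gamma = 1 everywhere once s^2 > dta^2 + (dd/g)^2 = 4 + 2.9, i.e.
        # s = 4 mm fails while s = dta = 2 mm sits exactly at gamma = 1.
        grid = GridSpec.isotropic((30, 5, 5), 1.0)
        x = grid.axis_coords(0)[:, None, None]
        ramp = np.broadcast_to(0.2 + 0.04 * x, grid.shape).copy()
        ref = Volume(ramp, grid)
        crit = GammaCriteria(5.0, 2.0, 10.0)
        meas1 = Volume(np.broadcast_to(0.2 + 0.04 * (x - 2.0), grid.shape).copy(), grid)
        res1 = gamma_index(meas1, ref, crit)
        interior1 = res1.gamma.values[5:-5]
        assert np.nanmax(interior1) <= 1.0 + 1e-6
        meas2 = Volume(np.broadcast_to(0.2 + 0.04 * (x - 4.0), grid.shape).copy(), grid)
        res2 = gamma_index(meas2, ref, crit)
        interior2 = res2.gamma.values[5:-5]
        assert np.nanmin(interior2) > 1.0

    def test_matches_exhaustive_oracle(self):
        """Engine equals the independent exhaustive-search oracle on a small
        volume to 1e-6."""
        grid = GridSpec.isotropic((10, 10, 10), 1.0)
        rng = np.random.default_rng(5)
        c = grid.voxel_centers()
        ref = Volume(np.exp(-np.sum((c - 4.5) ** 2, axis=-1) / 18.0), grid)
        meas = Volume(ref.values * (1 + 0.04 * rng.standard_normal(grid.shape)),
                      grid)
        crit = GammaCriteria(3.0, 2.0, 10.0)
        res = gamma_index(meas, ref, crit, subdivision=3)
        oracle = brute_force_gamma(meas, ref, crit, subdivision=3)
        mask = ~np.isnan(oracle)
        assert np.nanmax(np.abs(res.gamma.values[mask] - oracle[mask])) < 1e-6

    def test_pass_rate_monotone_in_criteria(self):
        grid, ref = self.small_volumes()
        rng = np.random.default_rng(9)
        meas = Volume(ref.values * (1 + 0.1 * rng.standard_normal(grid.shape)), grid)
        rates = [gamma_index(meas, ref, GammaCriteria(dd, dta, 10.0)).pass_rate_pct
                 for dd, dta in [(1.0, 0.5), (3.0, 1.0), (5.0, 2.0), (8.0, 4.0)]]
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_raster_mismatch_and_empty_threshold_rejected(self):
        grid, ref = self.small_volumes()
        other = GridSpec.isotropic((12, 12, 12), 0.5)
        with pytest.raises(ValueError, match="resample"):
            gamma_index(Volume(np.ones(other.shape), other), ref, GammaCriteria())
        zero = Volume(np.zeros(grid.shape), grid)
        with pytest.raises(ValueError):
            gamma_index(ref, zero, GammaCriteria())


def tiny_scene(energy=40.0, variant="das", rows=8):
    """Small fast scene: 40 MeV beam (range ~15 mm) entering at z=25 toward
    the array plane.  The reconstruction window stops short of the
    pulse-trailing-edge ghost zone (~v_s*tau_p beyond the peak)."""
    beam = BeamSpec(energy, (0.0, 0.0, 25.0), (0.0, 0.0, -1.0),
                    lateral_sigma_mm=2.0)
    return ImagingScene(
        beam=beam,
        dose_grid=GridSpec.isotropic((31, 31, 55), 0.4, (-6.0, -6.0, 4.2)),
        recon_grid=GridSpec.isotropic((26, 26, 21), 0.4, (-5.0, -5.0, 5.8)),
        array=matrix_array(rows, rows),
        medium=MediumProperties.water(),
        pulse=PulseShape(4.0),
        response=TransducerResponse(),
        record_length_us=50.0,
        variant=variant,
    )


class TestSpotTracking:
    def test_three_spots_10mm_noiseless(self):
        """Three-spot scan at 10 mm plan spacing: recovered adjacent
        separations within one voxel of plan (full aperture so the outer
        spots stay well inside the array's view)."""
        from protobeam.experiments import scan_plan_from_scene
        scene = tiny_scene(rows=16)
        plan = scan_plan_from_scene(scene, 3, 10.0)
        table = spot_tracking(plan, scene)
        seps = table["separation_mm"].dropna().to_numpy()
        assert seps.shape == (2,)
        np.testing.assert_allclose(seps, 10.0, atol=0.4)
        # recovered absolute positions match the plan's lateral entries
        np.testing.assert_allclose(table["x_mm"].to_numpy(), [-10.0, 0.0, 10.0],
                                   atol=0.4)

    def test_single_spot_no_separations(self):
        scene = tiny_scene()
        plan = scan_pattern(scene.beam, 1, 5.0)
        table = spot_tracking(plan, scene)
        assert table["separation_mm"].dropna().empty


class TestLineSpreadResolution:
    def test_wideband_axial_fwhm_near_grid_floor(self):
        """A near-delta pulse and wideband receiver push the axial FWHM toward
        the sampling/grid floor (well below the 1 MHz-band value)."""
        est = line_spread_resolution(
            (0.0, 0.0, 25.0), matrix_array(8, 8), MediumProperties.water(),
            PulseShape(0.05, "rectangular"),
            TransducerResponse(5.0, 100.0),
            grid_spacing_mm=0.4, fov_mm=10.0, sampling_mhz=40.0,
            record_length_us=40.0)
        assert est.axial_fwhm_mm < 1.0

    def test_narrowband_axial_fwhm_larger_and_limits_reported(self):
        est = line_spread_resolution(
            (0.0, 0.0, 25.0), matrix_array(8, 8), MediumProperties.water(),
            PulseShape(4.0), TransducerResponse(1.0, 60.0),
            grid_spacing_mm=0.4, fov_mm=12.0, record_length_us=40.0)
        assert est.bandwidth_limit_mm == pytest.approx(1.0018, abs=0.01)
        assert est.axial_fwhm_mm > 0.4
        assert est.lateral_fwhm_mm >= est.axial_fwhm_mm * 0.5
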