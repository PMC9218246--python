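"""Hemodynamic maps: KE, FF/RF, stasis, PV, KER, cutoff, interpolation."""

import numpy as np
import pytest

from dissectflow import FlowSeries, PhantomConfig, generate_phantom
from dissectflow.geometry import (
    CenterlinePlanes,
    LumenSegmentation,
    assign_voxels_to_planes,
    derive_false_lumen,
)
from dissectflow.hemodynamics import (
    AnalysisGrid,
    apply_cycle_cutoff,
    compute_flow_maps,
    compute_ke_map,
    compute_peak_velocity,
    compute_stasis_map,
    export_parametric_maps,
    compute_parametric_maps,
    interpolate_to_isotropic,
    summarize,
)

KE_UNIT = 5.3e-4  # mJ for a 1 mm^3 voxel at 1 m/s


def make_grid(velocity, tl, fl=None, dt=50.0):
    fl = np.zeros_like(tl) if fl is None else fl
    return AnalysisGrid(
        velocity=velocity,
        tl_mask=tl,
        fl_mask=fl,
        aorta_mask=tl | fl,
        included_phases=list(range(velocity.shape[0])),
        dt_ms=dt,
        origin_mm=np.zeros(3),
    )


def z_centerline(n, xy=(2.0, 2.0)):
    points = np.column_stack(
        [np.full(n, xy[0]), np.full(n, xy[1]), np.arange(n, dtype=float)]
    )
    return CenterlinePlanes(
        points_mm=points,
        tangents=np.tile([0.0, 0.0, 1.0], (n, 1)),
        arc_length_mm=np.arange(n, dtype=float),
    )


def block_masks(shape, tl_slices):
    tl = np.zeros(shape, dtype=bool)
    tl[tl_slices] = True
    return tl


class TestCycleCutoff:
    @pytest.mark.parametrize(
        "n_phases, fraction, expected",
        [(30, 0.629, 19), (20, 0.629, 13), (20, 1.0, 20), (10, 0.5, 5)],
    )
    def test_phase_counts(self, n_phases, fraction, expected):
        v = np.zeros((n_phases, 2, 2, 2, 3))
        series = FlowSeries(
            velocity=v,
            magnitude=np.ones(v.shape[:4]),
            voxel_size_mm=(1.0,) * 3,
            temporal_resolution_ms=1000.0 / n_phases,
            venc_cms=160.0,
            rr_interval_ms=1000.0,
        )
        phases = apply_cycle_cutoff(series, fraction)
        assert phases == list(range(expected))

    def test_invalid_fraction(self):
        v = np.zeros((4, 2, 2, 2, 3))
        series = FlowSeries(
            velocity=v,
            magnitude=np.ones(v.shape[:4]),
            voxel_size_mm=(1.0,) * 3,
            temporal_resolution_ms=250.0,
            venc_cms=160.0,
            rr_interval_ms=1000.0,
        )
        with pytest.raises(ValueError):
            apply_cycle_cutoff(series, 0.0)


class TestInterpolation:
    def _series(self, velocity):
        return FlowSeries(
            velocity=velocity,
            magnitude=np.ones(velocity.shape[:4]),
            voxel_size_mm=(2.0, 2.0, 2.0),
            temporal_resolution_ms=50.0,
            venc_cms=160.0,
            rr_interval_ms=50.0 * velocity.shape[0],
        )

    def _seg(self, shape):
        aorta = np.zeros(shape, dtype=bool)
        aorta[2:-2, 2:-2, 2:-2] = True
        tl = aorta.copy()
        return LumenSegmentation(
            aorta_mask=aorta, tl_mask=tl, fl_mask=np.zeros_like(tl), voxel_size_mm=(2.0,) * 3
        )

    def test_constant_field_reproduced(self):
        v = np.full((2, 12, 12, 12, 3), 0.37)
        grid = interpolate_to_isotropic(self._series(v), self._seg((12, 12, 12)))
        assert np.abs(grid.velocity - 0.37).max() < 1e-9

    def test_linear_field_reproduced_in_interior(self):
        # cubic splines reproduce linear fields away from the volume
        # boundary, where the prefilter's edge condition has decayed
        n = 36
        v = np.zeros((1, n, n, n, 3))
        x_mm = 2.0 * np.arange(n)
        v[0, ..., 0] = 0.01 * x_mm[None, None, :]
        grid = interpolate_to_isotropic(self._series(v), self._seg((n, n, n)))
        zz, yy, xx = np.indices(grid.tl_mask.shape).astype(float)
        expected = 0.01 * (xx + grid.origin_mm[0])
        err = np.abs(grid.velocity[0, ..., 0] - expected)
        m = 28  # >= 14 native voxels in from every face
        assert err[m:-m, m:-m, m:-m].max() < 1e-6

    def test_phantom_parabola_within_two_percent_rms(self):
        cfg = PhantomConfig(noise_sigma_ms=0.0, tear_jet_speed_ms=0.0, n_phases=4)
        series, truth = generate_phantom(cfg)
        seg = derive_false_lumen(truth.aorta_mask, truth.tl_mask, series.voxel_size_mm)
        grid = interpolate_to_isotropic(series, seg, included_phases=[0])
        from dissectflow.phantom import waveform_values

        w_tl, _, _ = waveform_values(cfg)
        zz, yy, xx = np.indices(grid.tl_mask.shape).astype(float)
        cx = (cfg.grid_shape[0] - 1) / 2 * cfg.voxel_size_mm
        cy = cx - cfg.fl_radius_mm
        r2 = (xx + grid.origin_mm[0] - cx) ** 2 + (yy + grid.origin_mm[1] - cy) ** 2
        analytic = w_tl[0] * np.maximum(1 - r2 / cfg.tl_radius_mm**2, 0.0)
        speed = np.linalg.norm(grid.velocity[0], axis=-1)
        m = grid.tl_mask
        rms = np.sqrt(((speed[m] - analytic[m]) ** 2).mean())
        assert rms <= 0.02 * analytic[m].max()

    def test_masks_resampled_nearest_preserve_topology(self, noiseless_phantom):
        from scipy import ndimage

        _, series, truth = noiseless_phantom
        seg = derive_false_lumen(truth.aorta_mask, truth.tl_mask, series.voxel_size_mm)
        grid = interpolate_to_isotropic(series, seg, included_phases=[0])
        for mask in (grid.tl_mask, grid.fl_mask):
            _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
            assert n == 1


class TestKineticEnergy:
    def test_unit_speed_single_phase(self):
        v = np.zeros((1, 1, 1, 1, 3))
        v[..., 2] = 1.0
        tl = np.ones((1, 1, 1), dtype=bool)
        _, per = compute_ke_map(make_grid(v, tl))
        assert per["TL"] == pytest.approx(KE_UNIT, rel=1e-12)

    def test_zero_velocity(self):
        tl = np.ones((2, 2, 2), dtype=bool)
        _, per = compute_ke_map(make_grid(np.zeros((3, 2, 2, 2, 3)), tl))
        assert per["TL"] == 0.0

    def test_uniform_speed_over_ten_phases(self):
        v = np.zeros((10, 3, 3, 3, 3))
        v[..., 0] = 1.0
        tl = np.ones((3, 3, 3), dtype=bool)
        _, per = compute_ke_map(make_grid(v, tl))
        assert per["TL"] == pytest.approx(10 * KE_UNIT, rel=1e-12)


class TestFlowDecomposition:
    def test_constant_forward_flow(self):
        v = np.zeros((20, 5, 5, 5, 3))
        v[..., 2] = 0.1
        tl = np.ones((5, 5, 5), dtype=bool)
        grid = make_grid(v, tl, dt=40.0)
        cl = z_centerline(5)
        a = assign_voxels_to_planes(grid.seg, cl)
        _, _, ff, rf = compute_flow_maps(grid, a, cl)
        assert ff["TL"] == pytest.approx(0.08, rel=1e-12)
        assert rf["TL"] == 0.0

    def test_sign_reversal_swaps_ff_rf(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(6, 4, 4, 4, 3))
        tl = np.ones((4, 4, 4), dtype=bool)
        cl = z_centerline(4)
        g1 = make_grid(v, tl)
        g2 = make_grid(-v, tl)
        a = assign_voxels_to_planes(g1.seg, cl)
        ff1_map, rf1_map, _, _ = compute_flow_maps(g1, a, cl)
        ff2_map, rf2_map, _, _ = compute_flow_maps(g2, a, cl)
        assert np.allclose(ff1_map[tl], rf2_map[tl])
        assert np.allclose(rf1_map[tl], ff2_map[tl])

    def test_balanced_phases_give_equal_ff_rf(self):
        v = np.zeros((8, 3, 3, 3, 3))
        v[:4, ..., 2] = 0.3
        v[4:, ..., 2] = -0.3
        tl = np.ones((3, 3, 3), dtype=bool)
        grid = make_grid(v, tl)
        cl = z_centerline(3)
        a = assign_voxels_to_planes(grid.seg, cl)
        _, _, ff, rf = compute_flow_maps(grid, a, cl)
        assert ff["TL"] == pytest.approx(rf["TL"], rel=1e-12)

    def test_decomposition_conserves_net_flow(self):
        """FF - RF equals the signed net flow per voxel, exactly."""
        rng = np.random.default_rng(123)
        v = rng.normal(scale=0.5, size=(10, 6, 6, 6, 3))
        tl = rng.random((6, 6, 6)) < 0.7
        tl[0, 0, 0] = True
        grid = make_grid(v, tl, dt=37.0)
        cl = z_centerline(6)
        a = assign_voxels_to_planes(grid.seg, cl)
        ff_map, rf_map, _, _ = compute_flow_maps(grid, a, cl)
        net = 1e-3 * (v[:, tl, 2] * 37.0).sum(axis=0)
        assert np.allclose(ff_map[tl] - rf_map[tl], net, atol=1e-15)


class TestStasis:
    @pytest.mark.parametrize(
        "speed, expected", [(0.05, 100.0), (0.2, 0.0), (0.0999, 100.0), (0.1, 0.0)]
    )
    def test_uniform_speed(self, speed, expected):
        v = np.zeros((4, 2, 2, 2, 3))
        v[..., 1] = speed
        tl = np.ones((2, 2, 2), dtype=bool)
        _, per = compute_stasis_map(make_grid(v, tl))
        assert per["TL"] == expected

    def test_fractional_phases(self):
        v = np.zeros((20, 2, 2, 2, 3))
        v[..., 0] = 0.5
        v[:5, ..., 0] = 0.01  # 5 of 20 below threshold
        tl = np.ones((2, 2, 2), dtype=bool)
        _, per = compute_stasis_map(make_grid(v, tl))
        assert per["TL"] == 25.0


class TestPeakVelocity:
    def test_uniform_peak_phase(self):
        v = np.zeros((6, 3, 3, 3, 3))
        v[..., 2] = 1.0
        v[3, ..., 2] = 2.0
        tl = np.ones((3, 3, 3), dtype=bool)
        _, per = compute_peak_velocity(make_grid(v, tl))
        assert per["TL"] == pytest.approx(200.0, rel=1e-12)

    def test_top_five_percent_average(self):
        v = np.zeros((1, 1, 10, 10, 3))
        v[..., 0] = 1.0
        v[0, 0, 0, :5, 0] = 3.0  # 5 voxels of 100
        tl = np.ones((1, 10, 10), dtype=bool)
        _, per = compute_peak_velocity(make_grid(v, tl))
        assert per["TL"] == pytest.approx(300.0, rel=1e-12)

    def test_lumens_peak_independently(self):
        v = np.zeros((4, 2, 2, 2, 3))
        tl = np.zeros((2, 2, 2), dtype=bool)
        tl[0] = True
        fl = ~tl
        v[1, tl, 0] = 1.0  # TL peaks at phase 1
        v[3, fl, 0] = 0.5  # FL peaks at phase 3
        _, per = compute_peak_velocity(make_grid(v, tl, fl))
        assert per["TL"] == pytest.approx(100.0)
        assert per["FL"] == pytest.approx(50.0)


class TestSummary:
    PER_LUMEN = {
        "TL": {"KE_mJ": 2.0, "FF_mL_per_cycle": 1.0, "RF_mL_per_cycle": 0.1,
               "stasis_pct": 10.0, "PV_cms": 220.0},
        "FL": {"KE_mJ": 4.0, "FF_mL_per_cycle": 0.5, "RF_mL_per_cycle": 0.2,
               "stasis_pct": 60.0, "PV_cms": 80.0},
    }

    def test_ker_and_indexing(self):
        s = summarize(self.PER_LUMEN, baseline_diameter_mm=44.0)
        assert s.ker == pytest.approx(2.0)
        assert s.indexed["TL"]["PV_cms"] == pytest.approx(5.0)
        for lumen in ("TL", "FL"):
            for key, raw in self.PER_LUMEN[lumen].items():
                assert s.indexed[lumen][key] * 44.0 == pytest.approx(raw, rel=1e-12)

    def test_unit_diameter_identity(self):
        s = summarize(self.PER_LUMEN, baseline_diameter_mm=1.0)
        assert s.indexed["TL"] == self.PER_LUMEN["TL"]

    def test_zero_tl_ke_flags_ker(self):
        per = {"TL": dict(self.PER_LUMEN["TL"], KE_mJ=0.0), "FL": self.PER_LUMEN["FL"]}
        s = summarize(per, baseline_diameter_mm=40.0)
        assert s.ker is None
        assert any("KER" in f for f in s.flags)


class TestScalingAndMonotonicity:
    def _outputs(self, v):
        tl = np.ones(v.shape[1:4], dtype=bool)
        grid = make_grid(v, tl)
        cl = z_centerline(v.shape[1])
        a = assign_voxels_to_planes(grid.seg, cl)
        _, per = compute_parametric_maps(grid, a, cl)
        return per["TL"]

    def test_velocity_scaling_laws(self):
        rng = np.random.default_rng(5)
        v = rng.normal(scale=0.4, size=(6, 4, 4, 4, 3))
        base = self._outputs(v)
        scaled = self._outputs(3.0 * v)
        assert scaled["KE_mJ"] == pytest.approx(9.0 * base["KE_mJ"], rel=1e-9)
        assert scaled["FF_mL_per_cycle"] == pytest.approx(3.0 * base["FF_mL_per_cycle"], rel=1e-9)
        assert scaled["RF_mL_per_cycle"] == pytest.approx(3.0 * base["RF_mL_per_cycle"], rel=1e-9)
        assert scaled["PV_cms"] == pytest.approx(3.0 * base["PV_cms"], rel=1e-9)

    def test_adding_phases_is_monotone(self):
        rng = np.random.default_rng(9)
        v = rng.normal(scale=0.4, size=(8, 3, 3, 3, 3))
        tl = np.ones((3, 3, 3), dtype=bool)
        cl = z_centerline(3)
        small = make_grid(v[:4], tl)
        large = make_grid(v, tl)
        a = assign_voxels_to_planes(small.seg, cl)
        ke_s, _ = compute_ke_map(small)
        ke_l, _ = compute_ke_map(large)
        ff_s, rf_s, _, _ = compute_flow_maps(small, a, cl)
        ff_l, rf_l, _, _ = compute_flow_maps(large, a, cl)
        assert (ke_l[tl] >= ke_s[tl]).all()
        assert (ff_l[tl] >= ff_s[tl]).all()
        assert (rf_l[tl] >= rf_s[tl]).all()


class TestExport:
    def test_roundtrip_and_background_nan(self, tmp_path):
        from dissectflow.io import load_volume

        rng = np.random.default_rng(2)
        v = rng.normal(scale=0.3, size=(4, 6, 6, 6, 3))
        tl = np.zeros((6, 6, 6), dtype=bool)
        tl[1:5, 1:5, 1:5] = True
        grid = make_grid(v, tl)
        cl = z_centerline(6)
        a = assign_voxels_to_planes(grid.seg, cl)
        maps, _ = compute_parametric_maps(grid, a, cl)
        paths = export_parametric_maps(maps, grid, tmp_path)
        nifti_paths = [p for name, p in paths.items() if name != "report"]
        assert len(nifti_paths) == 5
        vol, _ = load_volume(paths["kinetic_energy_mJ"])
        assert np.allclose(vol[tl], maps.ke_map[tl], rtol=1e-6)
        assert np.isnan(vol[~tl]).all()
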