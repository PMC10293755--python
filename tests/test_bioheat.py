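import numpy as np
import pytest

from thermospread import (
    CauteryApplication,
    TemperatureField,
    TissueModel,
    ground_truth_damage,
    simulate_field,
    surface_slice,
)
from thermospread.bioheat import max_stable_dt, source_mask
from thermospread.errors import ConfigError, StabilityError

NO_SOURCE = CauteryApplication(power_w=0.0, duration_s=0.01)


def gaussian_bump(tissue, amplitude=20.0, sigma_mm=2.0):
    nx, ny, nz = tissue.dims
    v = tissue.voxel_mm
    z, y, x = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    r2 = (
        ((x - (nx - 1) / 2) * v) ** 2
        + ((y - (ny - 1) / 2) * v) ** 2
        + ((z - (nz - 1) / 2) * v) ** 2
    )
    return tissue.ambient_c + amplitude * np.exp(-r2 / (2 * sigma_mm**2))


def axis_variance(excess, axis, pitch):
    w = excess.sum(axis=tuple(i for i in range(3) if i != axis))
    c = (np.arange(len(w)) + 0.5) * pitch
    mean = (w * c).sum() / w.sum()
    return (w * (c - mean) ** 2).sum() / w.sum()


class TestSimulateField:
    def test_zero_power_stays_ambient(self, tiny_tissue):
        fld = simulate_field(tiny_tissue, NO_SOURCE, t_end_s=1.0, dt_s=0.1, snapshot_every_s=0.5)
        np.testing.assert_array_equal(fld.snapshots, 37.0)

    def test_insulated_conservation(self, default_tissue):
        init = gaussian_bump(default_tissue)
        dt = 0.05
        fld = simulate_field(
            default_tissue, NO_SOURCE, t_end_s=100 * dt, dt_s=dt, snapshot_every_s=100 * dt,
            initial=init,
        )
        e0 = (fld.snapshots[0] - 37.0).sum()
        e1 = (fld.snapshots[-1] - 37.0).sum()
        assert abs(e1 - e0) / e0 < 1e-6

    def test_gaussian_variance_growth(self, default_tissue):
        # per-axis variance grows as sigma0^2 + 2*alpha*t for pure diffusion
        init = gaussian_bump(default_tissue, sigma_mm=2.0)
        t_end = 5.0
        fld = simulate_field(
            default_tissue, NO_SOURCE, t_end_s=t_end, dt_s=0.05, snapshot_every_s=t_end,
            initial=init,
        )
        alpha = default_tissue.diffusivity_mm2_s
        for axis in range(3):
            v0 = axis_variance(fld.snapshots[0] - 37.0, axis, default_tissue.voxel_mm)
            v1 = axis_variance(fld.snapshots[-1] - 37.0, axis, default_tissue.voxel_mm)
            assert v1 == pytest.approx(v0 + 2 * alpha * t_end, rel=0.01)

    def test_stability_violation_names_admissible_dt(self, tiny_tissue):
        dt_max = max_stable_dt(tiny_tissue)
        with pytest.raises(StabilityError, match=f"{dt_max:.6g}"):
            simulate_field(
                tiny_tissue, NO_SOURCE, t_end_s=1.0, dt_s=2 * dt_max, snapshot_every_s=0.5
            )

    def test_footprint_outside_grid_rejected(self, tiny_tissue):
        app = CauteryApplication(power_w=30.0, duration_s=2.0, prong_size_mm=(10.0, 4.0))
        with pytest.raises(ConfigError, match="footprint"):
            simulate_field(tiny_tissue, app, t_end_s=3.0, dt_s=0.1, snapshot_every_s=1.0)

    def test_t_end_before_application_end_rejected(self, tiny_tissue):
        app = CauteryApplication(power_w=30.0, duration_s=2.0)
        with pytest.raises(ConfigError):
            simulate_field(tiny_tissue, app, t_end_s=1.0, dt_s=0.1, snapshot_every_s=0.5)

    def test_maximum_principle_no_source(self, tiny_tissue):
        init = gaussian_bump(tiny_tissue)
        fld = simulate_field(
            tiny_tissue, NO_SOURCE, t_end_s=2.0, dt_s=0.1, snapshot_every_s=0.2, initial=init
        )
        maxima = fld.snapshots.max(axis=(1, 2, 3))
        minima = fld.snapshots.min(axis=(1, 2, 3))
        assert (np.diff(maxima) <= 1e-12).all()
        assert (np.diff(minima) >= -1e-12).all()

    def test_linearity_in_source(self, tiny_tissue):
        kw = dict(t_end_s=2.0, dt_s=0.1, snapshot_every_s=0.5)
        f1 = simulate_field(
            tiny_tissue, CauteryApplication(power_w=15.0, duration_s=1.0), **kw
        )
        f2 = simulate_field(
            tiny_tissue, CauteryApplication(power_w=30.0, duration_s=1.0), **kw
        )
        np.testing.assert_allclose(
            f2.snapshots - 37.0, 2 * (f1.snapshots - 37.0), rtol=1e-10, atol=1e-9
        )

    def test_fixed_ambient_boundary_loses_heat(self):
        tissue = TissueModel(dims=(16, 16, 8), voxel_mm=1.0, boundary="fixed_ambient")
        init = gaussian_bump(tissue)
        fld = simulate_field(
            tissue, NO_SOURCE, t_end_s=5.0, dt_s=0.5, snapshot_every_s=5.0, initial=init
        )
        assert (fld.snapshots[-1] - 37.0).sum() < (fld.snapshots[0] - 37.0).sum()

    def test_convective_top_face_cools(self):
        warm = TissueModel(dims=(8, 8, 4), voxel_mm=1.0, surface_h_w_mm2_k=1e-4)
        init = np.full((4, 8, 8), 50.0)
        fld = simulate_field(warm, NO_SOURCE, t_end_s=5.0, dt_s=0.5, snapshot_every_s=5.0, initial=init)
        assert fld.snapshots[-1][0].mean() < 50.0

    def test_grid_refinement_consistency(self):
        # halving the voxel changes ground-truth area by < 10% (default scenario)
        areas = {}
        for dims, vox, dt in [((60, 60, 40), 0.5, 0.02), ((120, 120, 80), 0.25, 0.01)]:
            tissue = TissueModel(dims=dims, voxel_mm=vox)
            app = CauteryApplication(power_w=30.0, duration_s=2.0)
            fld = simulate_field(tissue, app, t_end_s=3.0, dt_s=dt, snapshot_every_s=0.5)
            areas[vox] = ground_truth_damage(fld).surface_area_mm2
        assert areas[0.25] == pytest.approx(areas[0.5], rel=0.10)


class TestSourceMask:
    def test_two_prongs_symmetric(self, reduced_tissue):
        app = CauteryApplication(power_w=30.0, duration_s=2.0)
        mask = source_mask(reduced_tissue, app)
        top = mask[0]
        assert mask.any()
        np.testing.assert_array_equal(top, top[:, ::-1])  # mirror symmetry in x
        assert top[:, top.shape[1] // 2 - 1 : top.shape[1] // 2 + 1].sum() == 0  # gap


class TestSurfaceSlice:
    def test_uniform_field(self, tiny_tissue):
        fld = simulate_field(tiny_tissue, NO_SOURCE, t_end_s=1.0, dt_s=0.1, snapshot_every_s=0.5)
        np.testing.assert_array_equal(surface_slice(fld), 37.0)

    def test_slice_max_bounded_by_field_max(self, sim_field_30w2s):
        sl = surface_slice(sim_field_30w2s)
        for t in range(sl.shape[0]):
            assert sl[t].max() <= sim_field_30w2s.snapshots[t].max() + 1e-12

    def test_equals_direct_indexing(self, sim_field_30w2s):
        np.testing.assert_array_equal(
            surface_slice(sim_field_30w2s), sim_field_30w2s.snapshots[:, 0, :, :]
        )


class TestGroundTruthDamage:
    def _field_from(self, grids, voxel_mm=1.0):
        snaps = np.stack([np.asarray(g, dtype=float) for g in grids])
        return TemperatureField(
            snapshots=snaps,
            times=np.arange(snaps.shape[0], dtype=float),
            dt_s=1.0,
            voxel_mm=voxel_mm,
            ambient_c=37.0,
        )

    def test_never_above_threshold(self, tiny_tissue):
        fld = simulate_field(tiny_tissue, NO_SOURCE, t_end_s=1.0, dt_s=0.1, snapshot_every_s=0.5)
        truth = ground_truth_damage(fld)
        assert truth.surface_area_mm2 == 0.0
        assert truth.max_depth_mm == 0.0

    def test_handcrafted_field_convention(self):
        grid = np.full((3, 4, 4), 37.0)
        grid[0].flat[:5] = 70.0  # 5 hot voxels in the top layer only
        fld = self._field_from([np.full((3, 4, 4), 37.0), grid])
        truth = ground_truth_damage(fld)
        assert truth.surface_area_mm2 == 5.0
        assert truth.max_depth_mm == 0.5  # center of layer 0 at 1 mm voxels

    def test_depth_uses_deepest_layer_center(self):
        grid = np.full((4, 3, 3), 37.0)
        grid[0, 0, 0] = 70.0
        grid[2, 1, 1] = 70.0
        fld = self._field_from([grid], voxel_mm=0.5)
        assert ground_truth_damage(fld).max_depth_mm == pytest.approx(2.5 * 0.5)

    def test_longer_application_spreads_more(self, reduced_tissue):
        kw = dict(dt_s=0.05, snapshot_every_s=0.2)
        truths = {}
        for dur in (2.0, 4.0):
            app = CauteryApplication(power_w=30.0, duration_s=dur)
            fld = simulate_field(reduced_tissue, app, t_end_s=dur + 1.0, **kw)
            truths[dur] = ground_truth_damage(fld)
        assert truths[4.0].surface_area_mm2 >= truths[2.0].surface_area_mm2
        assert truths[4.0].max_depth_mm >= truths[2.0].max_depth_mm
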