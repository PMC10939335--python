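"""Voxelization and the transient conduction solver."""

import numpy as np
import pandas as pd
import pytest

import thermoseed as ts
from thermoseed.heat import (ConvectionModel, ResolutionError,
                             build_voxel_scene, solve_transient,
                             surface_average, volume_average)
from thermoseed.scene import MaterialProps


def scaffold_only_scene(material=None, h_air=10.0, duration=600.0,
                        t_off=600.0, d=20e-3, height=20e-3):
    exposure = ts.ExposureConfig(duration=duration, field_off_time=t_off,
                                 convective_coeff_air=h_air, medium_mode="air")
    region = ts.CylinderRegion(d, height, role_label="scaffold")
    return ts.validate_scene(ts.CoilSpec(), [region],
                             {"scaffold": material or ts.IRON_PLA}, exposure)


def uniform_power(vox, p_vol):
    power = np.zeros(vox.shape)
    power[vox.labels > 0] = p_vol
    return power


class TestVoxelization:
    def test_labeled_volume_within_5pct_at_1mm(self, default_scene):
        vox = build_voxel_scene(default_scene, 1e-3)
        vol = vox.region_mask("scaffold").sum() * (1e-3) ** 3
        assert vol == pytest.approx(default_scene.scaffold.volume(), rel=5e-2)

    def test_translation_equivariance(self, default_scene):
        shifted = default_scene.shifted((3e-3, 0, 0))
        v0 = build_voxel_scene(default_scene, 1e-3)
        v1 = build_voxel_scene(shifted, 1e-3)
        for v, scene in ((v0, default_scene), (v1, shifted)):
            mask = v.region_mask("scaffold")
            x, y, z = np.meshgrid(*v.grid_axes, indexing="ij")
            centroid = np.array([x[mask].mean(), y[mask].mean(), z[mask].mean()])
            assert centroid == pytest.approx(scene.scaffold.center, abs=0.5e-3)

    def test_refinement_reduces_volume_error(self, default_scene):
        errs = []
        for res in (2e-3, 1e-3, 0.5e-3):
            vox = build_voxel_scene(default_scene, res)
            vol = vox.region_mask("scaffold").sum() * res**3
            errs.append(abs(vol - default_scene.scaffold.volume()))
        assert errs[2] < errs[0]

    def test_too_coarse_resolution_rejected(self, default_scene):
        with pytest.raises(ResolutionError):
            build_voxel_scene(default_scene, 6e-3)


class TestTransient:
    def test_zero_power_stays_at_ambient(self):
        scene = scaffold_only_scene(duration=60.0, t_off=60.0)
        vox = build_voxel_scene(scene, 2e-3)
        hist = solve_transient(vox, uniform_power(vox, 0.0), scene.exposure)
        assert np.nanmax(np.abs(hist.fields - 19.0)) < 1e-9

    def test_insulated_uniform_ramp_exact(self):
        """h = 0, uniform source: dT/dt = P/(rho Cp) to 1e-6 relative."""
        scene = scaffold_only_scene(h_air=0.0, duration=100.0, t_off=100.0)
        vox = build_voxel_scene(scene, 2e-3)
        p = 1e5
        hist = solve_transient(vox, uniform_power(vox, p), scene.exposure)
        avg = volume_average(hist, "scaffold")
        expected = 19.0 + p * 100.0 / ts.IRON_PLA.volumetric_heat_capacity
        assert avg.iloc[-1] == pytest.approx(expected, rel=1e-6)
        spread = np.nanmax(hist.fields[-1]) - np.nanmin(hist.fields[-1])
        assert spread < 1e-9

    def test_lumped_capacitance_cooling(self):
        """Small Biot number: post-switch-off decay follows the lumped time
        constant rho Cp V / (h A) within 5%."""
        hi_k = MaterialProps(3.0, 0.0, 50.0, 1200.0, 2700.0)   # Bi ~ 1e-3
        scene = scaffold_only_scene(material=hi_k, duration=2000.0, t_off=100.0)
        vox = build_voxel_scene(scene, 2e-3)
        hist = solve_transient(vox, uniform_power(vox, 2e5), scene.exposure,
                               dt=0.5)
        avg = volume_average(hist, "scaffold")
        cool = avg[avg.index >= 150.0]
        theta = (cool - 19.0) / (cool.iloc[0] - 19.0)
        tau_fit = -1.0 / np.polyfit(cool.index - cool.index[0],
                                    np.log(theta), 1)[0]
        dx = 2e-3
        mask = vox.region_mask("scaffold")
        vol = mask.sum() * dx**3
        # exposed area of the voxelized body
        from thermoseed.heat import _surface_mask
        faces = 0
        padded = np.pad(mask, 1)
        for d in range(3):
            faces += np.sum(padded & ~np.roll(padded, 1, axis=d))
            faces += np.sum(padded & ~np.roll(padded, -1, axis=d))
        area = faces * dx**2
        tau_expected = hi_k.volumetric_heat_capacity * vol / (10.0 * area)
        assert tau_fit == pytest.approx(tau_expected, rel=5e-2)

    def test_energy_conservation_adiabatic(self, default_scene):
        """h = 0: enthalpy increase equals time-integrated power within 1%."""
        from dataclasses import replace
        exposure = replace(default_scene.exposure, duration=60.0,
                           field_off_time=60.0, convective_coeff_air=0.0)
        scene = ts.validate_scene(default_scene.coil, default_scene.regions,
                                  default_scene.materials, exposure)
        vox = build_voxel_scene(scene, 2e-3)
        rng = np.random.default_rng(1)
        power = np.zeros(vox.shape)
        solid = vox.labels > 0
        power[solid] = rng.uniform(0, 1e5, solid.sum())
        hist = solve_transient(vox, power, exposure, dt=0.5)
        dx = vox.resolution
        rho_cp = vox.property_map("volumetric_heat_capacity")
        dH = np.nansum((hist.fields[-1] - hist.fields[0]) * rho_cp) * dx**3
        assert dH == pytest.approx(power.sum() * dx**3 * 60.0, rel=1e-2)

    def test_cooling_branch_maximum_principle(self):
        """No source after switch-off: the global maximum never rises."""
        scene = scaffold_only_scene(duration=200.0, t_off=50.0)
        vox = build_voxel_scene(scene, 2e-3)
        hist = solve_transient(vox, uniform_power(vox, 5e5), scene.exposure)
        peaks = np.nanmax(hist.fields, axis=(1, 2, 3))
        after = peaks[hist.times >= 50.0]
        assert np.all(np.diff(after) <= 1e-9)

    def test_explicit_matches_implicit(self):
        scene = scaffold_only_scene(duration=30.0, t_off=30.0, d=12e-3,
                                    height=12e-3)
        vox = build_voxel_scene(scene, 3e-3)
        p = uniform_power(vox, 5e5)
        imp = solve_transient(vox, p, scene.exposure, dt=0.05)
        exp = solve_transient(vox, p, scene.exposure, method="explicit")
        diff = np.nanmax(np.abs(imp.fields[-1] - exp.fields[-1]))
        rise = np.nanmax(imp.fields[-1]) - 19.0
        assert diff < 0.02 * rise


class TestAverages:
    def test_uniform_field_averages_equal(self):
        scene = scaffold_only_scene(duration=10.0, t_off=10.0)
        vox = build_voxel_scene(scene, 2e-3)
        hist = solve_transient(vox, uniform_power(vox, 0.0), scene.exposure)
        v = volume_average(hist, "scaffold")
        s = surface_average(hist, "scaffold")
        np.testing.assert_allclose(v.values, s.values, atol=1e-12)

    def test_average_bounded_by_extremes(self, centered_result):
        hist = centered_result.history
        avg = volume_average(hist, "scaffold").values
        mask = hist.labels == 1
        lo = hist.fields[:, mask].min(axis=1)
        hi = hist.fields[:, mask].max(axis=1)
        assert np.all(avg >= lo - 1e-12) and np.all(avg <= hi + 1e-12)

    def test_centered_run_peaks_at_field_off(self, centered_result):
        avg = volume_average(centered_result.history, "scaffold")
        assert avg.idxmax() == pytest.approx(600.0, abs=1.5)

    def test_in_air_surface_below_volume_peak(self, air_result):
        """An IR camera (surface reading) underestimates the internal
        temperature of a scaffold heated in air."""
        vol = volume_average(air_result.history, "scaffold")
        surf = surface_average(air_result.history, "scaffold")
        assert surf.max() < vol.max()

    def test_empty_region_rejected(self, air_result):
        with pytest.raises(ValueError):
            volume_average(air_result.history, "phantom")


class TestWaterConvection:
    def _water_runs(self, duration=120.0):
        from thermoseed.pipeline import run_simulation
        scene = ts.default_scene("water")
        runs = {}
        for name, model in (("cond", ConvectionModel(forced_factor=1.0)),
                            ("conv", ConvectionModel())):
            runs[name] = run_simulation(scene, resolution=2e-3, noise_sd=0.0,
                                        duration=duration, sample=False,
                                        convection=model, dt=0.5)
        return runs

    def test_forced_unity_factor_reduces_to_conduction(self):
        from thermoseed.pipeline import run_simulation
        scene = ts.default_scene("water")
        plain = run_simulation(scene, resolution=2e-3, noise_sd=0.0,
                               duration=60.0, sample=False, dt=0.5)
        forced = run_simulation(scene, resolution=2e-3, noise_sd=0.0,
                                duration=60.0, sample=False, dt=0.5,
                                convection=ConvectionModel(forced_factor=1.0))
        np.testing.assert_allclose(forced.history.fields, plain.history.fields,
                                   atol=1e-9, equal_nan=True)

    def test_enhancement_lowers_peak(self):
        runs = self._water_runs()
        pc = volume_average(runs["cond"].history, "scaffold").max()
        pv = volume_average(runs["conv"].history, "scaffold").max()
        assert pv < pc

    def test_enhancement_factor_at_least_one(self):
        model = ConvectionModel()
        for dT in (0.0, 0.1, 5.0, 40.0):
            assert model.enhancement(dT) >= 1.0


def test_history_csv_export(tmp_path, air_result):
    path = tmp_path / "hist.csv"
    ts_hist = air_result.history
    from thermoseed.heat import history_to_csv
    history_to_csv(ts_hist, path, times=[0.0, 300.0])
    df = pd.read_csv(path)
    n_solid = int((ts_hist.labels > 0).sum())
    assert len(df) == 2 * n_solid
    assert set(df.columns) == {"time_s", "x_mm", "y_mm", "z_mm", "temp_C"}
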