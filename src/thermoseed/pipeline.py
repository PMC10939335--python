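"""Field -> loss -> heat -> thermometry pipeline for one scene placement."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import field as fld
from . import heat, loss, sar
from .scene import Scene
from .units import MU0


@dataclass
class SimulationResult:
    """Everything one heating run produces."""

    scene: Scene
    current_A: float
    field_map: fld.FieldMap
    homogeneity: fld.HomogeneityReport
    power_map: loss.PowerMap
    voxels: heat.VoxelScene
    history: heat.TemperatureHistory
    record: Optional[sar.TemperatureRecord]
    sar_result: Optional[sar.SARResult]

    @property
    def peak_volume_average(self) -> float:
        return float(heat.volume_average(self.history, "scaffold").max())


def run_simulation(scene: Scene, *, resolution: float = 2e-3, dt: float = 0.1,
                   bh_loop: Optional[loss.BHLoop] = None,
                   noise_sd: float = 0.0, seed: int = 0,
                   duration: Optional[float] = None,
                   store_every: float = 1.0,
                   sample: bool = True, window: float = 30.0,
                   convection: Optional[heat.ConvectionModel] = None,
                   method: str = "implicit") -> SimulationResult:
    """Run the full calorimetric simulation for one placement.

    Steps: calibrate the coil current to the target central flux density,
    superpose the Biot-Savart field on the voxel grid, convert the local
    drive amplitude to hysteresis power through the (amplitude-truncated)
    BH loop, add the induced-E eddy/dielectric background, integrate the
    heating/cooling transient, and read the virtual probes.

    ``duration`` overrides the exposure duration (e.g. heating-only runs
    in sweeps); ``noise_sd`` is the probe sensor noise (0 for noiseless
    records); ``convection`` activates the in-water natural-convection
    surrogate.
    """
    exposure = scene.exposure
    if duration is not None:
        exposure = replace(exposure, duration=duration,
                           field_off_time=min(exposure.field_off_time, duration))

    current = fld.calibrate_current(scene.coil, exposure.target_flux_density)
    coil = replace(scene.coil, current_amplitude=current,
                   frequency=exposure.frequency)

    voxels = heat.build_voxel_scene(scene, resolution)
    if convection is not None:
        voxels = heat.apply_water_convection(voxels, convection)
    fmap = fld.solenoid_field(coil, voxels.grid_axes)
    xi = fld.homogeneity(fmap, scene.scaffold)

    if bh_loop is None:
        scaff_mat = scene.materials["scaffold"]
        phantom_cp = (scene.materials.get("phantom").cp_J_per_gK
                      if "phantom" in scene.materials else 4.2)
        bh_loop = loss.calibrated_loop(
            drive_B=exposure.target_flux_density, frequency=exposure.frequency,
            scaffold_density=scaff_mat.density, scaffold_cp=scaff_mat.specific_heat,
            phantom_cp_J_per_gK=phantom_cp)

    h_amp = fmap.h_magnitude()
    scaff_mask = voxels.region_mask("scaffold")
    area_map = np.zeros_like(h_amp)
    area_map[scaff_mask] = loss.minor_loop_area(
        bh_loop, np.minimum(h_amp[scaff_mask], bh_loop.h_max))
    p_hyst = loss.hysteresis_power(exposure.frequency, area_map,
                                   scene.materials["scaffold"].density)

    e_map = fld.induced_efield(fmap)
    sigma_map = voxels.property_map("conductivity")
    p_eddy = loss.dielectric_eddy_power(e_map, sigma_map)
    density_map = voxels.property_map("density")
    power = loss.build_power_map(voxels.grid_axes, p_hyst, p_eddy, density_map)

    history = heat.solve_transient(voxels, power, exposure, dt=dt,
                                   store_times=np.arange(
                                       0.0, exposure.duration + 1e-9, store_every),
                                   method=method)

    record = None
    sar_result = None
    if sample:
        layout = sar.ProbeLayout()
        probe_names = list(layout.positions)
        if scene.phantom is None:
            probe_names = [p for p in probe_names if p != "O"]
        record = sar.sample_probes(
            history, layout, seed=seed, scaffold_center=scene.scaffold.center,
            noise_sd=noise_sd, probes=probe_names,
            metadata={"freq_hz": exposure.frequency,
                      "b0_mT": exposure.target_flux_density * 1e3,
                      "cp_J_per_gK": _phantom_cp(scene)})
        win = min(window, record.field_off_time)
        sar_result = sar.sar_average(record, specific_heat=_phantom_cp(scene),
                                     window=win)
    return SimulationResult(scene, current, fmap, xi, power, voxels, history,
                            record, sar_result)


def _phantom_cp(scene: Scene) -> float:
    mat = scene.materials.get("phantom")
    return mat.cp_J_per_gK if mat is not None else 4.2
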