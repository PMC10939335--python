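"""Transient heat conduction on a voxelized scaffold-phantom scene.

Finite-volume discretization on a uniform rectilinear grid: interface
conductances use the harmonic mean of the neighbouring voxel
conductivities; every solid face exposed to ambient air carries a Robin
(convective) condition, flux = h_a (T_surf - T_a), with the half-cell
conduction resistance in series.  The surrounding air is not meshed — its
only effect is the Robin exchange.  Volumetric sources (hysteresis +
eddy heating) are active while the field is on (t < t_off) and zero after.

Time integration is implicit backward-Euler with a fixed step (default
0.1 s), unconditionally stable so the step is independent of resolution;
an explicit forward-Euler mode with an automatic CFL-limited step is
available for cross-checks.

The in-water measurement environment replaces the (unresolved) natural-
convection term u . grad T by an effective-conductivity surrogate: water
voxels get k_eff = k_water * max(1, Nu), with the Nusselt number from an
enclosure correlation Nu = C Ra^n driven by the instantaneous scaffold-to-
water temperature difference and recomputed during the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .scene import ExposureConfig, MaterialProps, Scene

LABEL_AMBIENT, LABEL_SCAFFOLD, LABEL_PHANTOM = 0, 1, 2
_ROLE_OF_LABEL = {LABEL_SCAFFOLD: "scaffold", LABEL_PHANTOM: "phantom"}
GRAVITY = 9.81

#: thermophysical constants of water near room temperature used by the
#: natural-convection surrogate (thermal expansivity 1/K, kinematic
#: viscosity m^2/s, thermal diffusivity m^2/s)
WATER_BETA, WATER_NU, WATER_ALPHA = 2.07e-4, 1.0e-6, 1.43e-7


class ResolutionError(ValueError):
    """Grid resolution too coarse for the smallest region."""


class SolverError(RuntimeError):
    """Transient solve produced non-finite values."""


@dataclass(frozen=True)
class ConvectionModel:
    """Nusselt-correlation surrogate for natural convection in water.

    ``Nu = coefficient * Ra^exponent`` with the Rayleigh number built on
    the radial scaffold-phantom gap and the current scaffold-surface minus
    water-average temperature difference; the enhancement factor applied
    to the water conductivity is ``max(1, Nu)`` (clamped so the surrogate
    can only remove heat faster than pure conduction).
    """

    coefficient: float = 0.29
    exponent: float = 0.25
    gap: float = 2.5e-3
    update_interval: float = 5.0
    forced_factor: Optional[float] = None   # override for testing/reduction

    def enhancement(self, delta_T: float) -> float:
        if self.forced_factor is not None:
            return max(1.0, self.forced_factor)
        dT = max(delta_T, 0.0)
        ra = GRAVITY * WATER_BETA * dT * self.gap**3 / (WATER_NU * WATER_ALPHA)
        return max(1.0, self.coefficient * ra**self.exponent)


@dataclass(frozen=True)
class VoxelScene:
    """Voxelized scene: uniform grid, per-voxel region labels, materials."""

    grid_axes: tuple                 # voxel-centre coordinate vectors (m)
    labels: np.ndarray               # (nx, ny, nz) ints, 0 ambient
    materials: Mapping[str, MaterialProps]
    resolution: float
    convection: Optional[ConvectionModel] = None

    @property
    def shape(self):
        return self.labels.shape

    def property_map(self, attr: str) -> np.ndarray:
        out = np.zeros(self.labels.shape)
        for lab, role in _ROLE_OF_LABEL.items():
            if role in self.materials:
                out[self.labels == lab] = getattr(self.materials[role], attr)
        return out

    def region_mask(self, role: str) -> np.ndarray:
        lab = LABEL_SCAFFOLD if role == "scaffold" else LABEL_PHANTOM
        return self.labels == lab


def build_voxel_scene(scene: Scene, resolution: float) -> VoxelScene:
    """Voxelize the solid regions on a uniform grid of the given pitch.

    The grid spans the bounding box of the union of regions; voxels are
    labeled by the membership of their centre (scaffold wins over
    phantom).  Raises :class:`ResolutionError` when the pitch exceeds a
    quarter of the smallest cylinder dimension.
    """
    regions = scene.regions
    min_dim = min(min(r.diameter, r.height) for r in regions)
    if resolution > min_dim / 4.0 + 1e-12:
        raise ResolutionError(
            f"resolution {resolution * 1e3:.1f} mm too coarse for a "
            f"{min_dim * 1e3:.1f} mm region (need <= {min_dim / 4 * 1e3:.2f} mm)")
    los, his = zip(*(r.bounding_box() for r in regions))
    lo = np.min(np.array(los), axis=0)
    hi = np.max(np.array(his), axis=0)
    axes = []
    for d in range(3):
        n = max(int(np.round((hi[d] - lo[d]) / resolution)), 1)
        centre = 0.5 * (lo[d] + hi[d])
        axes.append(centre + (np.arange(n) - (n - 1) / 2.0) * resolution)
    x, y, z = axes
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    labels = np.zeros(X.shape, dtype=np.int8)
    phantom = scene.phantom
    if phantom is not None:
        labels[phantom.contains(pts).reshape(X.shape)] = LABEL_PHANTOM
    labels[scene.scaffold.contains(pts).reshape(X.shape)] = LABEL_SCAFFOLD
    return VoxelScene((x, y, z), labels, dict(scene.materials), resolution)


def apply_water_convection(voxels: VoxelScene,
                           enhancement_model: ConvectionModel | None = None) -> VoxelScene:
    """Attach the natural-convection surrogate to a water-phantom scene."""
    model = enhancement_model or ConvectionModel()
    return replace(voxels, convection=model)


@dataclass(frozen=True)
class TemperatureHistory:
    """Stored temperature fields (degC) at the requested times.

    ``fields`` has shape (n_times, nx, ny, nz) with NaN in ambient voxels.
    """

    times: np.ndarray
    fields: np.ndarray
    grid_axes: tuple
    labels: np.ndarray
    field_off_time: float

    def peak_time_index(self) -> int:
        return int(np.nanargmax([np.nanmean(f) for f in self.fields]))


def _assemble(voxels: VoxelScene, h_robin: float, k_map: np.ndarray):
    """Sparse conduction operator over solid voxels.

    Returns (L, robin_diag, solid_index) where L T gives the net outflow
    (W/K times T) for conduction between solid voxels, robin_diag the
    boundary conductance to ambient per solid voxel (W/K).
    """
    labels = voxels.labels
    nx, ny, nz = labels.shape
    dx = voxels.resolution
    area = dx * dx
    solid = labels.ravel() > 0
    n_solid = int(solid.sum())
    index = -np.ones(labels.size, dtype=np.int64)
    index[solid] = np.arange(n_solid)

    k_flat = k_map.ravel()
    rows, cols, vals = [], [], []
    diag = np.zeros(n_solid)
    robin = np.zeros(n_solid)

    strides = [ny * nz, nz, 1]
    shape3 = (nx, ny, nz)
    lin = np.arange(labels.size).reshape(shape3)
    for d, stride in enumerate(strides):
        # neighbour pairs along axis d
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[d] = slice(0, shape3[d] - 1)
        sl_hi[d] = slice(1, shape3[d])
        a = lin[tuple(sl_lo)].ravel()
        b = lin[tuple(sl_hi)].ravel()
        both = solid[a] & solid[b]
        ia, ib = index[a[both]], index[b[both]]
        ka, kb = k_flat[a[both]], k_flat[b[both]]
        g = area / (dx / (2 * ka) + dx / (2 * kb))
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-g, -g])
        np.add.at(diag, ia, g)
        np.add.at(diag, ib, g)
        # solid face against ambient voxel -> Robin
        for s_face, s_amb in ((a, b), (b, a)):
            bmask = solid[s_face] & ~solid[s_amb]
            if h_robin > 0 and bmask.any():
                i = index[s_face[bmask]]
                ki = k_flat[s_face[bmask]]
                u = area / (dx / (2 * ki) + 1.0 / h_robin)
                np.add.at(robin, i, u)
    # domain boundary faces
    if h_robin > 0:
        for d in range(3):
            for side in (0, -1):
                sl = [slice(None)] * 3
                sl[d] = side
                face = lin[tuple(sl)].ravel()
                fmask = solid[face]
                i = index[face[fmask]]
                ki = k_flat[face[fmask]]
                u = area / (dx / (2 * ki) + 1.0 / h_robin)
                np.add.at(robin, i, u)

    rows = np.concatenate(rows) if rows else np.zeros(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    vals = np.concatenate(vals) if vals else np.zeros(0)
    L = sp.coo_matrix((np.concatenate([vals, diag]),
                       (np.concatenate([rows, np.arange(n_solid)]),
                        np.concatenate([cols, np.arange(n_solid)]))),
                      shape=(n_solid, n_solid)).tocsc()
    return L, robin, index


def _surface_mask(labels: np.ndarray, lab: int) -> np.ndarray:
    """Voxels of a region with at least one face to a different label or
    the domain boundary."""
    region = labels == lab
    padded = np.pad(region, 1, constant_values=False)
    interior = np.ones_like(region)
    for d in range(3):
        lo = np.roll(padded, 1, axis=d)[1:-1, 1:-1, 1:-1]
        hi = np.roll(padded, -1, axis=d)[1:-1, 1:-1, 1:-1]
        interior &= lo & hi
    return region & ~interior


def solve_transient(voxels: VoxelScene, power, exposure: ExposureConfig,
                    store_times=None, dt: float = 0.1,
                    method: str = "implicit") -> TemperatureHistory:
    """Integrate the heating/cooling transient.

    ``power`` is a PowerMap (or bare volumetric array, W/m^3)
    co-registered with the voxel grid; sources are on for
    t < ``exposure.field_off_time`` and off after.  The initial condition
    is uniform ambient temperature (thermal equilibrium at t = 0).
    """
    vol_power = getattr(power, "volumetric_power", power)
    vol_power = np.asarray(vol_power, dtype=float)
    if vol_power.shape != voxels.shape:
        raise ValueError("power map not co-registered with the voxel grid")

    labels = voxels.labels
    solid = labels.ravel() > 0
    n_solid = int(solid.sum())
    dx = voxels.resolution
    vcell = dx**3

    rho_cp = voxels.property_map("volumetric_heat_capacity").ravel()[solid]
    M = rho_cp * vcell                          # J/K per voxel
    S_on = vol_power.ravel()[solid] * vcell     # W per voxel
    Ta = exposure.ambient_temperature
    h = exposure.convective_coeff_air
    t_end = exposure.duration
    t_off = exposure.field_off_time

    if store_times is None:
        store_times = np.arange(0.0, t_end + 1e-9, 1.0)
    store_times = np.asarray(store_times, dtype=float)

    k_base = voxels.property_map("thermal_conductivity")
    conv = voxels.convection
    water_mask3 = (labels == LABEL_PHANTOM) if conv is not None else None
    scaff_surf = _surface_mask(labels, LABEL_SCAFFOLD).ravel()[solid]
    water_flat = water_mask3.ravel()[solid] if conv is not None else None

    def build(factor: float):
        k_map = k_base.copy()
        if conv is not None and factor != 1.0:
            k_map[water_mask3] *= factor
        L, robin, index = _assemble(voxels, h, k_map)
        return L, robin, index

    factor = 1.0
    if conv is not None:
        factor = conv.enhancement(0.0)
    L, robin, index = build(factor)
    A_diag_robin = robin

    T = np.full(n_solid, Ta)
    n_steps = int(np.round(t_end / dt))
    stored = np.full((len(store_times), *labels.shape), np.nan)
    store_idx = 0

    def maybe_store(t_now, T_now):
        nonlocal store_idx
        while store_idx < len(store_times) and store_times[store_idx] <= t_now + dt * 1e-6:
            full = np.full(labels.size, np.nan)
            full[solid] = T_now
            stored[store_idx] = full.reshape(labels.shape)
            store_idx += 1

    if method == "explicit":
        k_max = max(m.thermal_conductivity for m in voxels.materials.values())
        rc_min = min(m.volumetric_heat_capacity for m in voxels.materials.values())
        dt_cfl = 0.9 * rc_min * dx**2 / (6.0 * k_max)
        dt_e = min(dt, dt_cfl)
        n_steps = int(np.ceil(t_end / dt_e))
        dt_e = t_end / n_steps
        maybe_store(0.0, T)
        t = 0.0
        for _ in range(n_steps):
            S = S_on if t < t_off - 1e-9 else 0.0
            rhs = -(L @ T) - A_diag_robin * (T - Ta) + S
            T = T + dt_e * rhs / M
            t += dt_e
            if not np.all(np.isfinite(T)):
                raise SolverError(f"explicit step diverged at t = {t:.2f} s")
            maybe_store(t, T)
        return TemperatureHistory(store_times, stored, voxels.grid_axes,
                                  labels, t_off)

    # implicit backward-Euler
    def factorize(Lm, robin_v):
        A = (sp.diags(M / dt) + Lm + sp.diags(robin_v)).tocsc()
        return splu(A)

    lu = factorize(L, robin)
    maybe_store(0.0, T)
    t = 0.0
    next_update = conv.update_interval if conv is not None else np.inf
    for _ in range(n_steps):
        S = S_on if t < t_off - 1e-9 else 0.0
        b = M / dt * T + S + robin * Ta
        T = lu.solve(b)
        t += dt
        if not np.all(np.isfinite(T)):
            raise SolverError(f"implicit step produced non-finite values at t = {t:.2f} s")
        maybe_store(t, T)
        if conv is not None and t >= next_update - 1e-9:
            next_update += conv.update_interval
            dT = float(T[scaff_surf].mean() - T[water_flat].mean())
            new_factor = conv.enhancement(dT)
            if abs(new_factor - factor) > 0.01:
                factor = new_factor
                L, robin, _ = build(factor)
                lu = factorize(L, robin)
    return TemperatureHistory(store_times, stored, voxels.grid_axes, labels, t_off)


def _region_label(region) -> int:
    if isinstance(region, str):
        return LABEL_SCAFFOLD if region == "scaffold" else LABEL_PHANTOM
    return LABEL_SCAFFOLD if region.role_label == "scaffold" else LABEL_PHANTOM


def volume_average(history: TemperatureHistory, region) -> pd.Series:
    """Arithmetic mean temperature over a region's voxels per stored time."""
    mask = history.labels == _region_label(region)
    if not mask.any():
        raise ValueError("region does not overlap the grid")
    vals = history.fields[:, mask].mean(axis=1)
    return pd.Series(vals, index=pd.Index(history.times, name="time_s"),
                     name="volume_avg_C")


def surface_average(history: TemperatureHistory, region) -> pd.Series:
    """Mean over a region's boundary voxels — the virtual IR-camera
    observable (an IR camera only sees the surface)."""
    lab = _region_label(region)
    mask = _surface_mask(history.labels, lab)
    if not mask.any():
        raise ValueError("region has no exterior faces on the grid")
    vals = history.fields[:, mask].mean(axis=1)
    return pd.Series(vals, index=pd.Index(history.times, name="time_s"),
                     name="surface_avg_C")


def history_to_csv(history: TemperatureHistory, path, times=None) -> None:
    """Export stored fields as tidy CSV (time_s, x_mm, y_mm, z_mm, temp_C)."""
    x, y, z = history.grid_axes
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    solid = history.labels > 0
    sel = history.times if times is None else np.asarray(times, dtype=float)
    frames = []
    for t in sel:
        i = int(np.argmin(np.abs(history.times - t)))
        f = history.fields[i]
        frames.append(pd.DataFrame({
            "time_s": history.times[i],
            "x_mm": X[solid] * 1e3, "y_mm": Y[solid] * 1e3, "z_mm": Z[solid] * 1e3,
            "temp_C": f[solid],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
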