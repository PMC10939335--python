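"""Magnetostatic field of the excitation solenoid and pickup-coil formulas.

The AC excitation is quasi-static at 400 kHz on cm scales, so the flux
density *amplitude* map is the static Biot-Savart field of the winding,
evaluated in free space: the dilute scaffold's permeability perturbation is
neglected (its nonlinear BH response enters only through the loss model).
Each turn is a circular filament whose field has the standard closed form
in complete elliptic integrals; the solenoid is their superposition.

Conventions: field "amplitude" is the sinusoid *peak* (not RMS) everywhere
in this package; H = B / mu0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import ellipe, ellipk

from .scene import CoilSpec, CylinderRegion, ProbeCoilSpec
from .units import MU0


class SingularityError(ValueError):
    """Requested field evaluation lies on (or numerically at) a filament."""


@dataclass(frozen=True)
class FieldMap:
    """Gridded flux-density vector amplitude on a rectilinear grid.

    ``flux_density`` has shape (nx, ny, nz, 3) in tesla (peak amplitude).
    """

    grid_axes: tuple   # (x, y, z) monotone coordinate vectors, metres
    flux_density: np.ndarray
    frequency: float

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.flux_density, axis=-1)

    def h_magnitude(self) -> np.ndarray:
        """|H| in A/m."""
        return self.magnitude() / MU0

    def save(self, path) -> None:
        x, y, z = self.grid_axes
        np.savez(path, x=x, y=y, z=z, flux_density=self.flux_density,
                 frequency=np.asarray(self.frequency))

    @classmethod
    def load(cls, path) -> "FieldMap":
        with np.load(path) as d:
            return cls((d["x"], d["y"], d["z"]), d["flux_density"],
                       float(d["frequency"]))


@dataclass(frozen=True)
class HomogeneityReport:
    """Mean/std of |H| over a region and their ratio xi (dimensionless)."""

    mean_field: float   # A/m
    std_field: float    # A/m
    xi: float
    uniform: bool = False
    n_nodes: int = 0


def loop_field(loop_radius: float, loop_z: float, current: float, points) -> np.ndarray:
    """Flux density of a circular current loop at arbitrary points.

    Exact closed form (axial + radial components) via complete elliptic
    integrals; the loop lies in the plane z = ``loop_z``, centred on the z
    axis, with radius ``loop_radius`` and current ``current``.

    Parameters are SI; returns an array of B vectors (T) matching the
    shape of ``points`` (last axis 3).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    p = np.atleast_2d(pts)
    x, y, zz = p[..., 0], p[..., 1], p[..., 2] - loop_z
    rho = np.hypot(x, y)
    a = float(loop_radius)

    dist2 = (rho - a) ** 2 + zz**2
    if np.any(dist2 < (1e-6 * a) ** 2):
        raise SingularityError("field point coincides with the loop filament")

    denom_plus = (a + rho) ** 2 + zz**2
    m = 4.0 * a * rho / denom_plus
    K = ellipk(m)
    E = ellipe(m)
    pref = MU0 * current / (2.0 * np.pi * np.sqrt(denom_plus))
    denom_minus = (a - rho) ** 2 + zz**2
    Bz = pref * (K + (a**2 - rho**2 - zz**2) / denom_minus * E)
    with np.errstate(divide="ignore", invalid="ignore"):
        Brho = pref * zz / rho * (-K + (a**2 + rho**2 + zz**2) / denom_minus * E)
        cos_phi = np.where(rho > 0, x / np.where(rho > 0, rho, 1.0), 0.0)
        sin_phi = np.where(rho > 0, y / np.where(rho > 0, rho, 1.0), 0.0)
    Brho = np.where(rho > 0, Brho, 0.0)
    B = np.stack([Brho * cos_phi, Brho * sin_phi, Bz], axis=-1)
    return B[0] if single else B


def solenoid_field(coil: CoilSpec, grid_axes) -> FieldMap:
    """Superpose the coil's turn filaments on a rectilinear grid.

    Linear in ``coil.current_amplitude``.  Raises ``SingularityError`` if a
    grid node falls on a filament.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in grid_axes)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    B = np.zeros_like(pts)
    for z0 in coil.turn_positions():
        B += loop_field(coil.filament_radius, z0, coil.current_amplitude, pts)
    return FieldMap((x, y, z), B, coil.frequency)


def field_at_points(coil: CoilSpec, points) -> np.ndarray:
    """B vectors of the full coil at arbitrary points (helper)."""
    pts = np.asarray(points, dtype=float)
    B = np.zeros(np.shape(pts))
    for z0 in coil.turn_positions():
        B = B + loop_field(coil.filament_radius, z0, coil.current_amplitude, pts)
    return B


def calibrate_current(coil: CoilSpec, target_B0: float) -> float:
    """Current amplitude giving |B| = ``target_B0`` at the coil centre.

    Exact by linearity: a single unit-current evaluation and a division.
    """
    if target_B0 < 0:
        raise ValueError("target_B0 must be non-negative")
    from dataclasses import replace

    unit = replace(coil, current_amplitude=1.0)
    b0 = np.linalg.norm(field_at_points(unit, np.zeros(3)))
    return target_B0 / b0


def homogeneity(field: FieldMap, region: CylinderRegion) -> HomogeneityReport:
    """Field-homogeneity metric xi = mean(|H|) / std(|H|) over a region.

    The statistic is taken over grid nodes inside the region using the
    sample (n-1) standard deviation of the |H| magnitude.  A perfectly
    uniform field has zero spread; that degenerate case is reported as
    xi = +inf with ``uniform=True`` rather than raising.
    """
    x, y, z = field.grid_axes
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    mask = region.contains(pts).reshape(X.shape)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("region must overlap the grid with at least 2 nodes")
    h = field.h_magnitude()[mask]
    mean = float(h.mean())
    std = float(h.std(ddof=1))
    if std == 0.0:
        return HomogeneityReport(mean, 0.0, np.inf, uniform=True, n_nodes=n)
    return HomogeneityReport(mean, std, mean / std, n_nodes=n)


def induced_efield(field: FieldMap) -> np.ndarray:
    """Azimuthal induced-E amplitude |E_phi| (V/m) on the field's grid.

    From Faraday's law in the axisymmetric quasi-static limit,
    ``|E_phi(r, z)| = omega * |Phi(r, z)| / (2 pi r)`` with Phi the flux of
    B_z through the disc of radius r at height z (r measured from the coil
    axis, which must lie inside the grid's xy footprint).  The radial B_z
    profile of each z-slice is sampled along the ray towards the farthest
    grid corner (legitimate for an axisymmetric source) and the flux
    integral is taken with the trapezoidal rule.  ``E_phi -> 0`` as
    ``r -> 0`` by construction.
    """
    x, y, z = field.grid_axes
    if not (x.min() <= 0.0 <= x.max() and y.min() <= 0.0 <= y.max()):
        raise ValueError("grid must contain the coil axis (x = y = 0)")
    omega = 2.0 * np.pi * field.frequency
    X, Y = np.meshgrid(x, y, indexing="ij")
    r_nodes = np.hypot(X, Y)

    # Ray towards the farthest corner stays inside the (convex) grid box.
    corner = np.array([x[np.argmax(np.abs(x))], y[np.argmax(np.abs(y))]])
    r_corner = np.hypot(*corner)
    u = corner / r_corner
    n_r = 4 * max(len(x), len(y)) + 1
    r_s = np.linspace(0.0, r_corner, n_r)
    sample_xy = np.outer(r_s, u)

    E = np.zeros((len(x), len(y), len(z)))
    for j in range(len(z)):
        bz_slice = field.flux_density[:, :, j, 2]
        interp = RegularGridInterpolator((x, y), bz_slice, bounds_error=False,
                                         fill_value=None)
        bz_r = interp(sample_xy)
        # trapezoid of integrand f(r) = 2 pi r Bz(r)
        integrand = 2.0 * np.pi * r_s * bz_r
        flux = np.concatenate([[0.0],
                               np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                                         * np.diff(r_s))])
        with np.errstate(divide="ignore", invalid="ignore"):
            e_r = omega * np.abs(flux) / (2.0 * np.pi * r_s)
        e_r[0] = 0.0
        E[:, :, j] = np.interp(r_nodes.ravel(), r_s, e_r).reshape(r_nodes.shape)
    return E


def emf_to_field(peak_to_peak_emf: float, frequency: float,
                 probe: ProbeCoilSpec) -> float:
    """Convert a pickup-coil peak-to-peak EMF to the H amplitude (A/m).

    Faraday's law for a sinusoidal field threading an n-turn loop of
    diameter d: ``V_pp = 2 n omega mu0 H pi (d/2)^2``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * frequency
    area = np.pi * (probe.diameter / 2.0) ** 2
    return peak_to_peak_emf / (2.0 * probe.n_turns * omega * MU0 * area)


def field_to_emf(h_amplitude: float, frequency: float,
                 probe: ProbeCoilSpec) -> float:
    """Inverse of :func:`emf_to_field`: peak-to-peak EMF for a given H."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * frequency
    area = np.pi * (probe.diameter / 2.0) ** 2
    return 2.0 * probe.n_turns * omega * MU0 * area * h_amplitude


def h_times_f(flux_density: float, frequency: float) -> float:
    """Safety/dose product |H| x f (A m^-1 s^-1) from peak B and frequency."""
    return flux_density / MU0 * frequency
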