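"""Hysteresis loops and conversion of field amplitude into heating power.

A ferromagnetic scaffold driven around a quasi-static BH loop dissipates,
per cycle and per unit volume, the loop area A_hyst = \\oint H dB (J/m^3);
at drive frequency f the volumetric hysteresis power is P_m = f * A_hyst.
Where the drive amplitude is below the loop's span, the loop is truncated
to the local amplitude (branches clipped to +-H_a and closed by the
vertical switching segments), which makes the per-cycle area a continuous,
non-decreasing function of amplitude that reduces to the full loop area at
full drive.  Eddy/dielectric background heating in conductive media is
P_e = sigma |E|^2 / 2 for peak-amplitude E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .units import MU0


class MalformedLoopError(ValueError):
    """BH loop branches do not close or cross."""


@dataclass(frozen=True)
class BHLoop:
    """Sampled hysteresis loop of the scaffold composite.

    Both branches are stored over ascending H on [-H_max, +H_max]; the
    descending (upper) branch must sit at or above the ascending (lower)
    branch everywhere inside, and the two must meet at the tips.
    ``mass_density`` (kg/m^3) converts volumetric loop area to the
    mass-specific value.
    """

    h_asc: np.ndarray
    b_asc: np.ndarray
    h_desc: np.ndarray
    b_desc: np.ndarray
    mass_density: float = 2700.0
    params: Optional[dict] = None

    def __post_init__(self):
        for name in ("h_asc", "b_asc", "h_desc", "b_desc"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        b_scale = max(np.abs(self.b_asc).max(), np.abs(self.b_desc).max(), 1e-300)
        tol = 1e-6 * b_scale
        if (abs(self.b_asc[0] - self.b_desc[0]) > tol
                or abs(self.b_asc[-1] - self.b_desc[-1]) > tol):
            raise MalformedLoopError("branches do not close at +-H_max")
        if not (np.all(np.diff(self.h_asc) > 0) and np.all(np.diff(self.h_desc) > 0)):
            raise MalformedLoopError("branch H samples must be strictly increasing")
        upper = np.interp(self.h_asc, self.h_desc, self.b_desc)
        if np.any(upper < self.b_asc - 1e-9 * b_scale):
            raise MalformedLoopError("descending branch dips below ascending branch")

    @property
    def h_max(self) -> float:
        return float(self.h_asc[-1])

    def branch_gap(self, h) -> np.ndarray:
        """Delta-B between descending and ascending branch at field H."""
        h = np.asarray(h, dtype=float)
        upper = np.interp(h, self.h_desc, self.b_desc)
        lower = np.interp(h, self.h_asc, self.b_asc)
        return np.clip(upper - lower, 0.0, None)


def synth_bh_loop(saturation_B: float, coercivity_H: float, branch_width: float,
                  H_max: float, n_samples: int = 1001,
                  mass_density: float = 2700.0) -> BHLoop:
    """Parametric sigmoid loop with finite coercivity.

    Branches ``B_desc(H) = Bs tanh((H + Hc)/w)`` and
    ``B_asc(H) = Bs tanh((H - Hc)/w)``, densely sampled on [-H_max, H_max]
    and forced closed at the tips (the tanh branches converge there; the
    residual gap is split symmetrically).  The construction is odd-symmetric
    across branches: B_desc(-H) = -B_asc(H).
    """
    if min(saturation_B, coercivity_H, branch_width, H_max) <= 0:
        raise ValueError("all loop parameters must be positive")
    if H_max <= coercivity_H:
        raise ValueError("H_max must exceed the coercivity")
    h = np.linspace(-H_max, H_max, int(n_samples))
    b_desc = saturation_B * np.tanh((h + coercivity_H) / branch_width)
    b_asc = saturation_B * np.tanh((h - coercivity_H) / branch_width)
    # close the tips exactly
    for i in (0, -1):
        mid = 0.5 * (b_desc[i] + b_asc[i])
        b_desc[i] = b_asc[i] = mid
    return BHLoop(h, b_asc, h.copy(), b_desc, mass_density=mass_density,
                  params={"saturation_B": saturation_B, "coercivity_H": coercivity_H,
                          "branch_width": branch_width, "H_max": H_max})


def loop_area(loop: BHLoop):
    """Per-cycle loop area: volumetric (J/m^3) and mass-specific (J/kg).

    Computed as the shoelace integral \\oint H dB around the closed polygon
    (ascending branch up, descending branch back).
    """
    h = np.concatenate([loop.h_asc, loop.h_desc[::-1]])
    b = np.concatenate([loop.b_asc, loop.b_desc[::-1]])
    area = 0.5 * abs(np.sum(h * np.roll(b, -1) - np.roll(h, -1) * b))
    return area, area / loop.mass_density


def minor_loop_area(loop: BHLoop, local_H_amplitude) -> np.ndarray:
    """Per-cycle area (J/m^3) of the loop truncated to drive +-H_a.

    Equal to the integral of the branch gap Delta-B(H) over [-H_a, +H_a]
    (the vertical closure segments at +-H_a bound the truncated region).
    Continuous, zero at zero amplitude, non-decreasing, and exactly the
    full loop area at H_a = H_max.  Amplitudes above H_max are clamped with
    a warning.
    """
    ha = np.asarray(local_H_amplitude, dtype=float)
    scalar = ha.ndim == 0
    ha = np.atleast_1d(ha)
    if np.any(ha < 0):
        raise ValueError("amplitude must be non-negative")
    if np.any(ha > loop.h_max * (1 + 1e-12)):
        warnings.warn("drive amplitude exceeds loop H_max; clamping", stacklevel=2)
        ha = np.minimum(ha, loop.h_max)
    grid, cumarea = _gap_cumulative(loop)
    area = np.interp(ha, grid, cumarea)
    return float(area[0]) if scalar else area


def _gap_cumulative(loop: BHLoop):
    """Cumulative integral A(H_a) = int_{-H_a}^{H_a} Delta-B dH on a grid."""
    n = max(len(loop.h_asc), len(loop.h_desc), 1024)
    grid = np.linspace(0.0, loop.h_max, n)
    # symmetric integral: integrate gap on [-Ha, Ha] as sum of both halves
    gap_pos = loop.branch_gap(grid)
    gap_neg = loop.branch_gap(-grid)
    integrand = gap_pos + gap_neg
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                                           * np.diff(grid))])
    return grid, cum


@dataclass(frozen=True)
class PowerMap:
    """Volumetric and mass-specific deposited power on the thermal grid.

    ``components`` holds the separate hysteresis and dielectric/eddy maps
    (W/m^3); ``volumetric_power`` is their sum and ``mass_power`` the sum
    divided by the local mass density.
    """

    grid_axes: tuple
    volumetric_power: np.ndarray   # W/m^3
    mass_power: np.ndarray         # W/kg
    components: Mapping[str, np.ndarray] = field(default_factory=dict)

    def total_power(self) -> float:
        """Volume integral of the deposited power (W); uniform grids."""
        x, y, z = self.grid_axes
        dx = np.diff(x).mean() if len(x) > 1 else 1.0
        dy = np.diff(y).mean() if len(y) > 1 else 1.0
        dz = np.diff(z).mean() if len(z) > 1 else 1.0
        return float(self.volumetric_power.sum() * dx * dy * dz)


def hysteresis_power(frequency: float, area_map: np.ndarray,
                     density: np.ndarray | float) -> np.ndarray:
    """Volumetric hysteresis power P_m = f * A_hyst per node (W/m^3).

    ``area_map`` carries the per-cycle loop area (J/m^3) at each node's
    local drive amplitude — zero outside the scaffold.  ``density`` is
    only used by callers for the mass-specific map; the volumetric power
    is linear in frequency.
    """
    if frequency < 0:
        raise ValueError("frequency must be non-negative")
    return frequency * np.asarray(area_map, dtype=float)


def dielectric_eddy_power(e_map: np.ndarray, conductivity_map: np.ndarray) -> np.ndarray:
    """Background Joule heating P_e = sigma |E|^2 / 2 per node (W/m^3).

    ``e_map`` is the peak-amplitude azimuthal induced field (V/m);
    ``conductivity_map`` the local sigma (S/m), zero wherever there is no
    conductive material.
    """
    return 0.5 * np.asarray(conductivity_map, dtype=float) * np.asarray(e_map) ** 2


def build_power_map(grid_axes, hyst: np.ndarray, eddy: np.ndarray,
                    density_map: np.ndarray) -> PowerMap:
    total = hyst + eddy
    with np.errstate(divide="ignore", invalid="ignore"):
        mass = np.where(density_map > 0, total / np.where(density_map > 0, density_map, 1.0), 0.0)
    return PowerMap(grid_axes, total, mass, {"hysteresis": hyst, "dielectric_eddy": eddy})


def calibrated_loop(*, target_sar: float = 1.0, drive_B: float = 30e-3,
                    frequency: float = 400e3,
                    scaffold_density: float = 2700.0,
                    scaffold_cp: float = 1200.0,
                    phantom_cp_J_per_gK: float = 4.2,
                    coercivity_H: float = 30e3, branch_width: float = 5e3,
                    H_max: float = 8e5) -> BHLoop:
    """Default synthetic loop, calibrated to the bench SAR scale.

    The loop's B-scale is set so that, at the nominal centre drive
    amplitude H0 = drive_B / mu0, the adiabatic initial heating slope at
    the scaffold centre maps through the calorimetric SAR definition
    (agar C_p times slope) to ``target_sar`` W/g.  Shape parameters put the
    operating amplitude below the coercivity, where the truncated-loop
    area grows linearly with amplitude (constant branch gap) — the regime
    in which deposited power tracks the local field amplitude.

    The resulting saturation induction is an *effective* value: it absorbs
    the narrowing of real minor loops relative to the truncated major loop
    and should not be read as the composite's physical magnetization.
    """
    h0 = drive_B / MU0
    slope = target_sar / phantom_cp_J_per_gK            # K/s
    p_v = slope * scaffold_density * scaffold_cp        # W/m^3
    area_needed = p_v / frequency                       # J/m^3 per cycle
    ref = synth_bh_loop(1.0, coercivity_H, branch_width, H_max,
                        mass_density=scaffold_density)
    unit_area = minor_loop_area(ref, h0)
    bs = area_needed / unit_area
    return synth_bh_loop(bs, coercivity_H, branch_width, H_max,
                         mass_density=scaffold_density)


# ---------------------------------------------------------------------------
# CSV schema: columns H_A_per_m, B_T, branch in {asc, desc}

def loop_to_csv(loop: BHLoop, path) -> None:
    frames = []
    for branch, h, b in (("asc", loop.h_asc, loop.b_asc),
                         ("desc", loop.h_desc, loop.b_desc)):
        frames.append(pd.DataFrame({"H_A_per_m": h, "B_T": b, "branch": branch}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def loop_from_csv(path, mass_density: float = 2700.0) -> BHLoop:
    df = pd.read_csv(path)
    required = {"H_A_per_m", "B_T", "branch"}
    if not required.issubset(df.columns):
        raise MalformedLoopError(f"BH CSV needs columns {sorted(required)}")
    asc = df[df.branch == "asc"].sort_values("H_A_per_m")
    desc = df[df.branch == "desc"].sort_values("H_A_per_m")
    if asc.empty or desc.empty:
        raise MalformedLoopError("BH CSV must contain both asc and desc branches")
    return BHLoop(asc.H_A_per_m.to_numpy(), asc.B_T.to_numpy(),
                  desc.H_A_per_m.to_numpy(), desc.B_T.to_numpy(),
                  mass_density=mass_density)
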