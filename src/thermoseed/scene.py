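"""Physical scene: induction coil, scaffold, phantom, materials, exposure.

The scene is the immutable configuration shared by the field, loss and heat
stages.  Coordinates are right-handed Cartesian with z along the coil axis
and the origin at the coil's geometric centre; all region offsets are
measured from that origin.  Internally everything is SI.

The default scene mirrors a bench-top induction-heating test of a
ferromagnetic iron-polymer scaffold (a 2 cm x 2 cm cylinder) embedded in a
cylindrical agar phantom (2.5 cm x 4 cm), driven by a single-layer 8-turn
solenoid at 400 kHz with 30 mT peak flux density at the coil centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import yaml

from .units import parse_length


class GeometryError(ValueError):
    """Raised for impossible or inconsistent scene geometry."""


class ConfigurationError(ValueError):
    """Raised for invalid or incomplete scene configuration."""


@dataclass(frozen=True)
class CoilSpec:
    """Single-layer excitation solenoid.

    The paper-style 8-turn head does not come with published bore/height;
    the defaults (25 mm inner radius, 8 turns evenly spaced over 48 mm,
    2 mm wire radius) are typical of this class of induction coil and are
    fully configurable.  ``current_amplitude`` is the *peak* of the
    sinusoidal excitation.
    """

    n_turns: int = 8
    inner_radius: float = 25e-3
    axial_pitch: float = 48e-3 / 7.0
    wire_radius: float = 2e-3
    current_amplitude: float = 1.0
    frequency: float = 400e3

    def __post_init__(self):
        if self.n_turns < 1:
            raise ConfigurationError("coil needs at least one turn")
        if self.inner_radius <= 0:
            raise ConfigurationError("coil inner_radius must be positive")
        if self.n_turns > 1 and self.axial_pitch <= 2 * self.wire_radius:
            raise ConfigurationError("axial_pitch must exceed the wire diameter")
        if self.frequency <= 0:
            raise ConfigurationError("coil frequency must be positive")

    @property
    def filament_radius(self) -> float:
        """Radius of the equivalent current filament (wire centre)."""
        return self.inner_radius + self.wire_radius

    @property
    def height(self) -> float:
        """Overall coil height h_C (outer wire extent)."""
        return (self.n_turns - 1) * self.axial_pitch + 2 * self.wire_radius

    def turn_positions(self) -> np.ndarray:
        """Axial stations of the turns, symmetric about z = 0."""
        n = self.n_turns
        return (np.arange(n) - (n - 1) / 2.0) * self.axial_pitch


@dataclass(frozen=True)
class ProbeCoilSpec:
    """Small pickup coil used to measure the applied field via Faraday's law.

    The bench probe is 7.3 mm in diameter with 2.5 turns; its physical
    height (3 cm) plays no role in the single-flux-linkage Faraday formula
    and is kept as metadata.
    """

    diameter: float = 7.3e-3
    n_turns: float = 2.5
    height: float = 30e-3

    def __post_init__(self):
        if self.diameter <= 0 or self.n_turns <= 0:
            raise ConfigurationError("probe coil diameter and n_turns must be positive")


@dataclass(frozen=True)
class CylinderRegion:
    """Axis-aligned cylinder (axis parallel to z) with a role label."""

    diameter: float
    height: float
    center_offset: tuple = (0.0, 0.0, 0.0)
    role_label: str = "scaffold"

    def __post_init__(self):
        if self.diameter <= 0 or self.height <= 0:
            raise GeometryError(f"{self.role_label}: diameter and height must be positive")
        object.__setattr__(self, "center_offset", tuple(float(v) for v in self.center_offset))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.center_offset, dtype=float)

    def contains(self, points: np.ndarray, *, tol: float = 1e-12) -> np.ndarray:
        """Vectorized membership test (boundary counts as inside)."""
        p = np.atleast_2d(points) - self.center
        r = np.hypot(p[..., 0], p[..., 1])
        return (r <= self.radius + tol) & (np.abs(p[..., 2]) <= self.height / 2.0 + tol)

    def bounding_box(self):
        c = self.center
        lo = c - np.array([self.radius, self.radius, self.height / 2.0])
        hi = c + np.array([self.radius, self.radius, self.height / 2.0])
        return lo, hi

    def shifted(self, offset) -> "CylinderRegion":
        off = self.center + np.asarray(offset, dtype=float)
        return replace(self, center_offset=tuple(off))

    def volume(self) -> float:
        return np.pi * self.radius**2 * self.height


@dataclass(frozen=True)
class MaterialProps:
    """Electromagnetic and thermal bulk properties, stored in SI.

    ``specific_heat`` is J/(kg K) and ``density`` kg/m^3 internally; use
    :meth:`from_table` to enter the tabulated J/(g K) and g/cm^3 values,
    which are converted exactly once here.
    """

    rel_permittivity: float
    conductivity: float          # S/m
    thermal_conductivity: float  # W/(m K)
    specific_heat: float         # J/(kg K)
    density: float               # kg/m^3

    def __post_init__(self):
        if self.conductivity < 0:
            raise ConfigurationError("conductivity must be non-negative")

    @classmethod
    def from_table(cls, eps_r, sigma, k, cp_J_per_gK, rho_g_per_cm3) -> "MaterialProps":
        return cls(eps_r, sigma, k, cp_J_per_gK * 1e3, rho_g_per_cm3 * 1e3)

    @property
    def cp_J_per_gK(self) -> float:
        return self.specific_heat / 1e3

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * C_p, J/(m^3 K)."""
        return self.density * self.specific_heat


# Tabulated bench materials.  Agar: tissue-mimicking phantom gel.
# IRON_PLA ("PP"): iron-microparticle-loaded PLA composite, the scaffold
# material.  Water values are standard distilled-water properties near room
# temperature (used by the in-water setup study).
AGAR = MaterialProps.from_table(70.0, 0.2, 0.48, 4.2, 1.0)
IRON_PLA = MaterialProps.from_table(3.0, 1e-5, 0.47, 1.2, 2.7)
PLA = MaterialProps.from_table(2.5, 1e-6, 0.29, 1.8, 0.9)
WATER = MaterialProps.from_table(78.0, 5.5e-6, 0.60, 4.186, 0.998)

MATERIAL_LIBRARY = {"agar": AGAR, "iron_pla": IRON_PLA, "pla": PLA, "water": WATER}


@dataclass(frozen=True)
class ExposureConfig:
    """Field drive and thermal boundary settings for one heating run.

    ``target_flux_density`` is the peak |B| at the coil centre the current
    is calibrated to; the field is on for ``field_off_time`` seconds out of
    ``duration``.  ``convective_coeff_air`` is the free-convection Robin
    coefficient h_a at solid-air interfaces (the cited source does not
    print it; 10 W/(m^2 K) is the standard free-convection-in-air value).
    """

    target_flux_density: float = 30e-3
    frequency: float = 400e3
    duration: float = 900.0
    field_off_time: float = 600.0
    ambient_temperature: float = 19.0
    convective_coeff_air: float = 10.0
    medium_mode: str = "agar"

    def __post_init__(self):
        if self.target_flux_density <= 0:
            raise ConfigurationError("target_flux_density must be positive")
        if not (0 < self.field_off_time <= self.duration):
            raise ConfigurationError("need 0 < field_off_time <= duration")
        if self.medium_mode not in ("agar", "air", "water"):
            raise ConfigurationError(f"unknown medium_mode {self.medium_mode!r}")


@dataclass(frozen=True)
class Scene:
    """Validated, immutable scene. Build through :func:`validate_scene`."""

    coil: CoilSpec
    regions: tuple
    materials: Mapping[str, MaterialProps]
    exposure: ExposureConfig = ExposureConfig()
    probe_coil: ProbeCoilSpec = ProbeCoilSpec()

    def region(self, role: str) -> Optional[CylinderRegion]:
        for r in self.regions:
            if r.role_label == role:
                return r
        return None

    @property
    def scaffold(self) -> CylinderRegion:
        return self.region("scaffold")

    @property
    def phantom(self) -> Optional[CylinderRegion]:
        return self.region("phantom")

    def shifted(self, offset) -> "Scene":
        """Rigidly translate scaffold and phantom together (the phantom
        carries the embedded scaffold, so misplacement moves both)."""
        return replace(self, regions=tuple(r.shifted(offset) for r in self.regions))


def _check_containment(scaffold: CylinderRegion, phantom: CylinderRegion):
    dc = scaffold.center - phantom.center
    radial = np.hypot(dc[0], dc[1])
    tol = 1e-9
    if radial + scaffold.radius > phantom.radius + tol:
        raise GeometryError(
            f"scaffold (radius {scaffold.radius * 1e3:.1f} mm) not radially contained "
            f"in phantom (radius {phantom.radius * 1e3:.1f} mm)"
        )
    if abs(dc[2]) + scaffold.height / 2 > phantom.height / 2 + tol:
        raise GeometryError("scaffold not axially contained in phantom")


def validate_scene(coil: CoilSpec, regions, materials,
                   exposure: ExposureConfig = ExposureConfig(),
                   probe_coil: ProbeCoilSpec = ProbeCoilSpec()) -> Scene:
    """Validate geometry/material consistency and freeze the scene.

    Exactly one scaffold region and at most one phantom region are allowed;
    when both are present the scaffold must be geometrically contained in
    the phantom (they may share a rigid offset).  Every region role needs
    material properties.
    """
    regions = tuple(regions)
    roles = [r.role_label for r in regions]
    if roles.count("scaffold") != 1:
        raise GeometryError("scene requires exactly one scaffold region")
    if roles.count("phantom") > 1:
        raise GeometryError("scene allows at most one phantom region")
    for r in regions:
        if r.role_label not in ("scaffold", "phantom"):
            raise GeometryError(f"unknown region role {r.role_label!r}")
        if r.role_label not in materials:
            raise ConfigurationError(f"missing material properties for role {r.role_label!r}")
    scaffold = next(r for r in regions if r.role_label == "scaffold")
    phantom = next((r for r in regions if r.role_label == "phantom"), None)
    if phantom is not None:
        _check_containment(scaffold, phantom)
    return Scene(coil=coil, regions=regions, materials=dict(materials),
                 exposure=exposure, probe_coil=probe_coil)


def default_scene(medium: str = "agar", *, exposure: ExposureConfig | None = None) -> Scene:
    """The calibrated reference scene.

    ``medium`` selects the measurement environment: ``"agar"`` (scaffold in
    an agar phantom, the recommended protocol), ``"air"`` (bare scaffold,
    IR-camera style setup) or ``"water"`` (phantom region filled with
    distilled water, optionally with the natural-convection surrogate).
    """
    scaffold = CylinderRegion(diameter=20e-3, height=20e-3, role_label="scaffold")
    if exposure is None:
        exposure = ExposureConfig(medium_mode=medium)
    elif exposure.medium_mode != medium:
        exposure = replace(exposure, medium_mode=medium)
    if medium == "air":
        return validate_scene(CoilSpec(), [scaffold], {"scaffold": IRON_PLA}, exposure)
    phantom = CylinderRegion(diameter=25e-3, height=40e-3, role_label="phantom")
    phantom_mat = WATER if medium == "water" else AGAR
    return validate_scene(CoilSpec(), [scaffold, phantom],
                          {"scaffold": IRON_PLA, "phantom": phantom_mat}, exposure)


# ---------------------------------------------------------------------------
# Config (YAML) serialization.  Lengths are written in mm; readers accept
# bare numbers (mm) or explicit unit suffixes.

def _region_to_config(r: CylinderRegion) -> dict:
    return {
        "diameter": f"{r.diameter * 1e3!r} mm",
        "height": f"{r.height * 1e3!r} mm",
        "center_offset": [f"{v * 1e3!r} mm" for v in r.center_offset],
    }


def _material_to_config(m: MaterialProps) -> dict:
    return {
        "rel_permittivity": m.rel_permittivity,
        "conductivity_S_per_m": m.conductivity,
        "thermal_conductivity_W_per_mK": m.thermal_conductivity,
        "specific_heat_J_per_gK": m.cp_J_per_gK,
        "density_g_per_cm3": m.density / 1e3,
    }


def scene_to_config(scene: Scene) -> dict:
    cfg = {
        "coil": {
            "n_turns": scene.coil.n_turns,
            "inner_radius": f"{scene.coil.inner_radius * 1e3!r} mm",
            "axial_pitch": f"{scene.coil.axial_pitch * 1e3!r} mm",
            "wire_radius": f"{scene.coil.wire_radius * 1e3!r} mm",
            "current_amplitude_A": scene.coil.current_amplitude,
            "frequency_Hz": scene.coil.frequency,
        },
        "probe_coil": {
            "diameter": f"{scene.probe_coil.diameter * 1e3!r} mm",
            "n_turns": scene.probe_coil.n_turns,
            "height": f"{scene.probe_coil.height * 1e3!r} mm",
        },
        "scaffold": _region_to_config(scene.scaffold),
        "materials": {role: _material_to_config(m) for role, m in scene.materials.items()},
        "exposure": {
            "target_flux_density_mT": scene.exposure.target_flux_density * 1e3,
            "frequency_Hz": scene.exposure.frequency,
            "duration_s": scene.exposure.duration,
            "field_off_time_s": scene.exposure.field_off_time,
            "ambient_temperature_C": scene.exposure.ambient_temperature,
            "convective_coeff_air_W_per_m2K": scene.exposure.convective_coeff_air,
            "medium_mode": scene.exposure.medium_mode,
        },
    }
    if scene.phantom is not None:
        cfg["phantom"] = _region_to_config(scene.phantom)
    return cfg


def _region_from_config(cfg: dict, role: str) -> CylinderRegion:
    off = cfg.get("center_offset", (0.0, 0.0, 0.0))
    return CylinderRegion(
        diameter=parse_length(cfg["diameter"]),
        height=parse_length(cfg["height"]),
        center_offset=tuple(parse_length(v) for v in off),
        role_label=role,
    )


def _material_from_config(cfg: dict) -> MaterialProps:
    return MaterialProps.from_table(
        cfg["rel_permittivity"],
        cfg["conductivity_S_per_m"],
        cfg["thermal_conductivity_W_per_mK"],
        cfg["specific_heat_J_per_gK"],
        cfg["density_g_per_cm3"],
    )


def scene_from_config(cfg: dict) -> Scene:
    try:
        ccfg = cfg["coil"]
        coil = CoilSpec(
            n_turns=int(ccfg.get("n_turns", 8)),
            inner_radius=parse_length(ccfg.get("inner_radius", 25.0)),
            axial_pitch=parse_length(ccfg.get("axial_pitch", 48.0 / 7.0)),
            wire_radius=parse_length(ccfg.get("wire_radius", 2.0)),
            current_amplitude=float(ccfg.get("current_amplitude_A", 1.0)),
            frequency=float(ccfg.get("frequency_Hz", 400e3)),
        )
        pcfg = cfg.get("probe_coil", {})
        probe_coil = ProbeCoilSpec(
            diameter=parse_length(pcfg.get("diameter", 7.3)),
            n_turns=float(pcfg.get("n_turns", 2.5)),
            height=parse_length(pcfg.get("height", 30.0)),
        )
        regions = [_region_from_config(cfg["scaffold"], "scaffold")]
        if "phantom" in cfg:
            regions.append(_region_from_config(cfg["phantom"], "phantom"))
        materials = {role: _material_from_config(m) for role, m in cfg["materials"].items()}
        ecfg = cfg.get("exposure", {})
        exposure = ExposureConfig(
            target_flux_density=float(ecfg.get("target_flux_density_mT", 30.0)) * 1e-3,
            frequency=float(ecfg.get("frequency_Hz", 400e3)),
            duration=float(ecfg.get("duration_s", 900.0)),
            field_off_time=float(ecfg.get("field_off_time_s", 600.0)),
            ambient_temperature=float(ecfg.get("ambient_temperature_C", 19.0)),
            convective_coeff_air=float(ecfg.get("convective_coeff_air_W_per_m2K", 10.0)),
            medium_mode=ecfg.get("medium_mode", "agar"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing config field: {exc}") from exc
    return validate_scene(coil, regions, materials, exposure, probe_coil)


def save_scene(scene: Scene, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scene_to_config(scene), fh, sort_keys=False)


def load_scene(path) -> Scene:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return scene_from_config(cfg)
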