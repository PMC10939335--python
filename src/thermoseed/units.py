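"""Unit handling at the package boundary.

Everything inside the package is SI (m, s, kg, K offsets in degC, T, A/m).
User-facing configuration accepts lengths in mm by default, or any value
with an explicit unit suffix ("25 mm", "2 cm", "0.025 m").  Table-style
material properties (J/(g K), g/cm^3) are converted to SI exactly once,
in :func:`thermoseed.scene.MaterialProps.from_table`.
"""

from __future__ import annotations

import math

#: Vacuum magnetic permeability (H/m).
MU0 = 4.0e-7 * math.pi

_LENGTH_FACTORS = {
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
}


class UnitError(ValueError):
    """Raised when a quantity with units cannot be parsed."""


def parse_length(value, default_unit: str = "mm") -> float:
    """Parse a length into metres.

    Bare numbers are interpreted in ``default_unit`` (mm at the config
    boundary); strings may carry an explicit suffix, e.g. ``"2 cm"``.
    """
    if isinstance(value, (int, float)):
        return float(value) * _LENGTH_FACTORS[default_unit]
    if isinstance(value, str):
        token = value.strip()
        for unit in sorted(_LENGTH_FACTORS, key=len, reverse=True):
            if token.endswith(unit):
                num = token[: -len(unit)].strip()
                try:
                    return float(num) * _LENGTH_FACTORS[unit]
                except ValueError as exc:  # pragma: no cover - message only
                    raise UnitError(f"cannot parse length {value!r}") from exc
        try:
            return float(token) * _LENGTH_FACTORS[default_unit]
        except ValueError as exc:
            raise UnitError(f"cannot parse length {value!r}") from exc
    raise UnitError(f"cannot parse length {value!r}")


def format_length_mm(metres: float) -> float:
    """Express a length in mm for user-facing output."""
    return metres * 1e3
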