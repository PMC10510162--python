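"""Unit and scale conversions applied before scoring.

Two conversions are shipped: Fahrenheit to Celsius for body temperature,
and the published AVPU to Glasgow Coma Scale correlation (A=15, V=12, P=8,
U=3) for level of consciousness.  Conversion output is deliberately
unrounded; rounding to recording precision happens at the scoring boundary
so a value is never double-rounded across a band edge.

The registry is extensible: new conversions register a (from_unit, to_unit)
pair without touching the scoring engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .errors import UnitError

CELSIUS = "degC"
FAHRENHEIT = "degF"

#: AVPU category -> Glasgow Coma Scale value (published correlation mapping).
AVPU_TO_GCS: dict[str, int] = {"A": 15, "V": 12, "P": 8, "U": 3}


@dataclass(frozen=True)
class ConvertedValue:
    """Audit record of one (possibly identity) unit conversion."""

    original_value: float
    original_unit: str
    converted_value: float
    converted_unit: str
    conversion_applied: bool

    def as_dict(self) -> dict:
        return {
            "original_value": self.original_value,
            "original_unit": self.original_unit,
            "converted_value": self.converted_value,
            "converted_unit": self.converted_unit,
            "conversion_applied": self.conversion_applied,
        }


def fahrenheit_to_celsius(t_f: float) -> float:
    """(t_f − 32) × 5/9, unrounded."""
    if not math.isfinite(t_f):
        raise ValueError(f"non-finite temperature {t_f!r}")
    return (t_f - 32.0) * 5.0 / 9.0


def celsius_to_fahrenheit(t_c: float) -> float:
    """Inverse of :func:`fahrenheit_to_celsius`."""
    if not math.isfinite(t_c):
        raise ValueError(f"non-finite temperature {t_c!r}")
    return t_c * 9.0 / 5.0 + 32.0


#: (from_unit, to_unit) -> conversion callable.  Identity pairs are implicit.
CONVERSIONS: dict[tuple[str, str], Callable[[float], float]] = {
    (FAHRENHEIT, CELSIUS): fahrenheit_to_celsius,
    (CELSIUS, FAHRENHEIT): celsius_to_fahrenheit,
}


def convert(value: float, from_unit: str, to_unit: str) -> ConvertedValue:
    """Convert *value* between units via the registry.

    Identity conversions are recorded with ``conversion_applied=False``;
    unknown unit pairs raise :class:`~ewsso.errors.UnitError` rather than
    passing the value through silently.
    """
    if from_unit == to_unit:
        return ConvertedValue(value, from_unit, value, to_unit, False)
    fn = CONVERSIONS.get((from_unit, to_unit))
    if fn is None:
        raise UnitError(f"no conversion registered from {from_unit!r} to {to_unit!r}")
    return ConvertedValue(value, from_unit, fn(value), to_unit, True)


def normalize_temperature(value: float, unit: str) -> ConvertedValue:
    """Express a body-temperature reading in Celsius.

    Accepts only the two unit dialects the datasets use (``degC``/``degF``);
    anything else is an error, never a silent pass-through.  Idempotent on
    Celsius input.
    """
    if unit not in (CELSIUS, FAHRENHEIT):
        raise UnitError(f"unrecognised temperature unit {unit!r}")
    return convert(value, unit, CELSIUS)


def avpu_to_gcs(category: str) -> int:
    """Map an AVPU consciousness category onto the Glasgow Coma Scale."""
    try:
        return AVPU_TO_GCS[category]
    except KeyError:
        raise ValueError(f"unknown AVPU category {category!r}") from None
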