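"""Canonical physical units and clinical-unit conversion.

Internally every quantity is expressed in seconds, millilitres and pascal
(and their compounds: flow ml/s, resistance Pa/(ml/s), compliance ml/Pa).
Infusion hardware data sheets and pump displays use hour-based units
(ml/h, Pa/(ml/h)); those are accepted at the boundary and converted here.
Lengths carry an arbitrary unit because only length ratios enter any
result (the voxel size is always a fraction of the catheter length).
"""

from __future__ import annotations

SECONDS_PER_HOUR = 3600.0

#: Multiplicative factor taking a value in the tagged unit to canonical units.
_TO_CANONICAL = {
    # time
    "s": 1.0,
    "h": SECONDS_PER_HOUR,
    # volume
    "ml": 1.0,
    # pressure
    "Pa": 1.0,
    # flow
    "ml/s": 1.0,
    "ml/h": 1.0 / SECONDS_PER_HOUR,
    # hydraulic resistance
    "Pa/(ml/s)": 1.0,
    "Pa/(ml/h)": SECONDS_PER_HOUR,
    # compliance
    "ml/Pa": 1.0,
}


class UnknownUnitError(ValueError):
    """Raised for a unit tag that is not in the conversion registry."""

    def __init__(self, unit: str):
        self.unit = unit
        super().__init__(
            f"unknown unit tag {unit!r}; known tags: {sorted(_TO_CANONICAL)}"
        )


def to_internal(value: float, unit: str) -> float:
    """Convert *value* expressed in *unit* to canonical (s, ml, Pa) units.

    >>> to_internal(12.0, "ml/h")
    0.003333333333333333...
    """
    try:
        factor = _TO_CANONICAL[unit]
    except KeyError:
        raise UnknownUnitError(unit) from None
    return value * factor


def from_internal(value: float, unit: str) -> float:
    """Inverse of :func:`to_internal` (canonical value -> tagged unit)."""
    try:
        factor = _TO_CANONICAL[unit]
    except KeyError:
        raise UnknownUnitError(unit) from None
    return value / factor


def known_units() -> tuple[str, ...]:
    return tuple(sorted(_TO_CANONICAL))
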