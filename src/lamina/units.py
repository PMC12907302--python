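"""Physical units and conversions.

The simulator computes internally in one default unit per physical
quantity (seconds, millivolts, picoamps, nanosiemens, millimetres,
nanofarads, hertz, nanomolar); user models may declare quantities in the
listed alternatives, which are converted at load time and reconverted on
output.  Units are metadata: no dimensional-coherence checking is done
across an equation — the user's model is taken at face value.

Per-membrane-area units (uA/cm2, mS/cm2, uF/cm2) convert to their
absolute counterparts only through an explicit membrane area (in cm2);
without one they form their own convertible family.
"""

from __future__ import annotations

__all__ = ["UnitError", "DEFAULT_UNITS", "convert_units", "to_default", "from_default"]


class UnitError(ValueError):
    pass


#: quantity -> default unit
DEFAULT_UNITS = {
    "time": "s",
    "voltage": "mV",
    "current": "pA",
    "conductance": "nS",
    "distance": "mm",
    "capacitance": "nF",
    "frequency": "Hz",
    "molarity": "nM",
    "current_density": "uA/cm2",
    "conductance_density": "mS/cm2",
    "capacitance_density": "uF/cm2",
}

#: unit -> (quantity, factor to the quantity's default unit)
_FACTORS: dict[str, tuple[str, float]] = {
    # time
    "s": ("time", 1.0),
    "ms": ("time", 1e-3),
    # voltage
    "mV": ("voltage", 1.0),
    "V": ("voltage", 1e3),
    # current
    "pA": ("current", 1.0),
    "nA": ("current", 1e3),
    # conductance
    "nS": ("conductance", 1.0),
    "pS": ("conductance", 1e-3),
    # distance (degrees and pixels are modalities, not units: they relate to
    # mm through a per-stimulus calibration factor, not a fixed constant)
    "mm": ("distance", 1.0),
    "um": ("distance", 1e-3),
    # capacitance
    "nF": ("capacitance", 1.0),
    "pF": ("capacitance", 1e-3),
    # frequency
    "Hz": ("frequency", 1.0),
    "kHz": ("frequency", 1e3),
    # molarity
    "nM": ("molarity", 1.0),
    "uM": ("molarity", 1e3),
    "mM": ("molarity", 1e6),
    # per-area families
    "uA/cm2": ("current_density", 1.0),
    "mS/cm2": ("conductance_density", 1.0),
    "uF/cm2": ("capacitance_density", 1.0),
}

# per-area -> absolute, given a membrane area in cm2:
#   1 uA/cm2 * 1 cm2 = 1 uA = 1e6 pA, etc.
_DENSITY_TO_ABS = {
    "current_density": ("current", 1e6),        # uA -> pA
    "conductance_density": ("conductance", 1e6),  # mS -> nS
    "capacitance_density": ("capacitance", 1e6),  # uF -> nF
}

_ALIASES = {
    "second": "s", "sec": "s", "millisecond": "ms",
    "millivolt": "mV", "volt": "V",
    "µM": "uM", "µm": "um", "µA/cm2": "uA/cm2", "µF/cm2": "uF/cm2",
}


def _resolve(unit: str) -> tuple[str, float]:
    u = _ALIASES.get(unit, unit)
    if u not in _FACTORS:
        raise UnitError(f"unknown unit {unit!r}")
    return _FACTORS[u]


def convert_units(value: float, from_unit: str, to_unit: str,
                  membrane_area_cm2: float | None = None) -> float:
    """Convert ``value`` between two units of the same physical quantity.

    A per-area unit converts to an absolute one (and back) only when
    ``membrane_area_cm2`` is given; any other cross-quantity conversion
    raises :class:`UnitError`.
    """
    q_from, f_from = _resolve(from_unit)
    q_to, f_to = _resolve(to_unit)
    if q_from == q_to:
        return value * (f_from / f_to)
    # density <-> absolute bridging
    for q_dens, (q_abs, scale) in _DENSITY_TO_ABS.items():
        if (q_from, q_to) == (q_dens, q_abs):
            if membrane_area_cm2 is None:
                raise UnitError(
                    f"converting {from_unit!r} to {to_unit!r} requires a membrane area")
            return value * f_from * membrane_area_cm2 * scale / f_to
        if (q_from, q_to) == (q_abs, q_dens):
            if membrane_area_cm2 is None:
                raise UnitError(
                    f"converting {from_unit!r} to {to_unit!r} requires a membrane area")
            return value * f_from / (membrane_area_cm2 * scale) / f_to
    raise UnitError(f"cannot convert {from_unit!r} ({q_from}) to {to_unit!r} ({q_to})")


def to_default(value: float, unit: str) -> float:
    """Convert ``value`` from ``unit`` to the default unit of its quantity."""
    q, f = _resolve(unit)
    return value * f


def from_default(value: float, unit: str) -> float:
    """Convert ``value`` from the default unit of its quantity to ``unit``."""
    q, f = _resolve(unit)
    return value / f
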