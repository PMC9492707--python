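"""Unit-style conversions to SI.

Simulation engines express trajectories and logs in one of several unit
styles.  The supported styles and their SI factors are:

========  ==========  ==========  ===============  ==========  ========
quantity  real        metal       si               lj
========  ==========  ==========  ===============  ==========  ========
length    angstrom    angstrom    meter            reduced
time      femtosecond picosecond  second           reduced
energy    kcal/mol    eV          joule            reduced
pressure  atmosphere  bar         pascal           reduced
charge    e           e           coulomb          reduced
========  ==========  ==========  ===============  ==========  ========

Reduced (lj) units carry no absolute scale; converting them requires an
explicit reference-scale mapping, otherwise :class:`UnitConfigurationError`
is raised.
"""

from __future__ import annotations

from typing import Mapping, Optional

from . import constants as c
from .errors import UnitConfigurationError

QUANTITIES = ("length", "time", "energy", "pressure", "charge", "temperature")

UNIT_STYLES = ("real", "metal", "si", "lj")

_REGISTRY: dict[str, dict[str, float]] = {
    "real": {
        "length": 1.0e-10,
        "time": 1.0e-15,
        "energy": c.KCAL_MOL_J,
        "pressure": c.ATM_PA,
        "charge": c.E_CHARGE,
        "temperature": 1.0,
    },
    "metal": {
        "length": 1.0e-10,
        "time": 1.0e-12,
        "energy": c.E_CHARGE,  # eV
        "pressure": c.BAR_PA,
        "charge": c.E_CHARGE,
        "temperature": 1.0,
    },
    "si": {q: 1.0 for q in QUANTITIES},
}


def si_factor(
    quantity: str,
    from_style: str,
    lj_reference: Optional[Mapping[str, float]] = None,
) -> float:
    """Multiplicative factor taking one `from_style` unit of `quantity` to SI.

    Parameters
    ----------
    quantity
        One of ``length, time, energy, pressure, charge, temperature``.
    from_style
        One of ``real, metal, si, lj``.
    lj_reference
        Mapping quantity -> SI scale of one reduced unit; required for the
        ``lj`` style.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")
    if from_style == "lj":
        if lj_reference is None or quantity not in lj_reference:
            raise UnitConfigurationError(
                f"lj units carry no absolute scale; provide lj_reference[{quantity!r}]"
            )
        return float(lj_reference[quantity])
    try:
        return _REGISTRY[from_style][quantity]
    except KeyError:
        raise ValueError(
            f"unknown unit style {from_style!r}; expected one of {UNIT_STYLES}"
        ) from None


def convert_units(
    value: float,
    quantity: str,
    from_style: str,
    lj_reference: Optional[Mapping[str, float]] = None,
) -> float:
    """Convert `value` expressed in `from_style` units of `quantity` to SI."""
    return value * si_factor(quantity, from_style, lj_reference)
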