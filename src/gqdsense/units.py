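"""Physical constants and centralized unit conversion.

All energy conversions in the package go through this module so the
conversion factors appear exactly once:

* 1 Hartree = 627.5095 kcal/mol = 27.2114 eV
* k_B = 1.98720e-3 kcal mol^-1 K^-1  (k_B * 298 K = 0.59219 kcal/mol)
* hc  = 1239.84 eV nm

The tabulated source data mixes eV, Hartree, kcal/mol and (silently)
kJ/mol; keeping the constants here makes the "tabulated" vs "physical"
kinetics modes auditable.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

from .errors import UnitError

HARTREE_TO_KCAL = 627.5095          # kcal/mol per Hartree
HARTREE_TO_EV = 27.2114             # eV per Hartree
EV_TO_KCAL = HARTREE_TO_KCAL / HARTREE_TO_EV
KCAL_TO_KJ = 4.184

BOLTZMANN_KCAL = 1.98720e-3         # kcal mol^-1 K^-1
BOLTZMANN_EV = 8.617333e-5          # eV K^-1
HC_EV_NM = 1239.84                  # eV * nm

#: kcal/mol-to-target factors for tagged energies (case-insensitive tags)
_TO_KCAL = {
    "hartree": HARTREE_TO_KCAL,
    "a.u.": HARTREE_TO_KCAL,
    "au": HARTREE_TO_KCAL,
    "ev": EV_TO_KCAL,
    "kcal/mol": 1.0,
    "kj/mol": 1.0 / KCAL_TO_KJ,
}


def normalize_unit(unit: str) -> str:
    key = unit.strip().lower()
    if key not in _TO_KCAL:
        raise UnitError(f"unknown energy unit tag: {unit!r}")
    return key


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between any two tagged units."""
    return value * _TO_KCAL[normalize_unit(from_unit)] / _TO_KCAL[normalize_unit(to_unit)]


def thermal_energy_kcal(temperature: float = 298.0) -> float:
    """k_B*T in kcal/mol (0.59219 at 298 K)."""
    return BOLTZMANN_KCAL * temperature


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero to ``ndigits`` decimals.

    Printed tables in this domain round 0.005 up in magnitude, which
    differs from Python's banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(value))
    return float(d.copy_abs().quantize(q, rounding=ROUND_HALF_UP) * (1 if d >= 0 else -1))
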