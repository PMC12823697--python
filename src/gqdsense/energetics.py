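"""Cohesive energy and counterpoise-corrected adsorption energy.

Cohesive energy per atom (isolated-atom references minus the bound total,
over the atom count) measures how doping destabilizes the host lattice.
Adsorption energy

    E_ads = E_complex - (E_host + E_guest) + E_BSSE      [kcal/mol]

is negative for favorable binding; the counterpoise term carries an
explicit unit tag because tabulated BSSE columns are often unitless.

Isolated-atom ground-state reference energies are user inputs — the
package never computes electronic structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Union

from .errors import ConfigurationError, LinkageError, UnitError
from .records import ComplexLink, SpeciesRecord, TaggedEnergy
from .units import convert_energy


@dataclass(frozen=True)
class EnergyBreakdown:
    """Resolved ingredients of one adsorption-energy evaluation."""

    e_complex: float  # Hartree
    e_host: float
    e_guest: float
    bsse: TaggedEnergy
    e_ads: float  # kcal/mol
    n_atoms: int


def cohesive_energy(
    e_total: float,
    atom_energies: Mapping[str, float],
    composition: Mapping[str, int],
    sign_convention: Literal["reported", "raw"] = "reported",
) -> float:
    """Cohesive energy per atom in kcal/mol.

    ``e_total`` and ``atom_energies`` are Hartree. The raw per-atom value
    (sum of isolated-atom energies minus the bound total, over n) is
    positive for a bound system; under the default reporting convention it
    is negated so that more negative means more stable.
    """
    n = sum(composition.values())
    if n < 1:
        raise ConfigurationError("composition must contain at least one atom")
    try:
        atom_sum = sum(atom_energies[elem] * count for elem, count in composition.items())
    except KeyError as exc:
        raise ConfigurationError(f"missing isolated-atom energy for element {exc}") from exc
    per_atom_hartree = (atom_sum - e_total) / n
    value = convert_energy(per_atom_hartree, "hartree", "kcal/mol")
    return -value if sign_convention == "reported" else value


def adsorption_energy(
    e_complex: float,
    e_host: float,
    e_guest: float,
    bsse: Union[TaggedEnergy, float],
    energies_unit: str = "hartree",
) -> float:
    """Counterpoise-corrected adsorption energy in kcal/mol.

    Totals are in ``energies_unit``; ``bsse`` must carry a unit tag (a bare
    float is rejected so silent unit mix-ups cannot happen).
    """
    if not isinstance(bsse, TaggedEnergy):
        raise UnitError("bsse must be a TaggedEnergy with an explicit unit tag")
    delta = convert_energy(e_complex - e_host - e_guest, energies_unit, "kcal/mol")
    return delta + convert_energy(bsse.value, bsse.unit, "kcal/mol")


def adsorption_energy_for_link(
    link: ComplexLink, records: Mapping[str, SpeciesRecord]
) -> EnergyBreakdown:
    """Resolve a complex link against a record registry and evaluate E_ads."""
    totals = {}
    for name in (link.complex_label, link.host_label, link.guest_label):
        rec = records.get(name)
        if rec is None:
            raise LinkageError(f"unresolved label {name!r} in complex link")
        if rec.e_total is None:
            raise LinkageError(f"record {name!r} carries no total energy")
        totals[name] = rec.e_total
    e_ads = adsorption_energy(
        totals[link.complex_label],
        totals[link.host_label],
        totals[link.guest_label],
        link.bsse,
    )
    return EnergyBreakdown(
        e_complex=totals[link.complex_label],
        e_host=totals[link.host_label],
        e_guest=totals[link.guest_label],
        bsse=link.bsse,
        e_ads=e_ads,
        n_atoms=records[link.complex_label].n_atoms,
    )
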