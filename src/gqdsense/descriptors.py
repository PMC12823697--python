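"""Conceptual-DFT global reactivity descriptors and electronic response.

All descriptors derive from the frontier orbital energies (eV):

    HLG    = |E_HOMO - E_LUMO|            (gap)
    eta    = (E_LUMO - E_HOMO) / 2        (chemical hardness)
    S      = 1 / (2 eta)                  (chemical softness)
    mu     = (E_HOMO + E_LUMO) / 2        (chemical potential)
    dNmax  = -mu / eta                    (maximum charge acceptance)
    ECT    = dNmax(sensor) - dNmax(complex)

A negative ECT means the analyte donates charge to the sensing surface.
Derived columns are always computed from unrounded intermediates; rounding
to printed precision happens only when comparing against tabulated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import DegenerateHardnessError, MissingPropertyError
from .records import ComplexLink, SpeciesRecord

#: hardness below this is treated as degenerate (softness/dNmax undefined)
ETA_TOLERANCE = 1e-9


def hlg(e_homo: float, e_lumo: float) -> float:
    """HOMO-LUMO gap, |E_HOMO - E_LUMO| in eV."""
    return abs(e_homo - e_lumo)


def hardness(e_homo: float, e_lumo: float) -> float:
    """Chemical hardness eta = (E_LUMO - E_HOMO)/2 in eV."""
    return (e_lumo - e_homo) / 2.0


def softness(eta: float) -> float:
    """Chemical softness S = 1/(2 eta) in eV^-1."""
    if eta <= ETA_TOLERANCE:
        raise DegenerateHardnessError(f"softness undefined for eta={eta}")
    return 1.0 / (2.0 * eta)


def chemical_potential(e_homo: float, e_lumo: float) -> float:
    """Chemical potential mu = (E_HOMO + E_LUMO)/2 in eV (negative for bound systems)."""
    return (e_homo + e_lumo) / 2.0


def delta_n_max(mu_pot: float, eta: float) -> float:
    """Maximum fractional charge acceptance, -mu/eta (dimensionless)."""
    if eta <= ETA_TOLERANCE:
        raise DegenerateHardnessError(f"dNmax undefined for eta={eta}")
    return -mu_pot / eta


def ect(dn_max_sensor: float, dn_max_complex: float) -> float:
    """Electrophilicity-based charge transfer, dNmax(sensor) - dNmax(complex).

    Negative values identify the analyte as the electron donor. The
    orientation is fixed so recomputed values reproduce the tabulated signs.
    """
    if not (math.isfinite(dn_max_sensor) and math.isfinite(dn_max_complex)):
        raise ValueError("ECT requires finite dNmax inputs")
    return dn_max_sensor - dn_max_complex


def dipole_magnitude(dipole_xyz: tuple[float, float, float]) -> float:
    """Total dipole moment |mu| = sqrt(mux^2 + muy^2 + muz^2) in Debye."""
    x, y, z = dipole_xyz
    return math.sqrt(x * x + y * y + z * z)


def mean_polarizability(polarizability_diag: tuple[float, float, float]) -> float:
    """Isotropic polarizability alpha = (axx + ayy + azz)/3 in a.u."""
    xx, yy, zz = polarizability_diag
    return (xx + yy + zz) / 3.0


def adsorption_deltas(
    sensor: SpeciesRecord, complex_: SpeciesRecord
) -> tuple[float, float]:
    """(complex - sensor) change in dipole (Debye) and polarizability (a.u.)."""
    for rec in (sensor, complex_):
        if rec.dipole_xyz is None or rec.polarizability_diag is None:
            raise MissingPropertyError(
                f"{rec.label}: dipole and polarizability required for adsorption deltas"
            )
    d_dip = dipole_magnitude(complex_.dipole_xyz) - dipole_magnitude(sensor.dipole_xyz)
    d_pol = mean_polarizability(complex_.polarizability_diag) - mean_polarizability(
        sensor.polarizability_diag
    )
    return d_dip, d_pol


@dataclass(frozen=True)
class ReactivityRow:
    """One system's global reactivity descriptors (eV scale; ECT complexes only)."""

    label: str
    lumo: float
    homo: float
    hlg: float
    eta: float
    s_soft: float
    mu_pot: float
    dn_max: float
    ect: Optional[float] = None


def reactivity_row(record: SpeciesRecord, sensor_dn_max: Optional[float] = None) -> ReactivityRow:
    """Compute all descriptors for one record from its frontier energies."""
    g = hlg(record.e_homo, record.e_lumo)
    eta = hardness(record.e_homo, record.e_lumo)
    mu = chemical_potential(record.e_homo, record.e_lumo)
    dn = delta_n_max(mu, eta)
    return ReactivityRow(
        label=record.label,
        lumo=record.e_lumo,
        homo=record.e_homo,
        hlg=g,
        eta=eta,
        s_soft=softness(eta),
        mu_pot=mu,
        dn_max=dn,
        ect=None if sensor_dn_max is None else ect(sensor_dn_max, dn),
    )


def reactivity_table(
    species: list[SpeciesRecord], links: list[ComplexLink] = ()
) -> pd.DataFrame:
    """Descriptor table for a record set, with ECT filled in for linked complexes.

    Columns follow the tabulated ordering: label, lumo, homo, hlg, eta,
    s, mu, dnmax, ect.
    """
    by_label = {rec.label: rec for rec in species}
    sensor_of = {lk.complex_label: lk.host_label for lk in links}
    rows = []
    for rec in species:
        sensor_dn = None
        host = sensor_of.get(rec.label)
        if host is not None:
            hrec = by_label[host]
            sensor_dn = delta_n_max(
                chemical_potential(hrec.e_homo, hrec.e_lumo),
                hardness(hrec.e_homo, hrec.e_lumo),
            )
        r = reactivity_row(rec, sensor_dn)
        rows.append(
            {
                "label": r.label,
                "lumo": r.lumo,
                "homo": r.homo,
                "hlg": r.hlg,
                "eta": r.eta,
                "s": r.s_soft,
                "mu": r.mu_pot,
                "dnmax": r.dn_max,
                "ect": r.ect,
            }
        )
    return pd.DataFrame(rows)
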