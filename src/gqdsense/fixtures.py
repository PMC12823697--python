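"""Bundled golden fixtures: the published descriptor tables.

The study tabulates, per functional/phase block, frontier orbital
energies with derived reactivity descriptors, dipole/polarizability/ZPE,
adsorption energies with recovery time and conductivity, UV excitation
lines, and bond-critical-point scalars, plus per-system cohesive
energies. Those printed values are stored here verbatim (as strings, so
the printed precision is known) together with outlier flags, and
:func:`reference_fixture_set` rebuilds validated record sets from them.

Flagged cells — internally inconsistent in the source — are excluded
from golden comparisons rather than silently accepted:

* the water-phase Zn complex ECT (prints -0.02, recomputes to +0.02);
* the range-separated-functional conductivity rows (about 10x what the
  conductivity model reconstructs from their gaps);
* two excitation lines whose printed energy violates E = hc/lambda by
  more than 0.03 eV (gas-phase Al sensor 357 nm / 3.30 eV and gas-phase
  Zn complex 528 nm / 2.28 eV).

Bond-critical-point rows are stored with their printed sign pattern even
where it is unphysical (V positive / G negative in places); Hb
comparisons therefore go through |V + G| vs |Hb|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import BCPRecord, ComplexLink, ExcitationLine, SpeciesRecord, TaggedEnergy

COMPOSITIONS = {
    "FA": {"C": 1, "H": 2, "O": 1},
    "Coronene": {"C": 24, "H": 12},
    "Al.Coronene": {"Al": 1, "C": 23, "H": 12},
    "Zn.Coronene": {"Zn": 1, "C": 23, "H": 12},
}

_SENSOR_OF = {
    "Coronene@FA": "Coronene",
    "Zn.Coronene@FA": "Zn.Coronene",
    "Al.Coronene@FA": "Al.Coronene",
}


@dataclass(frozen=True)
class ReactivityFixtureRow:
    functional: str
    phase: str
    label: str
    lumo: str
    homo: str
    hlg: str
    eta: str
    s: str
    mu: str
    dnmax: str
    ect: Optional[str] = None
    flagged: frozenset[str] = frozenset()


def _t3(func, phase, label, *cols, flagged=()):
    return ReactivityFixtureRow(func, phase, label, *cols, flagged=frozenset(flagged))


#: Reactivity table, all three method blocks, S/mu column order normalized.
REACTIVITY_TABLE: tuple[ReactivityFixtureRow, ...] = (
    _t3("B97D", "water", "FA", "-2.05", "-5.94", "3.89", "1.94", "0.25", "-3.99", "2.05"),
    _t3("B97D", "water", "Coronene", "-2.4", "-5.26", "2.86", "1.43", "0.34", "-3.83", "2.67"),
    _t3("B97D", "water", "Zn.Coronene", "-3.22", "-4.42", "1.2", "0.6", "0.83", "-3.82", "6.36"),
    _t3("B97D", "water", "Al.Coronene", "-2.64", "-4.73", "2.09", "1.04", "0.47", "-3.68", "3.52"),
    _t3("B97D", "water", "Coronene@FA", "-3.51", "-5.3", "1.79", "0.89", "0.55", "-4.40", "4.92", "-2.24"),
    _t3("B97D", "water", "Zn.Coronene@FA", "-3.18", "-4.37", "1.19", "0.59", "0.84", "-3.77", "6.34", "-0.02",
        flagged=("ect",)),
    _t3("B97D", "water", "Al.Coronene@FA", "-3.95", "-4.34", "0.39", "0.19", "2.56", "-4.14", "21.25", "-17.73"),
    _t3("B97D", "gas", "FA", "-2.56", "-6.33", "3.77", "1.88", "0.26", "-4.44", "2.35"),
    _t3("B97D", "gas", "Coronene", "-2.25", "-5.11", "2.86", "1.43", "0.34", "-3.68", "2.57"),
    _t3("B97D", "gas", "Zn.Coronene", "-3.54", "-4.63", "1.09", "0.54", "0.91", "-4.08", "7.49"),
    _t3("B97D", "gas", "Al.Coronene", "-2.53", "-4.62", "2.09", "1.04", "0.47", "-3.57", "3.42"),
    _t3("B97D", "gas", "Coronene@FA", "-2.37", "-5.19", "2.82", "1.41", "0.35", "-3.78", "2.68", "-0.10"),
    _t3("B97D", "gas", "Zn.Coronene@FA", "-3.48", "-4.34", "0.86", "0.43", "1.16", "-3.91", "9.09", "-1.59"),
    _t3("B97D", "gas", "Al.Coronene@FA", "-4.05", "-4.26", "0.21", "0.10", "4.76", "-4.15", "39.57", "-36.15"),
    _t3("WB97XD", "water", "FA", "0.62", "-9.85", "10.47", "5.23", "0.09", "-4.61", "0.88"),
    _t3("WB97XD", "water", "Coronene", "-0.29", "-7.61", "7.32", "3.66", "0.13", "-3.95", "1.07"),
    _t3("WB97XD", "water", "Zn.Coronene", "0.14", "-6.57", "6.71", "3.35", "0.14", "-3.21", "0.95"),
    _t3("WB97XD", "water", "Al.Coronene", "0.45", "-7.24", "7.69", "3.84", "0.13", "-3.39", "0.88"),
    _t3("WB97XD", "water", "Coronene@FA", "-0.34", "-7.64", "7.3", "3.65", "0.13", "-3.99", "1.09", "-0.01"),
    _t3("WB97XD", "water", "Zn.Coronene@FA", "-0.06", "-6.64", "6.58", "3.29", "0.15", "-3.35", "1.01", "-0.05"),
    _t3("WB97XD", "water", "Al.Coronene@FA", "-0.89", "-6.8", "5.91", "2.95", "0.16", "-3.84", "1.30", "-0.41"),
)


@dataclass(frozen=True)
class ResponseFixtureRow:
    functional: str
    phase: str
    label: str
    dipole: float       # Debye, magnitude
    polarizability: float  # a.u., isotropic
    zpe: float          # Hartree


RESPONSE_TABLE: tuple[ResponseFixtureRow, ...] = (
    ResponseFixtureRow("B97D", "water", "Coronene", 0.00, 311.58, 0.268),
    ResponseFixtureRow("B97D", "water", "Zn.Coronene", 0.94, 344.39, 0.258),
    ResponseFixtureRow("B97D", "water", "Al.Coronene", 0.73, 337.43, 0.258),
    ResponseFixtureRow("B97D", "water", "Coronene@FA", 1.81, 323.86, 0.297),
    ResponseFixtureRow("B97D", "water", "Zn.Coronene@FA", 3.62, 367.72, 0.286),
    ResponseFixtureRow("B97D", "water", "Al.Coronene@FA", 3.24, 398.56, 0.290),
    ResponseFixtureRow("B97D", "gas", "Coronene", 0.00, 304.53, 0.270),
    ResponseFixtureRow("B97D", "gas", "Zn.Coronene", 0.93, 335.00, 0.261),
    ResponseFixtureRow("B97D", "gas", "Al.Coronene", 0.75, 330.23, 0.261),
    ResponseFixtureRow("B97D", "gas", "Coronene@FA", 1.85, 316.50, 0.298),
    ResponseFixtureRow("B97D", "gas", "Zn.Coronene@FA", 3.36, 361.92, 0.289),
    ResponseFixtureRow("B97D", "gas", "Al.Coronene@FA", 2.33, 394.18, 0.290),
    ResponseFixtureRow("WB97XD", "water", "Coronene", 0.00, 296.74, 0.273),
    ResponseFixtureRow("WB97XD", "water", "Zn.Coronene", 2.52, 325.57, 0.265),
    ResponseFixtureRow("WB97XD", "water", "Al.Coronene", 0.68, 321.34, 0.263),
    ResponseFixtureRow("WB97XD", "water", "Coronene@FA", 1.82, 308.59, 0.300),
    ResponseFixtureRow("WB97XD", "water", "Zn.Coronene@FA", 3.58, 339.08, 0.295),
    ResponseFixtureRow("WB97XD", "water", "Al.Coronene@FA", 3.44, 385.78, 0.293),
)


@dataclass(frozen=True)
class EnergeticsFixtureRow:
    functional: str
    phase: str
    label: str
    eads: Optional[float]   # kcal/mol; None for bare sensors
    bsse: Optional[float]   # printed without units; interpreted as Hartree
    tau: Optional[float]    # s
    sigma: float            # A m^-2
    sigma_flagged: bool = False


ENERGETICS_TABLE: tuple[EnergeticsFixtureRow, ...] = (
    EnergeticsFixtureRow("B97D", "water", "Coronene", None, None, None, 1.73e9),
    EnergeticsFixtureRow("B97D", "water", "Zn.Coronene", None, None, None, 2.42e9),
    EnergeticsFixtureRow("B97D", "water", "Al.Coronene", None, None, None, 2.02e9),
    EnergeticsFixtureRow("B97D", "water", "Coronene@FA", -4.01, 0.0017, 8.76e-14, 2.15e9),
    EnergeticsFixtureRow("B97D", "water", "Zn.Coronene@FA", -6.16, 0.0031, 3.34e-12, 2.43e9),
    EnergeticsFixtureRow("B97D", "water", "Al.Coronene@FA", -39.57, 0.0028, 1.08e13, 2.85e9),
    EnergeticsFixtureRow("B97D", "gas", "Coronene", None, None, None, 1.73e9),
    EnergeticsFixtureRow("B97D", "gas", "Zn.Coronene", None, None, None, 2.48e9),
    EnergeticsFixtureRow("B97D", "gas", "Al.Coronene", None, None, None, 2.02e9),
    EnergeticsFixtureRow("B97D", "gas", "Coronene@FA", -4.43, 0.0017, 1.78e-13, 1.75e9),
    EnergeticsFixtureRow("B97D", "gas", "Zn.Coronene@FA", -15.81, 0.0021, 3.96e-5, 2.59e9),
    EnergeticsFixtureRow("B97D", "gas", "Al.Coronene@FA", -44.43, 0.0019, 3.93e16, 2.96e9),
    EnergeticsFixtureRow("WB97XD", "water", "Coronene", None, None, None, 7.05e9, True),
    EnergeticsFixtureRow("WB97XD", "water", "Zn.Coronene", None, None, None, 6.54e9, True),
    EnergeticsFixtureRow("WB97XD", "water", "Al.Coronene", None, None, None, 7.97e9, True),
    EnergeticsFixtureRow("WB97XD", "water", "Coronene@FA", -4.03, 0.0017, 9.14e-14, 7.08e9, True),
    EnergeticsFixtureRow("WB97XD", "water", "Zn.Coronene@FA", -13.09, 0.0023, 4.01e-7, 9.37e9, True),
    EnergeticsFixtureRow("WB97XD", "water", "Al.Coronene@FA", -42.26, 0.0018, 1.01e15, 8.19e9, True),
)


@dataclass(frozen=True)
class UVFixtureRow:
    phase: str          # functional is B97D throughout
    label: str
    lambda_nm: float
    eex: float          # eV, as printed
    f_osc: float
    eex_flagged: bool = False  # printed Eex inconsistent with hc/lambda


UV_TABLE: tuple[UVFixtureRow, ...] = (
    UVFixtureRow("water", "Coronene", 338, 3.66, 0.4780),
    UVFixtureRow("water", "Zn.Coronene", 352, 3.52, 0.1215),
    UVFixtureRow("water", "Zn.Coronene", 490, 2.52, 0.0285),
    UVFixtureRow("water", "Al.Coronene", 394, 3.14, 0.0481),
    UVFixtureRow("water", "Al.Coronene", 490, 2.52, 0.0128),
    UVFixtureRow("water", "Coronene@FA", 338, 3.66, 0.4437),
    UVFixtureRow("water", "Zn.Coronene@FA", 398, 3.10, 0.0253),
    UVFixtureRow("water", "Zn.Coronene@FA", 541, 2.28, 0.0190),
    UVFixtureRow("water", "Al.Coronene@FA", 579, 2.13, 0.0017),
    UVFixtureRow("water", "Al.Coronene@FA", 694, 1.78, 0.0103),
    UVFixtureRow("gas", "Coronene", 328, 3.77, 0.5307),
    UVFixtureRow("gas", "Zn.Coronene", 352, 3.52, 0.1215),
    UVFixtureRow("gas", "Zn.Coronene", 490, 2.52, 0.0285),
    UVFixtureRow("gas", "Al.Coronene", 357, 3.30, 0.0450, True),
    UVFixtureRow("gas", "Al.Coronene", 480, 2.57, 0.0205),
    UVFixtureRow("gas", "Coronene@FA", 329, 3.76, 0.4947),
    UVFixtureRow("gas", "Zn.Coronene@FA", 403, 3.10, 0.0127),
    UVFixtureRow("gas", "Zn.Coronene@FA", 528, 2.28, 0.0184, True),
    UVFixtureRow("gas", "Al.Coronene@FA", 613, 2.02, 0.0167),
    UVFixtureRow("gas", "Al.Coronene@FA", 785, 1.57, 0.0118),
)


@dataclass(frozen=True)
class BCPFixtureRow:
    functional: str     # water phase throughout
    label: str
    rho: float
    lap_rho: float
    v_r: float          # printed sign pattern kept verbatim
    g_r: float
    vir: float          # undefined in the source; loaded opaquely
    hb: float


BCP_TABLE: tuple[BCPFixtureRow, ...] = (
    BCPFixtureRow("B97D", "Coronene@FA", 0.0098, -0.0081, 0.0066, -0.0015, 0.0052, 0.005),
    BCPFixtureRow("B97D", "Zn.Coronene@FA", 0.0541, -0.0595, 0.0657, 0.0061, 0.0719, 0.071),
    BCPFixtureRow("B97D", "Al.Coronene@FA", 0.0502, -0.07827, 0.0738, 0.0044, 0.0693, 0.078),
    BCPFixtureRow("WB97XD", "Coronene@FA", 0.0089, -0.0074, 0.0060, -0.0014, 0.0045, 0.004),
    BCPFixtureRow("WB97XD", "Zn.Coronene@FA", 0.0225, -0.0101, 0.0098, -0.0002, 0.0096, 0.009),
    BCPFixtureRow("WB97XD", "Al.Coronene@FA", 0.0523, -0.0846, 0.0793, -0.0052, 0.0741, 0.074),
)

#: Cohesive energy per atom (kcal/mol, more negative = more stable); B97D, water.
COHESIVE_ENERGIES = {
    "Coronene": -148.71,
    "Zn.Coronene": -145.99,
    "Al.Coronene": -141.18,
}


def last_digit_tol(printed: str) -> float:
    """One unit in the last printed decimal digit of a tabulated value."""
    if "." in printed:
        return 10.0 ** -(len(printed) - printed.index(".") - 1)
    return 1.0


def _role_of(label: str) -> str:
    if label == "FA":
        return "analyte"
    return "complex" if label.endswith("@FA") else "sensor"


def _composition_of(label: str) -> dict[str, int]:
    if label.endswith("@FA"):
        base = COMPOSITIONS[label[: -len("@FA")]]
        comp = dict(base)
        for elem, count in COMPOSITIONS["FA"].items():
            comp[elem] = comp.get(elem, 0) + count
        return comp
    return dict(COMPOSITIONS[label])


@dataclass(frozen=True)
class FixtureSet:
    """Validated record sets per (functional, phase) block plus expected tables."""

    species_blocks: dict[tuple[str, str], list[SpeciesRecord]]
    link_blocks: dict[tuple[str, str], list[ComplexLink]]
    reactivity: tuple[ReactivityFixtureRow, ...] = REACTIVITY_TABLE
    response: tuple[ResponseFixtureRow, ...] = RESPONSE_TABLE
    energetics: tuple[EnergeticsFixtureRow, ...] = ENERGETICS_TABLE
    uv: tuple[UVFixtureRow, ...] = UV_TABLE
    bcp: tuple[BCPFixtureRow, ...] = BCP_TABLE
    cohesive: dict[str, float] = field(default_factory=lambda: dict(COHESIVE_ENERGIES))


def reference_fixture_set() -> FixtureSet:
    """Rebuild validated species records and links from the bundled tables.

    Records carry the printed frontier energies; dipole magnitudes embed as
    (d, 0, 0) and isotropic polarizabilities as (a, a, a) so the derived
    magnitude/mean reproduce the printed scalars. Excitation lines (the
    dispersion-corrected functional only) and bond-critical-point scalars
    attach to their blocks; counterpoise corrections are tagged Hartree.
    """
    t4 = {(r.functional, r.phase, r.label): r for r in RESPONSE_TABLE}
    t5 = {(r.functional, r.phase, r.label): r for r in ENERGETICS_TABLE}
    t6: dict[tuple[str, str], list[ExcitationLine]] = {}
    for r in UV_TABLE:
        t6.setdefault((r.phase, r.label), []).append(
            ExcitationLine(lambda_nm=r.lambda_nm, e_ex=r.eex, f_osc=r.f_osc)
        )
    t7 = {(r.functional, r.label): r for r in BCP_TABLE}

    species_blocks: dict[tuple[str, str], list[SpeciesRecord]] = {}
    link_blocks: dict[tuple[str, str], list[ComplexLink]] = {}
    for row in REACTIVITY_TABLE:
        key = (row.functional, row.phase)
        label = row.label
        resp = t4.get((row.functional, row.phase, label))
        exci = t6.get((row.phase, label), []) if row.functional == "B97D" else []
        bcp = t7.get((row.functional, label)) if row.phase == "water" else None
        rec = SpeciesRecord(
            label=label,
            role=_role_of(label),
            phase=row.phase,
            functional=row.functional,
            e_homo=float(row.homo),
            e_lumo=float(row.lumo),
            dipole_xyz=None if resp is None else (resp.dipole, 0.0, 0.0),
            polarizability_diag=None
            if resp is None
            else (resp.polarizability,) * 3,
            zpe=None if resp is None else resp.zpe,
            composition=_composition_of(label),
            excitations=exci,
            bcps=[]
            if bcp is None
            else [BCPRecord(rho=bcp.rho, lap_rho=bcp.lap_rho, v_r=bcp.v_r, g_r=bcp.g_r)],
        )
        species_blocks.setdefault(key, []).append(rec)
        if label.endswith("@FA"):
            bsse = t5[(row.functional, row.phase, label)].bsse
            link_blocks.setdefault(key, []).append(
                ComplexLink(
                    complex_label=label,
                    host_label=_SENSOR_OF[label],
                    guest_label="FA",
                    bsse=TaggedEnergy(value=bsse, unit="hartree"),
                )
            )
    return FixtureSet(species_blocks=species_blocks, link_blocks=link_blocks)
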