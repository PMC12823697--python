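"""Data model, validation and I/O for quantum-chemistry summary records.

A :class:`SpeciesRecord` holds the ~15 scalars the downstream analysis
needs per chemical system (frontier orbital energies, total energy,
dipole/polarizability, excitation and vibrational line lists, bond
critical point scalars, composition). Records travel in a small YAML
interchange format documented in ``docs/record_schema.md``; full
electronic-structure log parsing is deliberately out of scope — an
external converter can emit the same schema.
"""

from __future__ import annotations

import math
import warnings
from typing import IO, Iterable, Literal, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import (
    DegenerateGeometryError,
    LinkageError,
    ParseError,
    RecordValidationError,
)
from .units import HC_EV_NM, normalize_unit

Role = Literal["sensor", "analyte", "complex", "atom"]
Phase = Literal["water", "gas"]

#: soft consistency band for |Eex - hc/lambda| (eV); violations are flagged,
#: never fatal, because tabulated excitation energies are rounded separately
#: from their wavelengths.
EXCITATION_CONSISTENCY_EV = 0.2


class TaggedEnergy(BaseModel):
    """An energy value with an explicit unit tag."""

    model_config = ConfigDict(frozen=True)

    value: float
    unit: str

    @field_validator("unit")
    @classmethod
    def _known_unit(cls, v: str) -> str:
        return normalize_unit(v)


class ExcitationLine(BaseModel):
    """One electronic transition: wavelength, exciton energy, oscillator strength."""

    model_config = ConfigDict(frozen=True)

    lambda_nm: float = Field(gt=0)
    e_ex: float
    f_osc: float = Field(ge=0)

    def energy_consistent(self, tol: float = EXCITATION_CONSISTENCY_EV) -> bool:
        """True when Eex agrees with hc/lambda within ``tol`` eV."""
        return abs(self.e_ex - HC_EV_NM / self.lambda_nm) <= tol


class VibLine(BaseModel):
    """One vibrational mode (cm^-1) and its IR intensity."""

    model_config = ConfigDict(frozen=True)

    freq_cm1: float
    intensity: float = Field(ge=0)


class BCPRecord(BaseModel):
    """Electron-density scalars at one bond critical point (atomic units).

    ``convention="printed"`` accepts tabulated values verbatim even where
    their sign pattern is unphysical; ``convention="physical"`` enforces
    G(r) > 0 and V(r) < 0, which the synthetic generator uses.
    """

    model_config = ConfigDict(frozen=True)

    rho: float = Field(gt=0)
    lap_rho: float
    v_r: float
    g_r: float
    convention: Literal["printed", "physical"] = "printed"

    @model_validator(mode="after")
    def _physical_signs(self) -> "BCPRecord":
        if self.convention == "physical" and not (self.g_r > 0 and self.v_r < 0):
            raise ValueError(
                f"physical-sign BCP requires G(r) > 0 and V(r) < 0, got "
                f"G={self.g_r}, V={self.v_r}"
            )
        return self


class SpeciesRecord(BaseModel):
    """One chemical system's quantum-chemistry summary.

    Energies: ``e_homo``/``e_lumo`` in eV, ``e_total``/``zpe`` in Hartree.
    ``dipole_xyz`` in Debye, ``polarizability_diag`` diagonal components in
    atomic units, coordinates in Å.
    """

    model_config = ConfigDict(frozen=True)

    label: str = Field(min_length=1)
    role: Role
    phase: Phase
    functional: str = Field(min_length=1)
    e_homo: float
    e_lumo: float
    e_total: Optional[float] = None
    zpe: Optional[float] = None
    dipole_xyz: Optional[tuple[float, float, float]] = None
    polarizability_diag: Optional[tuple[float, float, float]] = None
    composition: dict[str, int] = Field(default_factory=dict)
    excitations: list[ExcitationLine] = Field(default_factory=list)
    vib_modes: list[VibLine] = Field(default_factory=list)
    bcps: list[BCPRecord] = Field(default_factory=list)
    coordinates: Optional[list[tuple[str, float, float, float]]] = None

    @model_validator(mode="after")
    def _invariants(self) -> "SpeciesRecord":
        if self.e_homo > self.e_lumo:
            raise ValueError(
                f"{self.label}: e_homo ({self.e_homo}) above e_lumo "
                f"({self.e_lumo}); occupied levels must lie below virtual"
            )
        for elem, count in self.composition.items():
            if count <= 0:
                raise ValueError(f"{self.label}: composition count {elem}={count} must be positive")
        if self.polarizability_diag is not None and any(a <= 0 for a in self.polarizability_diag):
            raise ValueError(f"{self.label}: polarizability diagonal must be positive")
        for line in self.excitations:
            if not line.energy_consistent():
                warnings.warn(
                    f"{self.label}: excitation at {line.lambda_nm} nm has Eex "
                    f"{line.e_ex} eV inconsistent with hc/lambda "
                    f"({HC_EV_NM / line.lambda_nm:.3f} eV)",
                    stacklevel=2,
                )
        return self

    @property
    def n_atoms(self) -> int:
        return sum(self.composition.values())


class ComplexLink(BaseModel):
    """Host/guest/complex label triple with its counterpoise correction."""

    model_config = ConfigDict(frozen=True)

    complex_label: str
    host_label: str
    guest_label: str
    bsse: TaggedEnergy


# ---------------------------------------------------------------------------
# interchange I/O

def _wrap_validation(kind: str, payload: dict) -> SpeciesRecord | ComplexLink:
    try:
        if kind == "species":
            return SpeciesRecord(**payload)
        return ComplexLink(**payload)
    except Exception as exc:  # pydantic ValidationError carries field names
        label = payload.get("label") or payload.get("complex_label") or "<unlabeled>"
        msg = str(exc)
        if "e_homo" in msg and "above e_lumo" in msg:
            raise RecordValidationError(f"{kind} record {label!r}: {msg}") from exc
        raise ParseError(f"{kind} record {label!r}: {msg}") from exc


def read_records(
    source: Union[str, IO[str], dict],
) -> tuple[list[SpeciesRecord], list[ComplexLink]]:
    """Read the YAML interchange format.

    ``source`` may be a path, an open text stream, or an already-parsed
    mapping. Returns validated species records and complex links; duplicate
    labels and dangling/mismatched links are rejected.
    """
    if isinstance(source, dict):
        doc = source
    else:
        if isinstance(source, str):
            with open(source, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
    if doc is None:
        return [], []
    if not isinstance(doc, dict):
        raise ParseError("interchange stream must be a mapping with 'species'/'complexes'")

    species = [_wrap_validation("species", item) for item in doc.get("species") or []]
    links = [_wrap_validation("complex", item) for item in doc.get("complexes") or []]

    by_label: dict[str, SpeciesRecord] = {}
    for rec in species:
        if rec.label in by_label:
            raise ParseError(f"duplicate species label {rec.label!r}")
        by_label[rec.label] = rec

    for link in links:
        members = []
        for name in (link.complex_label, link.host_label, link.guest_label):
            if name not in by_label:
                raise LinkageError(f"complex link {link.complex_label!r}: unresolved label {name!r}")
            members.append(by_label[name])
        if len({m.phase for m in members}) > 1 or len({m.functional for m in members}) > 1:
            raise LinkageError(
                f"complex link {link.complex_label!r}: members mix phases/functionals"
            )
    return species, links


def write_records(
    species: Sequence[SpeciesRecord],
    links: Sequence[ComplexLink] = (),
    stream: Optional[IO[str]] = None,
) -> str:
    """Serialize records back to the interchange format (full float precision).

    Returns the YAML text; also writes it to ``stream`` when given.
    ``read_records(write_records(...))`` round-trips every field exactly.
    """
    doc = {
        "species": [rec.model_dump(mode="json", exclude_none=True) for rec in species],
        "complexes": [link.model_dump(mode="json") for link in links],
    }
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# geometry operators (tested on synthetic coordinates; the source tables
# print distances/angles directly)

def bond_length(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two points in Å."""
    a, b = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    return float(np.linalg.norm(a - b))


def bond_angle(p1: Sequence[float], vertex: Sequence[float], p3: Sequence[float]) -> float:
    """Angle in degrees at ``vertex``, clamped to [0, 180]."""
    v = np.asarray(vertex, dtype=float)
    u1 = np.asarray(p1, dtype=float) - v
    u2 = np.asarray(p3, dtype=float) - v
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("bond angle undefined: zero-length arm at vertex")
    cosang = float(np.dot(u1, u2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def validate_minimum(vib_modes: Iterable[VibLine]) -> bool:
    """True iff every vibrational frequency is real (> 0 cm^-1).

    A structure with no imaginary frequencies sits at a true minimum rather
    than a transition state.
    """
    modes = list(vib_modes)
    if not modes:
        raise RecordValidationError("cannot judge stability from an empty mode list")
    return all(m.freq_cm1 > 0 for m in modes)
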