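"""QTAIM bond-critical-point energetics and interaction classification.

The total energy density at a bond critical point, Hb = V(r) + G(r),
combined with the sign of the density Laplacian, drives the Rozas scheme
for grading host-guest contacts:

    Hb < 0, lap < 0  -> strong, covalent-like
    Hb > 0, lap < 0  -> medium strength, largely electrostatic
    Hb > 0, lap > 0  -> weak, dispersive

The fourth sign pattern (Hb < 0, lap > 0) falls outside the stated
scheme; it is mapped to the nearest category with a warning flag rather
than rejected. Non-covalent-interaction (NCI) points carry the density
signed by the second Hessian eigenvalue, sign(lambda2)*rho: negative is
attractive, near zero van der Waals, positive steric repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .errors import GqdError

Category = Literal["strong_covalent_like", "medium_electrostatic", "weak_dispersive"]
NCIClass = Literal["attractive", "van_der_waals", "repulsive"]

NCI_VDW_BAND = 0.01  # a.u.; conventional near-zero band for sign(lambda2)*rho


def total_energy_density(v_r: float, g_r: float) -> float:
    """Hb = V(r) + G(r) in atomic units."""
    return v_r + g_r


@dataclass(frozen=True)
class InteractionClass:
    """Rozas category with the sign pair it was derived from."""

    category: Category
    basis: tuple[str, str]  # (sign of Hb, sign of lap_rho) as '-'/'+'
    outside_scheme: bool = False


def rozas_classify(hb: float, lap_rho: float) -> InteractionClass:
    """Classify an interaction from the signs of Hb and the Laplacian.

    Depends only on signs, so it is invariant under positive rescaling.
    Zero is treated as non-negative ('+').
    """
    s_hb = "-" if hb < 0 else "+"
    s_lap = "-" if lap_rho < 0 else "+"
    if s_hb == "-" and s_lap == "-":
        return InteractionClass("strong_covalent_like", (s_hb, s_lap))
    if s_hb == "+" and s_lap == "-":
        return InteractionClass("medium_electrostatic", (s_hb, s_lap))
    if s_hb == "+" and s_lap == "+":
        return InteractionClass("weak_dispersive", (s_hb, s_lap))
    # (-, +): not covered by the scheme; flag and map to the nearest grade
    return InteractionClass("medium_electrostatic", (s_hb, s_lap), outside_scheme=True)


@dataclass(frozen=True)
class NCIPoint:
    """One NCI sample: sign(lambda2)*rho with an optional reduced gradient."""

    signed_density: float  # a.u.
    rdg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rdg is not None and self.rdg < 0:
            raise GqdError("reduced density gradient must be non-negative")


def nci_classify(point: NCIPoint, vdw_band: float = NCI_VDW_BAND) -> NCIClass:
    """Bucket an NCI point as attractive / van der Waals / repulsive."""
    if vdw_band <= 0:
        raise GqdError("vdw_band must be positive")
    if point.signed_density < -vdw_band:
        return "attractive"
    if point.signed_density > vdw_band:
        return "repulsive"
    return "van_der_waals"
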