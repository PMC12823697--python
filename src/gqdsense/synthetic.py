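"""Synthetic quantum-chemistry record sets with a planted ground truth.

The generator stands in for the electronic-structure engine: for each
synthetic system it emits a sensor, an analyte and a complex record whose
scalar fields are constructed so every pipeline descriptor is recoverable
exactly (zero noise) or unbiasedly (relative Gaussian noise). Total
energies are built backwards from a planted adsorption energy so the
counterpoise-corrected energy balance returns it to machine precision;
excitation energies satisfy E = hc/lambda exactly; bond-critical-point
scalars are drawn with physical signs (G > 0, V < 0) from a requested
mix of interaction classes. Every planted truth is stored in a ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import descriptors, kinetics
from .errors import ConfigurationError
from .records import (
    BCPRecord,
    ComplexLink,
    ExcitationLine,
    SpeciesRecord,
    TaggedEnergy,
    VibLine,
)
from .topology import rozas_classify, total_energy_density
from .units import HARTREE_TO_KCAL, HC_EV_NM

DEFAULT_SEED = 20251213

#: rough isolated-atom ground-state energies (Hartree) used as draw centers
_ATOM_ENERGY_CENTERS = {"C": -37.8, "H": -0.5, "O": -75.0, "Al": -242.3, "Zn": -1779.3}


class GeneratorSpec(BaseModel):
    """Parameters of the synthetic study.

    Defaults mirror the conditions of the study being emulated: frontier
    HOMO levels in [-10, -4] eV, gaps up to ~4 eV, adsorption energies
    spanning weak physisorption to strong chemisorption (-45 to -4
    kcal/mol), counterpoise corrections on the ~2 mHartree scale.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = DEFAULT_SEED
    n_systems: int = Field(default=10, ge=1)
    frontier_range: tuple[float, float] = (-10.0, -4.0)
    gap_range: tuple[float, float] = (0.2, 4.0)
    eads_range: tuple[float, float] = (-45.0, -4.0)
    bsse_scale: float = Field(default=0.002, gt=0)  # Hartree
    rozas_mix: tuple[float, float, float] = (0.2, 0.6, 0.2)  # strong/medium/weak
    noise_sd: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _ranges(self) -> "GeneratorSpec":
        for name in ("frontier_range", "gap_range", "eads_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a nonempty interval, got ({lo}, {hi})")
        if self.gap_range[0] <= 0:
            raise ValueError("gap_range must be strictly positive")
        if abs(sum(self.rozas_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.rozas_mix):
            raise ValueError("rozas_mix must be non-negative probabilities summing to 1")
        return self


@dataclass(frozen=True)
class SyntheticSet:
    """Generated records plus the ledger of planted truths."""

    species: list[SpeciesRecord]
    links: list[ComplexLink]
    ledger: dict = field(default_factory=dict)


def _frontier(rng: np.random.Generator, spec: GeneratorSpec) -> tuple[float, float]:
    homo = rng.uniform(*spec.frontier_range)
    gap = rng.uniform(*spec.gap_range)
    return homo, homo + gap


def _reactivity_truth(e_homo: float, e_lumo: float) -> dict:
    eta = descriptors.hardness(e_homo, e_lumo)
    mu = descriptors.chemical_potential(e_homo, e_lumo)
    return {
        "hlg": descriptors.hlg(e_homo, e_lumo),
        "eta": eta,
        "s": descriptors.softness(eta),
        "mu": mu,
        "dnmax": descriptors.delta_n_max(mu, eta),
    }


def _draw_bcp(rng: np.random.Generator, mix: tuple[float, float, float]) -> BCPRecord:
    cls = rng.choice(("strong", "medium", "weak"), p=mix)
    g = rng.uniform(0.003, 0.08)
    if cls == "strong":
        lap = -rng.uniform(0.01, 0.1)
        v = -(g + rng.uniform(0.002, 0.05))       # Hb < 0
    else:
        lap = -rng.uniform(0.01, 0.1) if cls == "medium" else rng.uniform(0.01, 0.1)
        v = -(g - rng.uniform(0.0005, min(0.008, 0.9 * g)))  # Hb > 0, V < 0
    return BCPRecord(
        rho=rng.uniform(0.005, 0.06), lap_rho=lap, v_r=v, g_r=g, convention="physical"
    )


def _vib_modes(rng: np.random.Generator) -> list[VibLine]:
    n = int(rng.integers(4, 9))
    return [
        VibLine(freq_cm1=float(rng.uniform(80.0, 3200.0)), intensity=float(rng.uniform(0.0, 100.0)))
        for _ in range(n)
    ]


def _excitations(
    rng: np.random.Generator, lambda_max: float, n_extra: int
) -> list[ExcitationLine]:
    f_main = rng.uniform(0.2, 0.6)
    lines = [ExcitationLine(lambda_nm=lambda_max, e_ex=HC_EV_NM / lambda_max, f_osc=f_main)]
    for _ in range(n_extra):
        lam = rng.uniform(250.0, 900.0)
        lines.append(
            ExcitationLine(lambda_nm=lam, e_ex=HC_EV_NM / lam, f_osc=rng.uniform(0.0, 0.9) * f_main)
        )
    return lines


def generate_sensor_set(spec: GeneratorSpec = GeneratorSpec()) -> SyntheticSet:
    """Generate ``n_systems`` sensor/analyte/complex triples with a truth ledger.

    With ``noise_sd = 0`` every descriptor the pipeline computes (gap
    descriptors, ECT, E_ads, cohesive energy, recovery time, conductivity,
    dipole/polarizability deltas, Hb and its interaction class, UV red
    shift) matches the ledger to machine precision. With noise, reported
    values are true values perturbed by multiplicative N(1, noise_sd)
    factors, so recovered quantities stay unbiased on the relative scale.
    """
    if not isinstance(spec, GeneratorSpec):
        raise ConfigurationError("generate_sensor_set expects a GeneratorSpec")
    rng = np.random.default_rng(spec.seed)
    noisy = lambda x: float(x) * (1.0 + spec.noise_sd * rng.standard_normal()) if spec.noise_sd else float(x)

    atom_energies = {
        elem: center + rng.uniform(-0.2, 0.2) for elem, center in _ATOM_ENERGY_CENTERS.items()
    }
    species: list[SpeciesRecord] = []
    links: list[ComplexLink] = []
    systems = []

    for i in range(spec.n_systems):
        s_label, a_label = f"S{i:03d}", f"A{i:03d}"
        c_label = f"{s_label}@{a_label}"
        dopant = rng.choice(("C", "Al", "Zn"))
        comp_s = {"C": int(rng.integers(10, 30)), "H": int(rng.integers(6, 15))}
        if dopant != "C":
            comp_s[dopant] = 1
        comp_a = {"C": 1, "H": 2, "O": 1}
        comp_c = {k: comp_s.get(k, 0) + comp_a.get(k, 0) for k in {*comp_s, *comp_a}}

        # frontier structure: complex gap is a planted narrowing of the sensor gap
        homo_s, lumo_s = _frontier(rng, spec)
        homo_a, lumo_a = _frontier(rng, spec)
        gap_s = lumo_s - homo_s
        gap_c = gap_s * rng.uniform(0.2, 0.8)
        homo_c = homo_s + rng.uniform(-0.2, 0.2)
        lumo_c = homo_c + gap_c

        # totals built backwards from planted cohesive and adsorption energies
        e_coh_s = rng.uniform(-160.0, -100.0)  # kcal/mol per atom, reporting sign
        n_s = sum(comp_s.values())
        atom_sum_s = sum(atom_energies[e] * c for e, c in comp_s.items())
        e_total_s = atom_sum_s - n_s * (-e_coh_s) / HARTREE_TO_KCAL
        e_total_a = sum(atom_energies[e] * c for e, c in comp_a.items()) - rng.uniform(0.1, 0.5)
        e_ads = rng.uniform(*spec.eads_range)
        bsse = spec.bsse_scale * rng.uniform(0.5, 1.5)  # Hartree, positive correction
        # noise enters through the reported complex total, so the recovered
        # E_ads is the true value times a multiplicative noise factor
        e_total_c = e_total_s + e_total_a + (noisy(e_ads) - bsse * HARTREE_TO_KCAL) / HARTREE_TO_KCAL

        # electronic response: planted increases upon complexation
        dip_s = rng.uniform(-1.0, 1.0, size=3)
        d_dip = rng.uniform(0.5, 3.0)
        mag_s = float(np.linalg.norm(dip_s))
        dip_c = dip_s * ((mag_s + d_dip) / mag_s)
        pol_s = rng.uniform(250.0, 350.0, size=3)
        d_pol = rng.uniform(5.0, 40.0)
        pol_c = pol_s + d_pol

        # spectra: planted red shift of the strongest line
        lam_s = rng.uniform(300.0, 450.0)
        shift = rng.uniform(20.0, 250.0)
        lam_c = lam_s + shift

        bcp = _draw_bcp(rng, spec.rozas_mix)
        hb = total_energy_density(bcp.v_r, bcp.g_r)

        def _species(label, role, homo, lumo, total, comp, dip=None, pol=None,
                     exci=(), bcps=()):
            h, l = noisy(homo), noisy(lumo)
            if h > l:
                h, l = l, h
            return SpeciesRecord(
                label=label, role=role, phase="water", functional="B97D",
                e_homo=h, e_lumo=l, e_total=total,
                dipole_xyz=None if dip is None else tuple(noisy(x) for x in dip),
                polarizability_diag=None if pol is None else tuple(abs(noisy(x)) for x in pol),
                composition=comp, excitations=list(exci), vib_modes=_vib_modes(rng),
                bcps=list(bcps),
            )

        species.append(
            _species(s_label, "sensor", homo_s, lumo_s, e_total_s, comp_s,
                     dip_s, pol_s, _excitations(rng, lam_s, int(rng.integers(0, 3))))
        )
        species.append(_species(a_label, "analyte", homo_a, lumo_a, e_total_a, comp_a))
        species.append(
            _species(c_label, "complex", homo_c, lumo_c, e_total_c, comp_c,
                     dip_c, pol_c, _excitations(rng, lam_c, int(rng.integers(0, 3))), [bcp])
        )
        links.append(
            ComplexLink(
                complex_label=c_label, host_label=s_label, guest_label=a_label,
                bsse=TaggedEnergy(value=bsse, unit="hartree"),
            )
        )

        sensor_truth = _reactivity_truth(homo_s, lumo_s)
        complex_truth = _reactivity_truth(homo_c, lumo_c)
        cfg = kinetics.KineticsConfig(mode="tabulated")
        rec_time = kinetics.recovery_time(e_ads, cfg)
        systems.append(
            {
                "labels": {"sensor": s_label, "analyte": a_label, "complex": c_label},
                "sensor": sensor_truth,
                "analyte": _reactivity_truth(homo_a, lumo_a),
                "complex": complex_truth,
                "ect": descriptors.ect(sensor_truth["dnmax"], complex_truth["dnmax"]),
                "e_ads": e_ads,
                "bsse_hartree": bsse,
                "e_coh_sensor": e_coh_s,
                "tau": rec_time.tau,
                "log10_tau": rec_time.log10_tau,
                "sigma": kinetics.conductivity(gap_c, cfg),
                "sensor_class": kinetics.classify_sensor_mode(e_ads, rec_time.tau),
                "delta_dipole": d_dip,
                "delta_polarizability": d_pol,
                "lambda_max_sensor": lam_s,
                "lambda_max_complex": lam_c,
                "red_shift_nm": shift,
                "hb": hb,
                "rozas_class": rozas_classify(hb, bcp.lap_rho).category,
            }
        )

    ledger = {
        "spec": spec.model_dump(),
        "atom_energies": atom_energies,
        "systems": systems,
    }
    return SyntheticSet(species=species, links=links, ledger=ledger)
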