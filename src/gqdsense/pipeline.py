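"""End-to-end orchestration: records in, descriptor tables and ranking out.

``run_full_analysis`` takes one block of validated records (one
functional/phase slice), computes every descriptor table the analysis
needs — reactivity, electronic response deltas, energetics/kinetics,
UV summaries, bond-topology classification — then classifies each
complex as reversible sensor / stable detector / weak physisorption and
ranks candidates by binding strength (primary key |E_ads|, tie-broken by
gap narrowing |dHLG| then dipole gain). Outputs are plain CSV/JSON and
byte-identical across reruns of the same inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import descriptors, kinetics, spectra, topology
from .energetics import adsorption_energy_for_link
from .errors import GqdError
from .records import ComplexLink, SpeciesRecord


@dataclass(frozen=True)
class RunConfig:
    """Options for one analysis run."""

    mode: str = "tabulated"  # kinetics mode: paper | physical
    temperature: float = 298.0
    eads_override: Optional[Mapping[str, float]] = None  # kcal/mol per complex label
    output_dir: Optional[Path] = None


@dataclass
class ReportBundle:
    """All tables produced by one run, plus the candidate ranking."""

    reactivity: pd.DataFrame
    response: pd.DataFrame
    energetics: pd.DataFrame
    uv: pd.DataFrame
    topology: pd.DataFrame
    ranking: list[dict] = field(default_factory=list)
    constants: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)


def _stage(failures: list[dict], name: str, label: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                failures.append({"stage": name, "record": label, "error": str(exc)})
                return True  # recorded; continue with partial outputs
            return False

    return _Ctx()


def run_full_analysis(
    species: list[SpeciesRecord],
    links: list[ComplexLink],
    cfg: RunConfig = RunConfig(),
) -> ReportBundle:
    if not species:
        raise GqdError("no input records: nothing to analyze")
    by_label = {rec.label: rec for rec in species}
    kcfg = kinetics.KineticsConfig(mode=cfg.mode, temperature=cfg.temperature)
    failures: list[dict] = []

    reactivity = descriptors.reactivity_table(species, links)

    resp_rows, energy_rows, uv_rows, topo_rows = [], [], [], []
    for link in links:
        comp = by_label[link.complex_label]
        host = by_label[link.host_label]

        with _stage(failures, "response", link.complex_label):
            d_dip, d_pol = descriptors.adsorption_deltas(host, comp)
            resp_rows.append(
                {
                    "label": comp.label,
                    "dipole_sensor": descriptors.dipole_magnitude(host.dipole_xyz),
                    "dipole_complex": descriptors.dipole_magnitude(comp.dipole_xyz),
                    "delta_dipole": d_dip,
                    "polarizability_sensor": descriptors.mean_polarizability(host.polarizability_diag),
                    "polarizability_complex": descriptors.mean_polarizability(comp.polarizability_diag),
                    "delta_polarizability": d_pol,
                }
            )

        with _stage(failures, "energetics", link.complex_label):
            if cfg.eads_override and comp.label in cfg.eads_override:
                e_ads = float(cfg.eads_override[comp.label])
            else:
                e_ads = adsorption_energy_for_link(link, by_label).e_ads
            rec_time = kinetics.recovery_time(e_ads, kcfg)
            gap = descriptors.hlg(comp.e_homo, comp.e_lumo)
            host_gap = descriptors.hlg(host.e_homo, host.e_lumo)
            energy_rows.append(
                {
                    "label": comp.label,
                    "e_ads": e_ads,
                    "bsse": link.bsse.value,
                    "bsse_unit": link.bsse.unit,
                    "tau_s": rec_time.tau,
                    "log10_tau": rec_time.log10_tau,
                    "sigma": kinetics.conductivity(gap, kcfg),
                    "sigma_sensor": kinetics.conductivity(host_gap, kcfg),
                    "delta_hlg": gap - host_gap,
                    "classification": kinetics.classify_sensor_mode(e_ads, rec_time.tau),
                    "mode": cfg.mode,
                }
            )

        with _stage(failures, "spectra", link.complex_label):
            if host.excitations and comp.excitations:
                ref = spectra.uv_summary(host.label, host.excitations)
                summ = spectra.uv_summary(comp.label, comp.excitations, reference=ref)
                uv_rows.append(
                    {
                        "label": comp.label,
                        "lambda_max_sensor": ref.lambda_max,
                        "lambda_max_complex": summ.lambda_max,
                        "red_shift_nm": summ.shift_vs_reference,
                        "eex_complex": spectra.eex_from_lambda(summ.lambda_max),
                    }
                )

        with _stage(failures, "topology", link.complex_label):
            for idx, bcp in enumerate(comp.bcps):
                hb = topology.total_energy_density(bcp.v_r, bcp.g_r)
                cls = topology.rozas_classify(hb, bcp.lap_rho)
                topo_rows.append(
                    {
                        "label": comp.label,
                        "bcp_index": idx,
                        "rho": bcp.rho,
                        "lap_rho": bcp.lap_rho,
                        "hb": hb,
                        "category": cls.category,
                        "outside_scheme": cls.outside_scheme,
                    }
                )

    energy_df = pd.DataFrame(energy_rows)
    resp_df = pd.DataFrame(resp_rows)

    ranking: list[dict] = []
    if not energy_df.empty:
        keyed = energy_df.copy()
        keyed["abs_eads"] = keyed["e_ads"].abs()
        keyed["abs_dhlg"] = keyed["delta_hlg"].abs()
        dmu = dict(zip(resp_df.get("label", []), resp_df.get("delta_dipole", [])))
        keyed["delta_dipole"] = keyed["label"].map(dmu).fillna(0.0)
        keyed = keyed.sort_values(
            by=["abs_eads", "abs_dhlg", "delta_dipole"], ascending=False, kind="mergesort"
        )
        ranking = [
            {
                "rank": i + 1,
                "label": row.label,
                "e_ads": row.e_ads,
                "classification": row.classification,
            }
            for i, row in enumerate(keyed.itertuples())
        ]

    bundle = ReportBundle(
        reactivity=reactivity,
        response=resp_df,
        energetics=energy_df,
        uv=pd.DataFrame(uv_rows),
        topology=pd.DataFrame(topo_rows),
        ranking=ranking,
        constants={
            "mode": cfg.mode,
            "temperature_K": cfg.temperature,
            "attempt_frequency_s-1": kcfg.nu0,
            "kBT_kcal_mol": kinetics.thermal_energy_kcal(cfg.temperature),
            "hc_eV_nm": spectra.HC_EV_NM,
        },
        failures=failures,
    )
    if cfg.output_dir is not None:
        write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    """Write every table as CSV plus ranking/constants/failures as JSON."""
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("reactivity", "response", "energetics", "uv", "topology"):
        getattr(bundle, name).to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "ranking.json").write_text(json.dumps(bundle.ranking, indent=2) + "\n")
    (outdir / "constants.json").write_text(json.dumps(bundle.constants, indent=2) + "\n")
    manifest = {"failures": bundle.failures, "complete": not bundle.failures}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
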