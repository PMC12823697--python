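# gqdsense

Descriptor analysis for doped graphene-quantum-dot gas sensors.

`gqdsense` post-processes quantum-chemistry summary records — frontier
orbital energies, total energies, dipole/polarizability tensors, TD-DFT
excitation lists, vibrational lines and bond-critical-point scalars — into
the descriptor suite used to rank candidate sensor/adsorbent materials for
small-analyte (here: formaldehyde on pristine, Al-doped and Zn-doped
coronene) detection. It is aimed at computational chemists who already have
electronic-structure output and want a reproducible, unit-safe, tested
pipeline for the *analysis* layer; it never runs electronic structure
itself.

## What it computes

From the HOMO/LUMO energies (eV) of each species:

- gap `HLG = |E_HOMO − E_LUMO|`, chemical hardness `η = (E_LUMO − E_HOMO)/2`,
  softness `S = 1/2η`, chemical potential `µ = (E_HOMO + E_LUMO)/2`,
  maximum charge acceptance `ΔN_max = −µ/η`, and the charge transfer
  `ECT = ΔN_max(sensor) − ΔN_max(complex)` (negative ⇒ the analyte donates
  charge to the surface).

From total energies (Hartree) and a unit-tagged counterpoise correction:

- cohesive energy per atom `E_Coh = (Σᵢ Eᵢᵃᵗᵒᵐ − E_total)/n` (reported with
  the more-negative-is-more-stable sign), and the BSSE-corrected adsorption
  energy `E_ads = E_complex − (E_host + E_guest) + E_BSSE` in kcal/mol.

From `E_ads` and the complex gap `E_g`:

- transition-state-theory recovery time `τ = ν₀⁻¹ exp(−E_ads/k_BT)` and the
  Richardson-type conductivity proxy `σ = A T^{3/2} exp(−E_g/2kT)`, each in
  a table-faithful `tabulated` mode and a dimensionally consistent `physical`
  mode (see `docs/methods.md` for why the two differ), plus a
  reversible-sensor / stable-detector / weak-physisorption classification.

Also: UV λmax summaries and adsorption-induced red shifts, Gaussian/
Lorentzian line broadening for DOS/IR-style curves, QTAIM total energy
density `H_b = V(r) + G(r)` with the Rozas interaction classification and
NCI `sign(λ₂)ρ` banding, and Kendall-style rank-concordance / sign-agreement
statistics for cross-functional trend checks. A seeded synthetic-record
generator with a planted-truth ledger makes the whole pipeline testable
without any electronic-structure engine.

## Worked example

```python
from gqdsense import reference_fixture_set, run_full_analysis, RunConfig

fx = reference_fixture_set()                      # bundled golden tables
key = ("B97D", "water")
eads = {r.label: r.eads for r in fx.energetics
        if (r.functional, r.phase) == key and r.eads is not None}
bundle = run_full_analysis(fx.species_blocks[key], fx.link_blocks[key],
                           RunConfig(eads_override=eads))
print(bundle.energetics[["label", "e_ads", "tau_s", "sigma", "classification"]])
print(bundle.ranking[0])
```

prints

```
         label  e_ads        tau_s        sigma            classification
   Coronene@FA  -4.01 8.726423e-14 2.150796e+09        weak_physisorption
Zn.Coronene@FA  -6.16 3.293016e-12 2.427635e+09         reversible_sensor
Al.Coronene@FA -39.57 1.046341e+13 2.852961e+09 stable_detector_adsorbent

{'rank': 1, 'label': 'Al.Coronene@FA', 'e_ads': -39.57,
 'classification': 'stable_detector_adsorbent'}
```

Read: the pristine complex binds formaldehyde too weakly (−4.01 kcal/mol) to
be a robust sensor; the Zn-doped complex binds moderately and desorbs in
picoseconds, making it the reversible-sensing candidate; the Al-doped
complex binds so strongly (−39.57 kcal/mol, τ ≈ 10¹³ s) that it is a
permanent detector/adsorbent — and its near-closed gap (0.39 eV) gives it
the highest conductivity response, 2.85×10⁹ A m⁻².

The same pipeline runs from the shell:

```sh
gqdsense report --out report/                      # bundled fixtures
gqdsense simulate --seed 7 --n-systems 20 --out synth.yaml
gqdsense report --input synth.yaml --out synth-report/
gqdsense kinetics --e-ads -6.16 --gap 1.19
```

Input records use a small YAML interchange schema documented in
`docs/record_schema.md`.

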