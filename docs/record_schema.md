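# Record interchange schema

`gqdsense` reads and writes one YAML document per study slice (one
functional / one phase). Full electronic-structure log parsing is out of
scope by design: any converter (e.g. a short cclib script) can emit this
schema, which carries only the ~15 scalars per species that the analysis
consumes.

## Document layout

```yaml
species:
  - label: Coronene            # unique within the document
    role: sensor               # sensor | analyte | complex | atom
    phase: water               # water | gas
    functional: B97D           # free-form method tag
    e_homo: -5.26              # eV
    e_lumo: -2.40              # eV
    e_total: -921.437210       # Hartree (optional)
    zpe: 0.268                 # Hartree (optional)
    dipole_xyz: [0.0, 0.0, 0.0]          # Debye components (optional)
    polarizability_diag: [311.58, 311.58, 311.58]  # a.u. (optional)
    composition: {C: 24, H: 12}          # element -> positive count
    excitations:                         # optional TD-DFT line list
      - {lambda_nm: 338.0, e_ex: 3.66, f_osc: 0.478}
    vib_modes:                           # optional IR line list
      - {freq_cm1: 3052.0, intensity: 41.0}
    bcps:                                # optional bond-critical-point scalars (a.u.)
      - {rho: 0.0098, lap_rho: -0.0081, v_r: 0.0066, g_r: -0.0015}
    coordinates:                         # optional, Å
      - [C, 0.0, 0.0, 0.0]

complexes:
  - complex_label: Coronene@FA
    host_label: Coronene
    guest_label: FA
    bsse: {value: 0.0017, unit: hartree}   # unit tag is mandatory
```

## Units and validation

- Frontier energies are eV; totals and ZPE are Hartree; dipoles Debye;
  polarizabilities atomic units; wavelengths nm; vibrations cm⁻¹.
  Counterpoise corrections always carry an explicit unit tag
  (`hartree`, `ev`, `kcal/mol`, `kj/mol`).
- `e_homo > e_lumo` is a validation error; composition counts must be
  positive; polarizability entries must be positive.
- Excitation lines are soft-checked against `E = hc/λ` (hc = 1239.84
  eV·nm) within 0.2 eV; violations warn but do not fail, because
  tabulated energies and wavelengths are often rounded independently.
- Bond-critical-point records default to `convention: printed`
  (tabulated values accepted verbatim); `convention: physical` enforces
  G(r) > 0 and V(r) < 0 and is what the synthetic generator emits.
- Duplicate species labels are rejected; each complex link must resolve
  all three labels to records sharing one phase and one functional.

`write_records(read_records(doc))` round-trips every field at full float
precision.
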