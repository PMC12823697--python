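# Methods

## Scope and model

`gqdsense` implements the *analysis* layer of a descriptor-based screening
study for gas-sensing nanomaterials: given per-species quantum-chemistry
summaries (a sensor surface, an analyte, and their adsorption complex, per
functional and solvation phase), it derives energetic, reactivity, kinetic,
transport, spectral and bond-topology descriptors and ranks the candidates.
Everything upstream — geometry optimization, TD-DFT, wavefunction topology
searches — is out of scope; those stages' scalar outputs are the package's
inputs.

Core relations (frontier energies in eV):

- `HLG = |E_HOMO − E_LUMO|`, `η = (E_LUMO − E_HOMO)/2`, `S = 1/2η`,
  `µ = (E_HOMO + E_LUMO)/2`, `ΔN_max = −µ/η`.
- `ECT = ΔN_max(sensor) − ΔN_max(complex)`. The donor/acceptor wording in
  the conceptual-DFT literature is ambiguous about orientation; this
  orientation is fixed empirically because it reproduces the bundled
  reference values (a negative ECT then means the analyte donates charge).
- `E_Coh = (Σᵢ Eᵢᵃᵗᵒᵐ − E_total)/n`, converted to kcal/mol. As written the
  expression is positive for bound systems; the default reporting
  convention negates it so that more negative ⇒ more stable, matching how
  cohesive energies are conventionally quoted. Isolated-atom reference
  energies are user-supplied inputs (they depend on the upstream method and
  spin state), never computed here.
- `E_ads = E_complex − (E_host + E_guest) + E_BSSE`, in kcal/mol, with the
  counterpoise term carried as a tagged quantity because its unit is easy
  to lose (values around 0.002 are Hartree-scale, ≈ 1–2 kcal/mol; Hartree
  is the default interpretation, configurable).
- `τ = ν₀⁻¹ exp(−E_ads/k_BT)` and `σ = A T^{3/2} exp(−E_g/2kT)` with
  A = 6×10⁵ A m⁻² K⁻³ᐟ², T defaulting to 298 K.
- `H_b = V(r) + G(r)` at each bond critical point; Rozas classification on
  the signs of (H_b, ∇²ρ); NCI classification of sign(λ₂)ρ against a ±0.01
  a.u. van-der-Waals band (a conventional scale, configurable).
- Trend agreement between method/phase slices: Kendall-style pair counting
  `(concordant − discordant)/all pairs`, ties counted as neither. No tie
  correction is applied — at n = 3–6 systems a tau-b style correction adds
  nothing defensible — and no significance testing is offered for the same
  reason.

## The "tabulated" vs "physical" kinetics modes

The bundled reference tables for τ and σ cannot be reproduced from the
formulas above with the constants as stated alongside them. Two
reconstructions, verified cell-by-cell in the acceptance suite, are needed:

1. **Attempt frequency.** The stated ν₀ = 10¹² s⁻¹ misses every tabulated τ
   by four orders of magnitude; ν₀ = 10¹⁶ s⁻¹ reproduces all nine complex
   rows within a few percent. `mode="tabulated"` therefore uses 10¹⁶ s⁻¹.
2. **Conductivity exponent.** The tabulated σ values are reproduced (to 3
   significant figures, all twelve dispersion-functional rows) only when
   the gap in eV is divided by 2·k_B·T expressed in kJ/mol (4.9554 at
   298 K) — a unit inconsistency implemented verbatim for fixture
   fidelity.

`mode="physical"` is the dimensionally consistent alternative: ν₀ = 10¹²
s⁻¹ as stated, and the Boltzmann factor with gap and 2k_BT both in eV
(which suppresses σ to ~10⁻¹⁵ A m⁻² for eV-scale gaps — the proxy is then
only useful for *relative* comparisons). Every emitted kinetics row carries
its mode tag, and the pipeline logs the constants actually used
(ν₀, k_BT, hc) so runs are auditable.

Sensor classification thresholds: τ ≥ 1 s ⇒ stable detector/adsorbent;
otherwise |E_ads| < 5 kcal/mol ⇒ weak physisorption, else reversible
sensor. The 1 s / 5 kcal/mol cutpoints are package choices that separate
the three qualitative regimes the reference systems span (τ from 10⁻¹³ s to
10¹³ s); both are keyword-configurable.

## Golden fixtures and flagged cells

The bundled tables store printed values verbatim as strings (so the printed
precision is known) and are compared at one unit in the last printed digit,
computing all derived columns from unrounded intermediates and rounding
half-away-from-zero only for comparison — the source tables mix truncation
and rounding (e.g. S = 0.2577 printed as 0.25), so a pure-rounding
comparison would generate false mismatches. Four groups of cells are
flagged as internally inconsistent and excluded from golden matching rather
than silently accepted: one complex-row ECT whose printed sign disagrees
with its own frontier energies; the range-separated functional's σ rows
(≈10× the model's reconstruction from their own gaps); two excitation lines
violating E = hc/λ by > 0.03 eV; and the undefined "VIR" column, which is
loaded opaquely and never computed. Bond-critical-point rows keep their
printed sign pattern even where unphysical (V > 0, G < 0 in places), so
H_b comparisons run through |V+G| vs |H_b|.

λmax is taken as the highest-oscillator-strength line of a spectrum (the
alternative — lowest-energy reported line — is not used; the strongest line
is what an absorbance maximum measures).

## Synthetic generator

`generate_sensor_set` emulates a study slice without any electronic
structure: for each system it draws a sensor (HOMO uniform in [−10, −4] eV,
gap in (0.2, 4.0] eV), an analyte, and a complex with a planted gap
narrowing (20–80 % of the sensor gap), planted dipole (+0.5–3 D) and
polarizability (+5–40 a.u.) increases, a planted UV red shift (20–250 nm,
with E = hc/λ exact on every line), vibrational modes all real, and one
bond critical point drawn from a requested mixture of Rozas classes with
physical signs (G > 0, V < 0). Total energies are constructed backwards
from a planted adsorption energy (uniform in [−45, −4] kcal/mol, spanning
weak physisorption to strong chemisorption) and a positive counterpoise
term (~0.002 Hartree), so the energy balance recovers E_ads to ≈10⁻¹⁰
kcal/mol (the Hartree round trip costs a few ulps); isolated-atom reference
energies are drawn per element and stored in the ledger. All draws come
from one seeded generator (default seed 20251213) in a fixed stream order,
so identical specs produce byte-identical record sets.

Noise (`noise_sd`) multiplies reported values by 1 + σ·N(0,1) relative
factors — frontier energies (re-ordered if perturbation inverts them),
dipole and polarizability components, and the adsorption energy through the
complex total — so recovered quantities are unbiased on the relative scale.

What the generator does *not* emulate: correlated errors between
descriptors, realistic spectral line shapes or intensities, geometry, or
any relationship between composition and electronic structure. Passing the
recovery tests therefore demonstrates that the pipeline's arithmetic,
unit handling and plumbing are correct — not that the descriptors
themselves are accurate for real materials.

## Numerical choices

- Conversion constants, fixed in one module: 1 Hartree = 627.5095 kcal/mol
  = 27.2114 eV; k_B = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹; hc = 1239.84 eV·nm.
- τ is computed in the log domain and reported with log₁₀τ alongside, so
  strongly bound systems (exponents > 700) never overflow.
- Hardness below 10⁻⁹ eV is treated as degenerate (softness and ΔN_max
  raise rather than divide by ~0).
- Broadening kernels (Gaussian σ = FWHM/2.3548, Lorentzian γ = FWHM/2) are
  unit-area, so the curve integral approximates the summed stick
  intensities; defaults 0.3 eV Gaussian for DOS, 8 cm⁻¹ Lorentzian for IR,
  1000 grid points — presentation defaults only.
- DOS gaps from overlapping level sets floor at 0 with a warning rather
  than going negative.
- The (H_b < 0, ∇²ρ > 0) sign quadrant falls outside the Rozas scheme; it
  maps to the nearest grade (medium/electrostatic) with an
  `outside_scheme` flag instead of raising.
- Ranking key: primary |E_ads|, tie-broken by |ΔHLG| then Δµ (binding
  strength first, then electronic response), with a stable sort so equal
  candidates keep input order.

## Problem sizes

The test and acceptance workloads are desk-scale by construction: 21
fixture rows per descriptor table, 6 bond-critical-point rows, 20 lines of
UV data, synthetic sets of 20–100 systems, and 1000 short random lists for
the concordance oracle. The full suite runs in a few seconds.

## Known limitations

- E_ads for the reference systems is an input, not an output: the study's
  total energies are not tabulated, so the headline adsorption energies
  cannot be recomputed, only propagated (the synthetic generator covers the
  recomputation path instead).
- The conductivity proxy's paper mode reproduces a unit inconsistency by
  design; its absolute values should not be compared across modes.
- Single-determinant frontier-orbital descriptors are qualitative trend
  indicators, not band structure; the package inherits that interpretive
  limit from its inputs.
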