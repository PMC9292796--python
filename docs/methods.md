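# Methods

`scavkin` turns tabulated Gibbs free energies of elementary
radical-scavenging reactions into solution-phase rate constants, branching
ratios and overall antioxidant activities. This note records the model, the
parameters that matter, the numerical choices, and what the bundled and
synthetic datasets can and cannot demonstrate.

## The kinetic model

A scavenging *channel* is one elementary reaction of an antioxidant with a
reactive oxygen species via one mechanism — hydrogen atom transfer (HAT),
radical adduct formation (RAF), single electron transfer (SET) or direct
oxidation of the chalcogen centre (OX) — at one molecular site in one
solvent. Its inputs are the activation free energy ΔG‡ and reaction free
energy ΔG_r in kcal mol⁻¹, typically produced upstream by a DFT +
continuum-solvation workflow (which is entirely outside this package).

Per channel the pipeline evaluates:

1. **Solution-phase corrections.** Quantum-chemical free energies refer to
   the 1 atm ideal-gas standard state. Two corrections convert a
   bimolecular barrier to the 1 M solution convention:
   the standard-state term −(m−1)·RT·ln(V_M) with V_M = RT/P = 24.465
   L mol⁻¹ at 298.15 K (−1.894 kcal mol⁻¹ for m = 2), and a solvent-cage
   term −RT·[ln(n·10^{2(n−1)}) − (n−1)] (−2.547 kcal mol⁻¹ for n = 2)
   accounting for the reduced entropy loss of forming an encounter complex
   inside a solvent cage. Together they are worth a factor
   exp(4.441/RT) = V_M·200/e ≈ 1.80·10³ on a bimolecular rate constant;
   omitting them under-estimates rates by exactly that factor. Both vanish
   for unimolecular steps. Tabulated barriers are treated as *uncorrected*
   and the corrections are applied inside the pipeline; with them applied,
   the activation-controlled electron-transfer cells of the bundled
   dataset reproduce the published rate constants to within the input
   rounding, and without them they are ~1800× too small.

2. **Tunneling.** The Wigner transmission coefficient
   κ = 1 + (1/24)(hcν‡/k_BT)², from the magnitude ν‡ (cm⁻¹) of the
   transition-state imaginary frequency. κ defaults to 1 when no frequency
   is available — absent data must not invent tunneling — and frequencies
   can be injected per channel through the configuration.

3. **Eyring–Polanyi TST.** k = κ·(k_BT/h)·exp(−ΔG‡/RT); at 298.15 K the
   prefactor is 6.212·10¹² s⁻¹. In the 1 M convention the same number is
   read as M⁻¹ s⁻¹ for bimolecular channels.

4. **Marcus theory (SET).** Electron transfer has no nuclear saddle point;
   its barrier is ΔG‡ = (λ/4)(1 + ΔG_r/λ)² with reorganization energy λ.
   The channel is in the *inverted* region when |ΔG_r| > λ (exergonicity
   beyond the reorganization energy raises the barrier). Because published
   tables print ΔG‡ but rarely λ, `infer_lambda` inverts the quadratic
   λ² + (2ΔG_r − 4ΔG‡)λ + ΔG_r² = 0 and labels each admissible root by
   region. The small root is computed as ΔG_r²/λ_big to avoid the
   catastrophic cancellation the direct quadratic formula suffers when
   λ ≪ |ΔG_r|.

5. **Diffusion.** The Smoluchowski steady-state encounter rate
   k_D = 4π·R_AB·(D_A + D_B)·N_A with Stokes–Einstein coefficients
   D_X = k_BT/(6πηa_X). Reported in M⁻¹ s⁻¹ (×10³ from m³ mol⁻¹ s⁻¹).

6. **Collins–Kimball coupling.** k_app = k_D·k/(k_D + k), the harmonic
   interpolation between activation and diffusion control. A channel is
   flagged diffusion-controlled when k ≥ θ·k_D (θ = 1 by default).

Per (antioxidant, radical, medium) context the mechanism-level rate is the
degeneracy-weighted sum over that mechanism's channels, branching ratios
are Γ_i = 100·k_i/Σk_j, and the overall activity is the plain sum. A
mechanism cell is reported diffusion-controlled when any member channel is
or when its *summed* thermal rate reaches the shared encounter rate — a
six-site addition mechanism can saturate diffusion collectively even
though no single site does.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| temperature | 298.15 | K | the reference tables are reported at 298.15 K; overridable per medium |
| V_M | RT/P at T, 1 atm (24.465 at 298.15 K) | L mol⁻¹ | ideal-gas molar volume for the 1 atm → 1 M conversion |
| viscosity (water) | 8.91·10⁻⁴ | Pa s | literature value at 298.15 K (not printed with the energy tables) |
| viscosity (pentyl ethanoate) | 8.62·10⁻⁴ | Pa s | literature value at 298.15 K |
| Stokes radii | per species; 2.0 Å (radicals) / 4.0 Å (antioxidants) when unregistered | m | sphere-equivalent estimates; every substitution is logged |
| reaction distance R_AB | a_A + a_B (contact) | m | standard Smoluchowski choice; overridable per (pair, mechanism, medium) |
| κ | 1 unless a frequency is supplied | — | tunneling only matters for light-atom transfer (HAT); no invented data |
| σ | 2 on ring sites, 1 on the amino site / site-free mechanisms | — | two symmetry-equivalent benzo rings |
| diffusion threshold θ | 1.0 | — | flag semantics k_thermal ≥ k_D |

**Degeneracy convention.** By default σ multiplies the *thermal* rate
before Collins–Kimball coupling: each symmetric site is an independent
reactive funnel sharing one encounter pair. The alternative (σ outside the
coupling, `sigma_convention="post"`) is a configuration switch. The two
conventions differ only near the diffusion limit; the published mechanism
sums are consistent with degeneracy-weighted site sums, but the source
material does not pin the convention down, so the ambiguity is explicit.

**Clamping.** A corrected barrier that comes out negative (barrierless
channels) is clamped to zero rather than extrapolating super-prefactor
rates: κ·k_BT/h is the physical ceiling and the diffusion cap handles the
rest. The clamp is recorded on the result and can be disabled.

## The bundled dataset and its calibration

The package ships the complete free-energy dataset for the phenothiazine
scaffold and its Se/Te analogues (PS, PSE, PTE) against HO•, HOO• and
CH₃OO• in water and pentyl ethanoate — 228 channels (156 with barriers;
the aromatic-site HAT rows are thermodynamics-only, as published) — plus
the published apparent rate constants and branching ratios they produced.
Files are checksummed; energies are transcribed at the printed 0.1
kcal mol⁻¹, so the honest error budget is ±0.05 kcal mol⁻¹ per energy,
i.e. ±exp(0.05/RT) ≈ ±9 % per Boltzmann factor. One printed cell (PTE,
RAF site 5a, water ΔG_r) has a garbled decimal separator and is encoded
as −38.7 with a note in the fixture metadata. RAF at the Te 5a junction
opens the central ring; those channels are flagged and still counted in
mechanism sums by default (`include_ring_opening=False` excludes them).

**Diffusion calibration.** The published diffusion-controlled rates
(~2.6·10⁹ M⁻¹ s⁻¹ for the barrierless water HAT channels) lie *below* the
floor that contact-distance Smoluchowski/Stokes–Einstein theory permits in
water — with R_AB = a_A + a_B the closed form
k_D = (2k_BT·N_A/3η)·(a+b)²/(ab) ≥ 8k_BT·N_A/(3η) ≈ 7.4·10⁹ M⁻¹ s⁻¹
regardless of the radii. The published values therefore imply effective
reaction distances shorter than contact (plausibly transition-state
separations), which were never published. At load time the package fits
one effective R_AB per published diffusion-controlled mechanism cell by
root-finding Σᵢ k_D·kᵢ/(k_D + kᵢ) = k_published over the cell's channels
(Brent's method on log₁₀k_D, then R_AB = k_D/(4π·D_AB·N_A); the fitted
distances come out at 1.5–2.5 Å). Consequences, stated plainly:

* those cells are *calibrated*, not predicted — they are excluded from any
  claim of reproduction and marked as such in the diff report;
* `DiffusionInputs` accepts sub-contact reaction distances (with an
  informational log message) instead of rejecting them;
* one calibrated cell (water SET, PTE+CH₃OO•) has a published rate at
  ~61 % of its thermal ceiling, which forces the fitted k_D *above*
  k_thermal; its rate reproduces exactly but its published
  diffusion-controlled footnote cannot be recovered under the
  k_thermal ≥ k_D flag definition. This is asserted, not hidden.

**Robustness classes** in the reproduction diff:

* `robust` (31 cells): activation-controlled SET cells (pure
  corrected-Eyring numbers; they recompute within 0.88–1.08× of print,
  inside the ±9 % input-rounding budget plus coupling slack) and all
  overall rows and branching ratios, which are arithmetic on published
  values;
* `calibrated` (23 cells): everything printed with the
  diffusion-controlled footnote;
* `not-reproducible` (18 cells): activation-controlled HAT and RAF cells.
  The lipid HAT cells require transition-state imaginary frequencies that
  were never published (the printed rates imply κ ≈ 7); the RAF cells
  additionally carry a ~2–3× gap against the σ = 2, κ = 1 reconstruction
  whose origin (unprinted tunneling, unrounded barriers, or a different σ
  convention) cannot be resolved from the published material. Recomputed
  values land at 0.1–0.45× of print.

The qualitative mechanism map survives recomputation: RAF dominates
hydroxyl scavenging in water for all three scaffolds, HAT dominates
peroxyl scavenging for the S and Se scaffolds, SET for the Te scaffold,
and SET contributes 0 % in the lipid medium everywhere.

## The synthetic generator

`scavkin.synthetic` draws seeded channel tables with the reference data's
*structure* so every pipeline stage is testable without the bundled
dataset: amino-site HAT exergonic (ΔG_r ∈ [−40, −2]) and barrierless in
the polar medium, aromatic HAT endergonic for peroxyl-class radicals and
thermodynamics-only (the reference data prints no aromatic barriers), ring
sites doubly degenerate, SET barriers in [0, 15] kcal mol⁻¹ in the polar
medium versus [40, 66] in the lipid one (which freezes lipid SET below
10⁻¹⁰ M⁻¹ s⁻¹), and each SET channel carrying a reorganization energy
consistent with its (ΔG_r, ΔG‡) pair via the Marcus inverse. Draws are
uniform within the table-derived ranges — the source data supports no
richer distributional model, and this is a modelling choice, not an
inference. One integer seed determines everything; there is no global
random state.

Ground truth is computed by `brute_force_k_app`, a closed-form
single-expression evaluation of the entire chain sharing no code path
with the staged pipeline; the property suite requires agreement to 10⁻¹²
relative on ≥1000 seeded channels. A perturbation harness adds uniform
±δ noise to all free energies and verifies the documented sensitivity:
δ = 0.05 kcal mol⁻¹ moves every rate by at most ×/÷ exp(0.05/RT) = 1.088
(activation-controlled channels attain the bound; clamped or
diffusion-capped ones move less).

What passing synthetic tests does *not* show: the generator has no
correlated chalcogen trends, no correlation between ΔG_r and ΔG‡ within a
mechanism (real barriers track reaction energies), and no solvent effects
beyond the range shifts — it validates the kinetics arithmetic, not any
chemistry.

## Numerical choices

* CODATA constants; the gas constant in kcal mol⁻¹ K⁻¹ uses the
  thermochemical calorie (4.184 J). Energies stay kcal mol⁻¹ floats
  end-to-end (no unit-registry layer); diffusion works in SI internally.
* The Marcus inverse uses the product-of-roots form for the small root
  (see above); round-tripping is property-tested to 10⁻⁹.
* Calibration root-finding brackets log₁₀k_D in [−3, 30] with Brent's
  method; cells whose summed thermal rate falls below the published value
  admit no solution and are left uncalibrated.
* Branching ratios are kept exact internally and rounded half-away-from-
  zero to integer percent in reports; an all-zero context has no defined
  branching and is rejected.
* Reports carry rates at 3 significant figures; machine (JSON) output
  keeps full double precision. No output embeds timestamps, so identical
  inputs give byte-identical files.

## Known limitations

* No Eckart or small-curvature tunneling, no variational TST; Wigner only.
* Neutral reactants only: no ionic-strength or electrostatic corrections
  to the diffusion rate.
* No multi-antioxidant mixture kinetics and no time-course integration;
  the outputs are elementary rate constants and their ratios.
* Species are opaque labels with scalar properties — no structures, no
  chemical file formats, no recomputation of the upstream electronic
  structure or solvation energies.
* The activation-controlled HAT/RAF cells of the bundled dataset are
  reproducible only up to the unpublished tunneling/degeneracy information
  discussed above; treat those recomputed values as lower bounds.
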