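# scavkin

Radical-scavenging kinetics from quantum-chemical free energies.

Antioxidant molecules quench reactive oxygen species (HO•, HOO•, CH₃OO•,
…) through several competing elementary mechanisms: hydrogen atom transfer
(HAT), radical adduct formation (RAF), single electron transfer (SET) and
direct oxidation of a chalcogen centre. Electronic-structure workflows
produce Gibbs free energies of activation and reaction for each channel;
turning those into *observable* solution-phase rate constants requires a
chain of kinetic corrections that is easy to get subtly wrong. `scavkin`
implements that chain as a reusable, tested pipeline for computational
chemists benchmarking scavengers:

* 1 atm → 1 M standard-state and solvent-cage corrections,
  ΔG‡(sol) = ΔG‡ − (m−1)RT ln V_M − RT[ln(n·10^{2(n−1)}) − (n−1)]
  (worth a factor V_M·200/e ≈ 1.80·10³ on a bimolecular rate constant);
* Eyring–Polanyi TST, k = κ(k_BT/h)e^{−ΔG‡/RT}, with the Wigner tunneling
  coefficient κ = 1 + (1/24)(hcν‡/k_BT)²;
* Marcus theory for electron transfer, ΔG‡ = (λ/4)(1 + ΔG_r/λ)², including
  inverted-region classification and inversion of the quadratic to recover
  admissible reorganization energies λ from tabulated barriers;
* Smoluchowski/Stokes–Einstein diffusion limits
  k_D = 4πR_AB(D_A + D_B)N_A and Collins–Kimball coupling
  k_app = k_D·k/(k_D + k);
* mechanism-level sums with reaction-path degeneracy, branching ratios
  Γ_i = 100·k_i/Σk_j and overall scavenging activity.

The package ships the complete published free-energy dataset for the
phenothiazine scaffold and its selenium/tellurium analogues (PS, PSE, PTE)
against HO•, HOO• and CH₃OO• in water and in pentyl ethanoate, together
with the published rate constants, and a reproduction harness that reruns
the whole pipeline against them. A seeded synthetic generator with an
independent closed-form oracle makes every stage testable without the
bundled data. See [docs/methods.md](docs/methods.md) for the model,
defaults, calibration and limitations.

## Worked example

Electron transfer from phenoselenazine to the hydroperoxyl radical in
water: the table barrier is 11.2 kcal mol⁻¹, the solution-phase
corrections take it to 6.759, and Collins–Kimball coupling against the
encounter rate barely trims the thermal rate:

```python
from scavkin import Mechanism, compute_channel_rate
from scavkin.dataset import load_fixture, calibrated_config

fixture = load_fixture()
config = calibrated_config(fixture)
channel = next(
    c for c in fixture.channel_set.channels
    if (c.antioxidant, c.radical, c.medium) == ("PSE", "HOO", "water")
    and c.mechanism is Mechanism.SET
)
r = compute_channel_rate(channel, fixture.channel_set, config)
print(f"barrier {r.dG_act_corrected:.3f} kcal/mol  "
      f"k_thermal {r.k_thermal:.3e}  k_D {r.k_D:.3e}  "
      f"k_app {r.k_app:.3e} M^-1 s^-1")
```

prints

```
barrier 6.759 kcal/mol  k_thermal 6.901e+07  k_D 8.073e+09  k_app 6.842e+07 M^-1 s^-1
```

i.e. k_app = 6.84·10⁷ M⁻¹ s⁻¹ against the published 7.02·10⁷ (−2.6 %,
well inside the ±9 % budget implied by the 0.1 kcal mol⁻¹ printing
precision of the input barrier). The same call on the lipid-phase
channels lands at 7.06·10⁻¹⁵ (PSE + HO•, published 6.84·10⁻¹⁵): electron
transfer is frozen out in the apolar medium.

The full reproduction, from the command line:

```
$ scavkin reproduce --out repro/
reproduction summary
====================
          robust:  31 cells, median recomputed/published = 1.000
      calibrated:  23 cells, median recomputed/published = 1.000
not-reproducible:  18 cells, median recomputed/published = 0.387

PASS  raf_dominates_hydroxyl_in_water
PASS  hat_dominates_peroxyls_for_PS_PSE_in_water
PASS  set_dominates_peroxyls_for_PTE_in_water
PASS  set_contributes_zero_in_lipid
```

`repro/reproduction_diff.csv` lists every published rate cell with its
recomputed value, ratio and robustness class: `robust` cells are genuine
recomputations (activation-controlled electron transfer, plus all sums
and branching ratios of published rates), `calibrated` cells are
diffusion-controlled and depend on fitted effective reaction distances
(the underlying radii were never published), and `not-reproducible` cells
need transition-state frequencies the source never printed — the classes
and the honest error budget are documented in the methods note.

Other subcommands: `scavkin compute` runs the pipeline on your own channel
table + species/media YAML (`--no-corrections` shows the 1800× effect),
`scavkin simulate --seed N` writes a synthetic table with oracle ground
truth, `scavkin validate` checks a table against the domain invariants.

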