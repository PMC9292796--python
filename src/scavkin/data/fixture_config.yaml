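# Species/media registry and fixture metadata for the bundled
# phenothiazine-scaffold dataset. Stokes radii are sphere-equivalent
# literature-flavoured estimates, NOT published values: diffusion-limited
# cells of the reference rate tables are reproduced through calibrated
# effective reaction distances, not through these radii (see the
# calibration block exposed at load time).
species:
  PS: {role: antioxidant, chalcogen: S, stokes_radius_angstrom: 3.90}
  PSE: {role: antioxidant, chalcogen: Se, stokes_radius_angstrom: 3.95}
  PTE: {role: antioxidant, chalcogen: Te, stokes_radius_angstrom: 4.05}
  HO: {role: radical, stokes_radius_angstrom: 2.00}
  HOO: {role: radical, stokes_radius_angstrom: 2.20}
  CH3OO: {role: radical, stokes_radius_angstrom: 2.70}
media:
  # Viscosities are literature defaults at 298.15 K (not printed with the
  # free-energy tables).
  water: {viscosity_pa_s: 8.91e-4, polarity_class: aqueous}
  pentyl_ethanoate: {viscosity_pa_s: 8.62e-4, polarity_class: lipid}
marcus_region_hints:
  # Electron transfer from PSE and PTE to the hydroxyl radical in water is
  # flagged as Marcus-inverted in the source tables (lambda < |dG_rxn|).
  PSE|HO|water: inverted
  PTE|HO|water: inverted
notes:
  typo_corrections:
    - channel: PTE RAF 5a water dG_rxn
      encoded: -38.7
      reason: >-
        printed with a garbled decimal separator; -38.7 is the evident
        reading, consistent with the lipid column (-39.8).
  ring_opening: >-
    RAF at the 5a junction of PTE opens the central ring; the parent
    antioxidant is not recoverable. Channels are flagged ring_opening=true
    and still counted in mechanism sums by default.
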