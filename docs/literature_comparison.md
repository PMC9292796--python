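# Literature context for the overall rate constants

Static reference table: calculated and experimental overall
radical-quenching rate constants (M⁻¹ s⁻¹) collected from the antioxidant
kinetics literature for molecules commonly used as benchmarks, alongside
the recomputed overall activities of the phenothiazine scaffolds. None of
the external values are computed by this package; they are shipped for
orientation only.

| Substrate    | ROS     | Solvent | k (calc)   | k (exp)    |
|--------------|---------|---------|------------|------------|
| PS           | HO•     | aqueous | 8.05·10¹⁰  |            |
| PSE          | HO•     | aqueous | 8.35·10¹⁰  |            |
| PTE          | HO•     | aqueous | 8.21·10¹⁰  |            |
| Glutathione  | HO•     | aqueous | 7.68·10⁹   | 8.72·10⁹   |
| Glutathione  | CH₃O•   | aqueous | 5.89·10⁸   | 9.00·10⁸   |
| Glutathione  | HOO•    | aqueous | 2.69·10⁷   |            |
| Glutathione  | CH₃OO•  | aqueous | 2.02·10⁴   |            |
| Sesamol      | HO•     | aqueous | 2.37·10¹⁰  | 1.10·10¹⁰  |
| Sesamol      | HOO•    | aqueous | 6.36·10⁷   |            |
| Caffeine     | HO•     | aqueous | 2.15·10⁹   | 5.60·10⁹   |
| Melatonin    | HO•     | aqueous | 1.85·10¹⁰  | 3.04·10¹⁰  |
| DHMBA        | HOO•    | aqueous | 1.34·10⁹   |            |
| Capsaicin    | ROO•    | mixed   | 6.50·10³   | 5.60·10³   |
| Tyrosol      | ROO•    | aqueous | 4.30·10³   | 9.40·10³   |
| Trolox       | HO•     | aqueous | 2.78·10¹⁰  | 8.10·10¹⁰  |
| Edaravone    | HO•     | aqueous | 1.35·10¹⁰  | 1.93·10⁹   |

DHMBA: 3,5-dihydroxy-4-methoxybenzyl alcohol.

The hydroxyl-radical rows cluster near the diffusion limit for every good
scavenger — which is exactly why the diffusion parameters (Stokes radii,
reaction distances) dominate the accuracy of any computed value in that
regime, and why this package treats the diffusion-controlled cells of its
bundled dataset as calibrated rather than predicted (see
[methods](methods.md)).
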