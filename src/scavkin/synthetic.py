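"""Seeded synthetic channel tables with stored ground-truth rates.

The generator emulates the statistical structure of the bundled dataset
without copying it: amino-site hydrogen abstraction is exergonic and
barrierless in the polar medium, aromatic-site abstraction is endergonic
for peroxyl-class radicals (and printed without barriers, i.e.
thermodynamics-only), ring sites are doubly degenerate, electron transfer
is kinetically feasible only in the polar medium (the lipid barrier floor
of 40 kcal mol^-1 pushes every lipid SET rate below 1e-10 M^-1 s^-1), and
every SET channel carries a reorganization energy consistent with its
(dG_rxn, dG_act) pair.

Ground truth is computed by :func:`brute_force_k_app`, a closed-form
single-expression evaluation of the whole per-channel chain that shares no
code with the pipeline modules; it is the independent oracle the property
suite compares the pipeline against.

All draws are uniform within table-derived ranges (no distributional model
is implied by the source data) and a single integer seed determines the
output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import channel_key
from .kinetics import infer_lambda
from .model import (
    CONSTANTS,
    P_STANDARD,
    ChannelSet,
    MediumSpec,
    Mechanism,
    Polarity,
    ReactionChannel,
    Role,
    SpeciesSpec,
)

#: Default draw ranges (kcal mol^-1 for energies, cm^-1 for frequencies,
#: metres for radii), spanning what the reference free-energy tables show.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "HAT_act_aqueous": (0.0, 0.0),  # amino-site HAT is barrierless in water
    "HAT_act_lipid": (6.0, 20.0),
    "HAT_rxn_amino": (-40.0, -2.0),
    "HAT_rxn_aromatic_hydroxyl": (-10.0, -5.5),
    "HAT_rxn_aromatic_peroxyl": (22.0, 29.0),
    "RAF_act_aqueous_hydroxyl": (4.0, 9.5),
    "RAF_act_aqueous_peroxyl": (21.0, 29.0),
    "RAF_act_lipid_hydroxyl": (7.5, 11.0),
    "RAF_act_lipid_peroxyl": (25.0, 32.0),
    "RAF_rxn_hydroxyl": (-14.0, -7.0),
    "RAF_rxn_peroxyl": (11.0, 24.0),
    "SET_act_aqueous": (0.0, 15.0),
    "SET_act_lipid": (40.0, 66.0),
    "SET_rxn_aqueous": (-17.0, 14.0),
    "SET_rxn_lipid": (28.0, 55.0),
    "OX_act_aqueous": (12.0, 35.0),
    "OX_act_lipid": (20.0, 43.0),
    "OX_rxn": (-26.0, 0.0),
    "imag_freq_hat": (1000.0, 3500.0),
    "radius_radical": (1.8e-10, 2.8e-10),
    "radius_antioxidant": (3.5e-10, 4.5e-10),
}

HAT_SITES = ("1", "2", "3", "4", "5")
RAF_SITES = ("2a", "2", "3", "4", "5", "5a")
RADICALS = ("hydroxyl", "peroxyl_a", "peroxyl_b")

_MEDIA = {
    "aqueous": MediumSpec(
        name="aqueous", viscosity=8.91e-4, polarity_class=Polarity.aqueous
    ),
    "lipid": MediumSpec(
        name="lipid", viscosity=8.62e-4, polarity_class=Polarity.lipid
    ),
}


class GeneratorSpec(BaseModel):
    """Parameters of a synthetic dataset; the seed fully determines it."""

    model_config = ConfigDict(frozen=True)

    seed: int
    n_antioxidants: int = Field(default=3, ge=1)
    mechanisms: tuple[Mechanism, ...] = (
        Mechanism.HAT,
        Mechanism.RAF,
        Mechanism.SET,
        Mechanism.OX,
    )
    media: tuple[str, ...] = ("aqueous", "lipid")
    ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    @model_validator(mode="after")
    def _check(self) -> "GeneratorSpec":
        if not self.mechanisms:
            raise ValueError("at least one mechanism is required")
        for key, (lo, hi) in self.ranges.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError(f"range {key!r} must be finite with lo <= hi")
        unknown = set(self.media) - set(_MEDIA)
        if unknown:
            raise ValueError(f"unknown media {sorted(unknown)}")
        return self


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated channel table plus oracle ground truth.

    ``truth`` has one row per kinetic channel, aligned with
    ``channel_set.kinetic_channels()``: the thermal, diffusion and apparent
    rate constants from the brute-force oracle.
    """

    spec: GeneratorSpec
    channel_set: ChannelSet
    truth: pd.DataFrame


def brute_force_k_app(
    dG_act: float,
    sigma: int = 1,
    imag_freq: float | None = None,
    temperature: float = 298.15,
    viscosity: float = 8.91e-4,
    radius_A: float = 2.0e-10,
    radius_B: float = 4.0e-10,
    reaction_distance: float | None = None,
    molecularity: int = 2,
    corrections: bool = True,
) -> tuple[float, float, float]:
    """Closed-form evaluation of the full per-channel chain.

    Returns ``(k_thermal, k_D, k_app)``.  This is the independent oracle:
    plain arithmetic, no pipeline types, one formula per quantity.
    """
    m = molecularity
    corr = (
        -(m - 1)
        * (CONSTANTS.R * temperature)
        * math.log(CONSTANTS.kB * CONSTANTS.N_A * temperature / P_STANDARD * 1000.0)
        - (CONSTANTS.R * temperature)
        * (math.log(m * 10.0 ** (2 * (m - 1))) - (m - 1))
        if corrections
        else 0.0
    )
    x = CONSTANTS.hc_over_kB * imag_freq / temperature if imag_freq else 0.0
    k_thermal = (
        sigma
        * (1.0 + x * x / 24.0)
        * (CONSTANTS.kB * temperature / CONSTANTS.h)
        * math.exp(
            -max(0.0, dG_act + corr) / (CONSTANTS.R * temperature)
        )
    )
    if m == 1:
        return k_thermal, math.inf, k_thermal
    k_D = (
        4.0
        * math.pi
        * (
            reaction_distance
            if reaction_distance is not None
            else radius_A + radius_B
        )
        * (
            CONSTANTS.kB * temperature / (6.0 * math.pi * viscosity * radius_A)
            + CONSTANTS.kB * temperature / (6.0 * math.pi * viscosity * radius_B)
        )
        * CONSTANTS.N_A
        * 1000.0
    )
    return k_thermal, k_D, k_D * k_thermal / (k_D + k_thermal)


def _u(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Draw a channel table with the reference data's structure."""
    rng = np.random.default_rng(spec.seed)
    R = spec.ranges

    species: dict[str, SpeciesSpec] = {}
    for radical in RADICALS:
        species[radical] = SpeciesSpec(
            name=radical,
            role=Role.radical,
            stokes_radius=_u(rng, R["radius_radical"]),
        )
    antioxidants = [f"AO{i + 1:02d}" for i in range(spec.n_antioxidants)]
    for name in antioxidants:
        species[name] = SpeciesSpec(
            name=name,
            role=Role.antioxidant,
            stokes_radius=_u(rng, R["radius_antioxidant"]),
        )

    media = {name: _MEDIA[name] for name in spec.media}
    channels: list[ReactionChannel] = []
    for medium_name in spec.media:
        polarity = media[medium_name].polarity_class.value
        for radical in RADICALS:
            rad_class = "hydroxyl" if radical == "hydroxyl" else "peroxyl"
            for ao in antioxidants:
                if Mechanism.HAT in spec.mechanisms:
                    for site in HAT_SITES:
                        if site == "1":
                            act = _u(rng, R[f"HAT_act_{polarity}"])
                            rxn = _u(rng, R["HAT_rxn_amino"])
                            nu = (
                                _u(rng, R["imag_freq_hat"])
                                if polarity == "lipid" and act > 0
                                else None
                            )
                        else:
                            # aromatic abstraction: thermodynamics-only rows
                            act, nu = None, None
                            rxn = _u(rng, R[f"HAT_rxn_aromatic_{rad_class}"])
                        channels.append(
                            ReactionChannel(
                                antioxidant=ao,
                                radical=radical,
                                mechanism=Mechanism.HAT,
                                site=site,
                                medium=medium_name,
                                dG_act=act,
                                dG_rxn=rxn,
                                imag_freq=nu,
                            )
                        )
                if Mechanism.RAF in spec.mechanisms:
                    for site in RAF_SITES:
                        channels.append(
                            ReactionChannel(
                                antioxidant=ao,
                                radical=radical,
                                mechanism=Mechanism.RAF,
                                site=site,
                                medium=medium_name,
                                dG_act=_u(
                                    rng, R[f"RAF_act_{polarity}_{rad_class}"]
                                ),
                                dG_rxn=_u(rng, R[f"RAF_rxn_{rad_class}"]),
                            )
                        )
                if Mechanism.SET in spec.mechanisms:
                    act = _u(rng, R[f"SET_act_{polarity}"])
                    lo, hi = R[f"SET_rxn_{polarity}"]
                    # a Marcus barrier can never undercut the endergonicity
                    rxn = _u(rng, (lo, min(hi, act)))
                    roots = infer_lambda(rxn, act)
                    lam = roots[int(rng.integers(len(roots)))][0] if roots else None
                    channels.append(
                        ReactionChannel(
                            antioxidant=ao,
                            radical=radical,
                            mechanism=Mechanism.SET,
                            medium=medium_name,
                            dG_act=act,
                            dG_rxn=rxn,
                            lambda_reorg=lam,
                        )
                    )
                if Mechanism.OX in spec.mechanisms and rad_class == "peroxyl":
                    channels.append(
                        ReactionChannel(
                            antioxidant=ao,
                            radical=radical,
                            mechanism=Mechanism.OX,
                            medium=medium_name,
                            dG_act=_u(rng, R[f"OX_act_{polarity}"]),
                            dG_rxn=_u(rng, R["OX_rxn"]),
                        )
                    )

    channel_set = ChannelSet(channels=channels, species=species, media=media)
    return SyntheticDataset(
        spec=spec, channel_set=channel_set, truth=_truth_table(channel_set)
    )


def _truth_table(channel_set: ChannelSet) -> pd.DataFrame:
    rows = []
    for c in channel_set.kinetic_channels():
        medium = channel_set.media[c.medium]
        k_thermal, k_D, k_app = brute_force_k_app(
            c.dG_act,
            sigma=c.sigma,
            imag_freq=c.imag_freq,
            temperature=medium.temperature,
            viscosity=medium.viscosity,
            radius_A=channel_set.species[c.radical].stokes_radius,
            radius_B=channel_set.species[c.antioxidant].stokes_radius,
            molecularity=c.molecularity,
        )
        rows.append(
            {
                "channel": channel_key(c),
                "k_thermal": k_thermal,
                "k_D": k_D,
                "k_app": k_app,
            }
        )
    return pd.DataFrame(rows)


def perturb(
    dataset: SyntheticDataset, magnitude: float, seed: int | None = None
) -> SyntheticDataset:
    """Add uniform noise in +/- ``magnitude`` (kcal mol^-1) to every free
    energy and recompute the ground truth.

    The sensitivity harness for the transcription error budget: +/-0.05
    kcal mol^-1 of input rounding moves an activation-controlled rate by at
    most a factor exp(0.05/RT) = 1.088.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = np.random.default_rng(
        dataset.spec.seed + 104729 if seed is None else seed
    )

    def jitter(value: float | None) -> float | None:
        if value is None:
            return None
        return value + float(rng.uniform(-magnitude, magnitude))

    channels = [
        c.model_copy(
            update={"dG_act": jitter(c.dG_act), "dG_rxn": jitter(c.dG_rxn)}
        )
        for c in dataset.channel_set.channels
    ]
    channel_set = ChannelSet(
        channels=channels,
        species=dataset.channel_set.species,
        media=dataset.channel_set.media,
    )
    return SyntheticDataset(
        spec=dataset.spec, channel_set=channel_set, truth=_truth_table(channel_set)
    )
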