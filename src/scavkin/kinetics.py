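"""Per-channel rate physics.

The chain for a bimolecular channel is

    kappa   = 1 + (1/24) * (h c nu / kB T)^2          (Wigner tunneling)
    k       = kappa * (kB T / h) * exp(-dG_act / RT)  (Eyring-Polanyi TST)
    k_D     = 4 pi R_AB (D_A + D_B) N_A               (Smoluchowski)
    D_X     = kB T / (6 pi eta a_X)                   (Stokes-Einstein)
    k_app   = k_D k / (k_D + k)                       (Collins-Kimball)

with the activation free energy first passed through the solution-phase
corrections of :mod:`scavkin.corrections`.  Electron-transfer barriers obey
Marcus theory, ``dG_act = (lambda/4) (1 + dG_rxn/lambda)^2``, whose inverse
(:func:`infer_lambda`) recovers the admissible reorganization energies from
a tabulated barrier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .config import RunConfig, channel_key, context_key, pair_key
from .corrections import corrected_barrier
from .model import (
    CONSTANTS,
    ChannelSet,
    MarcusRegion,
    Mechanism,
    RateResult,
    ReactionChannel,
)

logger = logging.getLogger(__name__)


def wigner_kappa(imag_freq: Optional[float], temperature: float = 298.15) -> float:
    """Wigner transmission coefficient from the magnitude of the
    transition-state imaginary frequency (cm^-1).

    ``1 + (1/24) (h c nu / kB T)^2``; an absent or zero frequency means no
    tunneling information, kappa = 1.
    """
    if imag_freq is None or imag_freq == 0.0:
        return 1.0
    if imag_freq < 0:
        raise ValueError("imaginary frequency must be a positive magnitude")
    x = CONSTANTS.hc_over_kB * imag_freq / temperature
    return 1.0 + x * x / 24.0


def eyring_rate(
    dG_act_corrected: float, kappa: float = 1.0, temperature: float = 298.15
) -> float:
    """Eyring-Polanyi TST rate constant, ``kappa (kB T/h) exp(-dG/RT)``.

    In the 1 M standard-state convention the same number serves as s^-1 for
    unimolecular and M^-1 s^-1 for bimolecular channels.
    """
    if dG_act_corrected < 0:
        raise ValueError("corrected barrier must be >= 0 (clamp upstream)")
    if kappa < 1.0:
        raise ValueError("transmission coefficient must be >= 1")
    return (
        kappa
        * CONSTANTS.kBT_over_h(temperature)
        * math.exp(-dG_act_corrected / CONSTANTS.RT(temperature))
    )


def marcus_barrier(
    dG_rxn: float, lambda_reorg: float
) -> tuple[float, MarcusRegion]:
    """Marcus activation free energy and region flag.

    The channel is in the inverted region iff it is exergonic beyond its
    reorganization energy (|dG_rxn| > lambda); the activationless point
    dG_rxn = -lambda is classified normal.
    """
    if lambda_reorg <= 0:
        raise ValueError("reorganization energy must be > 0")
    dG = (lambda_reorg / 4.0) * (1.0 + dG_rxn / lambda_reorg) ** 2
    region = (
        MarcusRegion.inverted
        if dG_rxn < 0 and -dG_rxn > lambda_reorg
        else MarcusRegion.normal
    )
    return dG, region


def infer_lambda(
    dG_rxn: float, dG_act: float
) -> list[tuple[float, MarcusRegion]]:
    """Real positive reorganization energies consistent with a Marcus pair.

    Solves ``(lambda/4)(1 + dG_rxn/lambda)^2 = dG_act``, i.e.
    ``lambda^2 + (2 dG_rxn - 4 dG_act) lambda + dG_rxn^2 = 0``.  Returns 0,
    1 or 2 roots, each labelled with its Marcus region; an empty list means
    no physical reorganization energy exists (a Marcus barrier can never lie
    below the endergonicity).
    """
    if dG_act < 0:
        raise ValueError("activation free energy must be >= 0")
    g, a = dG_rxn, dG_act
    disc = 16.0 * a * (a - g)
    if disc < 0:
        return []
    s = math.sqrt(disc) / 2.0  # = 2*sqrt(a*(a-g))
    big = 2.0 * a - g + s
    if big <= 0.0:
        return []
    # the root product is g^2; divide instead of subtracting (cancellation)
    roots = {big, g * g / big}
    out = []
    for lam in sorted(roots, reverse=True):
        if lam <= 0:
            continue
        region = (
            MarcusRegion.inverted if (g < 0 and -g > lam) else MarcusRegion.normal
        )
        out.append((lam, region))
    return out


@dataclass(frozen=True)
class DiffusionInputs:
    """Geometry and medium parameters of the encounter-rate calculation.

    ``reaction_distance`` defaults to contact, ``radius_A + radius_B``.
    Distances below the larger radius are physically a sub-contact,
    effective reaction distance (they absorb unprinted transition-state
    geometry); they are accepted with a warning rather than rejected.
    """

    radius_A: float  # m
    radius_B: float  # m
    viscosity: float  # Pa s
    temperature: float = 298.15
    reaction_distance: Optional[float] = None  # m

    def __post_init__(self) -> None:
        for name in ("radius_A", "radius_B", "viscosity", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.reaction_distance is not None:
            if self.reaction_distance <= 0:
                raise ValueError("reaction_distance must be > 0")
            if self.reaction_distance < max(self.radius_A, self.radius_B):
                logger.info(
                    "reaction distance %.3g m below the larger Stokes radius "
                    "%.3g m: treating it as an effective (calibrated) value",
                    self.reaction_distance,
                    max(self.radius_A, self.radius_B),
                )

    @property
    def R_AB(self) -> float:
        if self.reaction_distance is not None:
            return self.reaction_distance
        return self.radius_A + self.radius_B


def diffusion_rate(inputs: DiffusionInputs) -> float:
    """Smoluchowski steady-state encounter rate constant in M^-1 s^-1.

    Stokes-Einstein diffusion coefficients for both partners, mutual
    coefficient ``D_A + D_B``, and ``4 pi R_AB D_AB N_A`` converted from
    m^3 mol^-1 s^-1 with a factor 1000.
    """
    kBT = CONSTANTS.kB * inputs.temperature
    D_A = kBT / (6.0 * math.pi * inputs.viscosity * inputs.radius_A)
    D_B = kBT / (6.0 * math.pi * inputs.viscosity * inputs.radius_B)
    return 4.0 * math.pi * inputs.R_AB * (D_A + D_B) * CONSTANTS.N_A * 1000.0


def collins_kimball(k_thermal: float, k_D: float) -> float:
    """Apparent rate constant interpolating activation and diffusion
    control: ``k_D k / (k_D + k)``."""
    if k_thermal <= 0 or k_D <= 0:
        raise ValueError("rate constants must be > 0")
    if math.isinf(k_D):
        return k_thermal
    return k_D * k_thermal / (k_D + k_thermal)


def _marcus_region_for(
    channel: ReactionChannel, config: RunConfig
) -> MarcusRegion:
    """Classify a SET channel's Marcus region.

    Uses the explicit reorganization energy when present; otherwise inverts
    the Marcus quadratic from the tabulated barrier and picks the root
    matching a configured hint.  Two admissible roots without a hint are
    genuinely ambiguous: the normal root is selected and the ambiguity
    logged.
    """
    if channel.lambda_reorg is not None:
        return marcus_barrier(channel.dG_rxn, channel.lambda_reorg)[1]
    if channel.dG_act is None:
        return MarcusRegion.na
    roots = infer_lambda(channel.dG_rxn, channel.dG_act)
    if not roots:
        return MarcusRegion.na
    hint = config.marcus_region_hints.get(context_key(channel))
    if hint is not None:
        for _, region in roots:
            if region.value == hint:
                return region
        logger.warning(
            "Marcus region hint %r for %s has no matching root", hint,
            context_key(channel),
        )
    labels = {region for _, region in roots}
    if len(labels) > 1:
        logger.info(
            "both Marcus roots admissible for %s; defaulting to the normal "
            "region (supply a marcus_region_hint to override)",
            context_key(channel),
        )
        return MarcusRegion.normal
    return roots[0][1]


def compute_channel_rate(
    channel: ReactionChannel,
    channel_set: ChannelSet,
    config: Optional[RunConfig] = None,
) -> RateResult:
    """Run the full per-channel chain: corrections, tunneling, TST,
    diffusion and Collins-Kimball coupling."""
    config = config or RunConfig()
    medium = channel_set.medium_for(channel)
    T = medium.temperature

    nu = channel.imag_freq
    if nu is None:
        nu = config.imag_freq_map.get(channel_key(channel))
    kappa = wigner_kappa(nu, T)

    region = MarcusRegion.na
    dG_act = channel.dG_act
    if channel.mechanism is Mechanism.SET:
        if dG_act is None and channel.lambda_reorg is not None:
            dG_act, region = marcus_barrier(channel.dG_rxn, channel.lambda_reorg)
        else:
            region = _marcus_region_for(channel, config)

    barrier = corrected_barrier(
        channel,
        medium,
        dG_act=dG_act,
        apply_standard_state=config.apply_standard_state,
        apply_cage=config.apply_cage,
        clamp_negative=config.clamp_negative_barriers,
    )
    k_unit = eyring_rate(barrier.dG_act_corrected, kappa, T)
    sigma_in_thermal = config.sigma_convention == "thermal"
    k_thermal = channel.sigma * k_unit if sigma_in_thermal else k_unit

    if channel.molecularity == 1:
        k_D = math.inf
        k_app = k_thermal
        diffusion_limited = False
    else:
        radical_spec, antiox_spec = channel_set.species_pair(channel)
        a_A = radical_spec.stokes_radius if radical_spec else None
        if a_A is None:
            a_A = config.default_radical_radius
            logger.warning(
                "no Stokes radius for radical %r: substituting default %.2g m",
                channel.radical,
                a_A,
            )
        a_B = antiox_spec.stokes_radius if antiox_spec else None
        if a_B is None:
            a_B = config.default_antioxidant_radius
            logger.warning(
                "no Stokes radius for antioxidant %r: substituting default "
                "%.2g m",
                channel.antioxidant,
                a_B,
            )
        R_AB = config.reaction_distance_map.get(pair_key(channel))
        k_D = diffusion_rate(
            DiffusionInputs(
                radius_A=a_A,
                radius_B=a_B,
                viscosity=medium.viscosity,
                temperature=T,
                reaction_distance=R_AB,
            )
        )
        k_app = collins_kimball(k_thermal, k_D)
        diffusion_limited = k_thermal >= config.diffusion_threshold * k_D

    return RateResult(
        channel=channel,
        dG_act_corrected=barrier.dG_act_corrected,
        kappa=kappa,
        k_thermal=k_thermal,
        k_D=k_D,
        k_app=k_app,
        diffusion_limited=diffusion_limited,
        marcus_region=region,
        barrier_clamped=barrier.clamped,
        sigma_in_thermal=sigma_in_thermal,
    )


def compute_rates(
    channel_set: ChannelSet, config: Optional[RunConfig] = None
) -> list[RateResult]:
    """Evaluate every kinetic channel of a set (channels without an
    available barrier are skipped)."""
    config = config or RunConfig()
    return [
        compute_channel_rate(c, channel_set, config)
        for c in channel_set.kinetic_channels()
    ]
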