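"""Solution-phase thermal corrections to tabulated activation free energies.

Quantum-chemistry thermochemistry is printed for the 1 atm ideal-gas standard
state.  Solution kinetics need two corrections before the barrier enters the
Eyring equation:

1. *standard state*: moving every reactant from 1 atm to 1 M costs
   ``-(m - 1) * R * T * ln(V_M)`` for a reaction of molecularity ``m``,
   where ``V_M`` is the molar volume in L mol^-1 (24.465 at 298.15 K);
2. *solvent cage*: the entropy loss of bringing ``n`` reactants into one
   solvent cage is smaller in solution than the gas-phase translational
   partition function suggests; the correction is
   ``-R * T * [ln(n * 10^(2(n-1))) - (n - 1)]``.

Both vanish for unimolecular steps and are negative for bimolecular ones:
omitting them *under*-estimates a bimolecular rate constant by the factor
``V_M * 200 / e`` (about 1800 at 298.15 K), see
:func:`bimolecular_correction_factor`.

Tabulated barriers in the bundled dataset are treated as *uncorrected*; the
corrections are applied here, inside the pipeline.  A corrected barrier that
comes out negative (barrierless channel) is clamped to zero: the TST
prefactor is the physical ceiling and diffusion capping handles the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .model import CONSTANTS, T_STANDARD, MediumSpec, ReactionChannel


@dataclass(frozen=True)
class CorrectionBreakdown:
    """Standard-state and cage terms (kcal mol^-1); both <= 0 for
    bimolecular channels and exactly 0 for unimolecular ones."""

    dG_standard_state: float
    dG_cage: float

    @property
    def dG_total(self) -> float:
        return self.dG_standard_state + self.dG_cage


@dataclass(frozen=True)
class BarrierResult:
    breakdown: CorrectionBreakdown
    dG_act_corrected: float
    clamped: bool


def _resolve_T_VM(
    medium: Optional[MediumSpec], temperature: Optional[float]
) -> tuple[float, float]:
    if medium is not None:
        T = medium.temperature if temperature is None else temperature
        VM = (
            medium.molar_volume
            if temperature is None
            else CONSTANTS.molar_volume(temperature)
        )
    else:
        T = T_STANDARD if temperature is None else temperature
        VM = CONSTANTS.molar_volume(T)
    return T, VM


def standard_state_correction(
    molecularity: int,
    medium: Optional[MediumSpec] = None,
    temperature: Optional[float] = None,
) -> float:
    """1 atm -> 1 M standard-state shift of the activation free energy.

    Returns ``-(molecularity - 1) * R * T * ln(V_M)`` in kcal mol^-1
    (-1.894 for a bimolecular channel at 298.15 K).
    """
    if molecularity not in (1, 2):
        raise ValueError(f"unsupported molecularity {molecularity!r}")
    T, VM = _resolve_T_VM(medium, temperature)
    return -(molecularity - 1) * CONSTANTS.RT(T) * math.log(VM)


def cage_correction(
    n_reactants: int,
    medium: Optional[MediumSpec] = None,
    temperature: Optional[float] = None,
) -> float:
    """Solvent-cage (reduced entropy loss) correction in kcal mol^-1.

    ``-R*T*[ln(n * 10^(2(n-1))) - (n-1)]``: zero for one reactant, -2.547
    for two at 298.15 K.
    """
    if n_reactants < 1:
        raise ValueError("n_reactants must be >= 1")
    T, _ = _resolve_T_VM(medium, temperature)
    n = n_reactants
    return -CONSTANTS.RT(T) * (math.log(n * 10.0 ** (2 * (n - 1))) - (n - 1))


def bimolecular_correction_factor(
    medium: Optional[MediumSpec] = None, temperature: Optional[float] = None
) -> float:
    """Rate-constant enhancement implied by both corrections for a
    bimolecular reaction: ``exp(-dG_total / RT)`` = ``V_M * 200 / e``
    (~1.80e3 at 298.15 K, the factor by which uncorrected barriers
    under-estimate solution rate constants)."""
    T, _ = _resolve_T_VM(medium, temperature)
    total = standard_state_correction(2, medium, temperature) + cage_correction(
        2, medium, temperature
    )
    return math.exp(-total / CONSTANTS.RT(T))


def corrected_barrier(
    channel: ReactionChannel,
    medium: Optional[MediumSpec] = None,
    *,
    dG_act: Optional[float] = None,
    apply_standard_state: bool = True,
    apply_cage: bool = True,
    clamp_negative: bool = True,
) -> BarrierResult:
    """Apply the solution-phase corrections to a channel's barrier.

    ``dG_act`` overrides the channel's tabulated barrier (used when a Marcus
    barrier was derived upstream).  Corrections are additive and independent
    of mechanism; they depend only on molecularity and temperature.
    """
    raw = channel.dG_act if dG_act is None else dG_act
    if raw is None:
        raise ValueError(
            f"channel {channel.antioxidant}+{channel.radical} "
            f"{channel.mechanism.value}/{channel.site}: no activation free "
            "energy available"
        )
    m = channel.molecularity
    ss = standard_state_correction(m, medium) if apply_standard_state else 0.0
    cage = cage_correction(m, medium) if apply_cage else 0.0
    breakdown = CorrectionBreakdown(ss, cage)
    corrected = raw + breakdown.dG_total
    clamped = False
    if clamp_negative and corrected < 0.0:
        corrected = 0.0
        clamped = True
    return BarrierResult(breakdown, corrected, clamped)
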