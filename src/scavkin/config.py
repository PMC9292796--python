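"""Run configuration shared by the library pipeline and the CLI.

The defaults reproduce the reference-mode pipeline exactly: both thermal
corrections on, path degeneracy folded into the thermal rate before
Collins-Kimball coupling, and a transmission coefficient of 1 wherever no
imaginary frequency is available.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .model import ReactionChannel


def channel_key(channel: ReactionChannel) -> str:
    """Fully qualified channel identifier used by injection maps."""
    return "|".join(
        (
            channel.antioxidant,
            channel.radical,
            channel.mechanism.value,
            channel.site,
            channel.medium,
        )
    )


def pair_key(channel: ReactionChannel) -> str:
    """(antioxidant, radical, mechanism, medium) identifier; diffusion
    parameters are shared at this granularity."""
    return "|".join(
        (
            channel.antioxidant,
            channel.radical,
            channel.mechanism.value,
            channel.medium,
        )
    )


def context_key(channel: ReactionChannel) -> str:
    """(antioxidant, radical, medium) identifier for report grouping and
    Marcus region hints."""
    return "|".join((channel.antioxidant, channel.radical, channel.medium))


class RunConfig(BaseModel):
    """Knobs of the rate pipeline.

    ``sigma_convention`` decides where path degeneracy enters: ``"thermal"``
    multiplies the TST rate *before* diffusion coupling (each symmetric site
    is an independent reactive funnel sharing one encounter pair, the
    default); ``"post"`` multiplies the apparent rate after coupling.

    ``reaction_distance_map`` (metres, keyed by :func:`pair_key`) overrides
    the default contact distance ``a_A + a_B``; ``imag_freq_map`` (cm^-1,
    keyed by :func:`channel_key`) injects imaginary frequencies for channels
    whose tables print none; ``marcus_region_hints`` (keyed by
    :func:`context_key`) disambiguates the reorganization-energy root for
    SET channels.
    """

    model_config = ConfigDict(frozen=True)

    apply_standard_state: bool = True
    apply_cage: bool = True
    clamp_negative_barriers: bool = True
    sigma_convention: Literal["thermal", "post"] = "thermal"
    diffusion_threshold: float = Field(default=1.0, gt=0.0)
    include_ox: bool = False
    include_ring_opening: bool = True
    imag_freq_map: dict[str, float] = Field(default_factory=dict)
    reaction_distance_map: dict[str, float] = Field(default_factory=dict)
    marcus_region_hints: dict[str, Literal["normal", "inverted"]] = Field(
        default_factory=dict
    )
    #: Stokes radii substituted (with a warning) for unregistered species, m.
    default_radical_radius: float = Field(default=2.0e-10, gt=0.0)
    default_antioxidant_radius: float = Field(default=4.0e-10, gt=0.0)
    sig_figs: int = Field(default=3, ge=1)
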