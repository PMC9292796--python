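"""Core domain model for radical-scavenging kinetics.

The package computes apparent rate constants for elementary reactions of an
antioxidant with a reactive oxygen species (ROS).  The atomic unit is the
:class:`ReactionChannel`: one scavenging mechanism — hydrogen atom transfer
(HAT), radical adduct formation (RAF), single electron transfer (SET) or
direct oxidation of the chalcogen centre (OX) — at one molecular site in one
solvent, described by its Gibbs free energies of activation and reaction.

Unit conventions
----------------
* free energies: kcal mol^-1 (the thermodynamic layer never leaves them);
* Stokes radii and reaction distances: metres;
* viscosities: Pa s;
* bimolecular rate constants: M^-1 s^-1 (diffusion physics works in SI
  internally and converts m^3 mol^-1 s^-1 -> M^-1 s^-1 with a factor 1000);
* imaginary frequencies: positive magnitudes in cm^-1 (sign conventions of
  quantum-chemistry codes differ, so only the magnitude is stored).

Numeric invariants such as ``sigma >= 1`` are deliberately *not* enforced at
construction: :func:`validate_channel` reports them as structured violations
so that malformed input tables can be diagnosed row by row instead of dying
on the first bad cell.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Mechanism(str, Enum):
    """Radical-scavenging mechanism of one elementary channel."""

    HAT = "HAT"
    RAF = "RAF"
    SET = "SET"
    OX = "OX"


class Polarity(str, Enum):
    aqueous = "aqueous"
    lipid = "lipid"


class Role(str, Enum):
    antioxidant = "antioxidant"
    radical = "radical"


class Chalcogen(str, Enum):
    S = "S"
    Se = "Se"
    Te = "Te"
    none = "none"


class MarcusRegion(str, Enum):
    """Marcus regime of an electron-transfer channel.

    ``inverted`` means the reorganization energy is smaller than the
    exergonicity (|dG_r| > lambda), where more exergonic reactions acquire
    *larger* barriers.  Non-SET channels carry ``na``.
    """

    normal = "normal"
    inverted = "inverted"
    na = "n/a"


#: Pressure of the gas-phase standard state, Pa (1 atm).
P_STANDARD = 101325.0

#: Default absolute temperature, K.  Every reported table in the bundled
#: dataset refers to 298.15 K; media may override it.
T_STANDARD = 298.15


class PhysicalConstants(BaseModel):
    """CODATA physical constants in the mixed kcal/SI convention used here.

    ``R`` is the gas constant in kcal mol^-1 K^-1 (thermochemical calorie,
    1 cal = 4.184 J); ``hc_over_kB`` converts a wavenumber in cm^-1 to a
    temperature in K (the "second radiation constant", 1.43877 cm K).
    """

    model_config = ConfigDict(frozen=True)

    kB: float = 1.380649e-23  # J K^-1
    h: float = 6.62607015e-34  # J s
    N_A: float = 6.02214076e23  # mol^-1
    R: float = 1.380649e-23 * 6.02214076e23 / 4184.0  # kcal mol^-1 K^-1
    hc_over_kB: float = 6.62607015e-34 * 2.99792458e10 / 1.380649e-23  # cm K

    def RT(self, temperature: float = T_STANDARD) -> float:
        """Thermal energy R*T in kcal mol^-1 (0.5925 at 298.15 K)."""
        return self.R * temperature

    def kBT_over_h(self, temperature: float = T_STANDARD) -> float:
        """TST prefactor kB*T/h in s^-1 (6.212e12 at 298.15 K)."""
        return self.kB * temperature / self.h

    def molar_volume(
        self, temperature: float = T_STANDARD, pressure: float = P_STANDARD
    ) -> float:
        """Ideal-gas molar volume in L mol^-1 (24.465 at 298.15 K, 1 atm)."""
        return self.kB * self.N_A * temperature / pressure * 1000.0


CONSTANTS = PhysicalConstants()

#: Ring positions of the tricyclic scaffold; symmetry makes each of them
#: doubly degenerate (two equivalent benzo rings), hence sigma defaults to 2.
RING_SITES = frozenset({"2", "2a", "3", "4", "5", "5a"})
KNOWN_SITES = frozenset({"1", "none"}) | RING_SITES


class MediumSpec(BaseModel):
    """Solvent context: temperature, viscosity and polarity class.

    ``molar_volume`` (L mol^-1) parameterizes the 1 atm -> 1 M standard-state
    correction; unless overridden it is the ideal-gas value R*T/P at the
    medium's temperature and 1 atm.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    temperature: float = Field(default=T_STANDARD, gt=0.0)
    viscosity: float = Field(gt=0.0)  # Pa s
    polarity_class: Polarity
    molar_volume: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _default_molar_volume(self) -> "MediumSpec":
        if self.molar_volume is None:
            object.__setattr__(
                self, "molar_volume", CONSTANTS.molar_volume(self.temperature)
            )
        return self


class SpeciesSpec(BaseModel):
    """An opaque labelled reactant: an antioxidant or a radical.

    No molecular structure is carried; the only physical attribute is the
    Stokes radius (metres) entering the Stokes-Einstein diffusion
    coefficient, plus the chalcogen identity for antioxidants.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    role: Role
    stokes_radius: Optional[float] = None  # m
    chalcogen: Chalcogen = Chalcogen.none

    @model_validator(mode="after")
    def _radius_range(self) -> "SpeciesSpec":
        if self.stokes_radius is not None:
            if not (0.5e-10 < self.stokes_radius < 20e-10):
                raise ValueError(
                    "stokes_radius must lie in (0.5, 20) Angstrom, given in m"
                )
        return self


class ReactionChannel(BaseModel):
    """One elementary scavenging reaction.

    ``antioxidant``, ``radical`` and ``medium`` are names resolved against a
    :class:`ChannelSet` registry.  ``dG_act`` may be absent for SET channels
    (a Marcus barrier can be derived from ``lambda_reorg``) and for
    thermodynamics-only rows.  ``sigma`` is the reaction-path degeneracy; when
    not given it defaults from the site (ring sites are doubly degenerate).
    """

    model_config = ConfigDict(frozen=True)

    antioxidant: str
    radical: str
    mechanism: Mechanism
    site: str = "none"
    medium: str
    dG_act: Optional[float] = None  # kcal mol^-1, uncorrected
    dG_rxn: float  # kcal mol^-1
    lambda_reorg: Optional[float] = None  # kcal mol^-1, SET only
    imag_freq: Optional[float] = None  # cm^-1, positive magnitude
    sigma: Optional[int] = None
    molecularity: int = 2
    ring_opening: bool = False

    @model_validator(mode="after")
    def _default_sigma(self) -> "ReactionChannel":
        if self.sigma is None:
            sigma = (
                2
                if self.mechanism in (Mechanism.HAT, Mechanism.RAF)
                and self.site in RING_SITES
                else 1
            )
            object.__setattr__(self, "sigma", sigma)
        return self

    def context(self) -> tuple[str, str, str]:
        """(antioxidant, radical, medium) grouping key."""
        return (self.antioxidant, self.radical, self.medium)


class Violation(NamedTuple):
    field: str
    rule: str
    severity: str  # "error" | "warning"


def validate_channel(channel: ReactionChannel) -> list[Violation]:
    """Check a channel against the domain invariants.

    Returns an empty list iff every invariant holds.  Unknown site labels are
    reported with ``severity="warning"`` so the engine generalizes beyond the
    tricyclic scaffold; everything else is an error.
    """
    out: list[Violation] = []
    if channel.sigma is not None and channel.sigma < 1:
        out.append(Violation("sigma", "path degeneracy must be >= 1", "error"))
    if channel.molecularity not in (1, 2):
        out.append(Violation("molecularity", "must be 1 or 2", "error"))
    if channel.mechanism is Mechanism.SET:
        if channel.site != "none":
            out.append(
                Violation("site", "SET is site-free (site must be 'none')", "error")
            )
        if channel.imag_freq is not None:
            out.append(
                Violation(
                    "imag_freq",
                    "SET has no nuclear saddle point, no imaginary frequency",
                    "error",
                )
            )
    if channel.lambda_reorg is not None and channel.lambda_reorg <= 0:
        out.append(
            Violation("lambda_reorg", "reorganization energy must be > 0", "error")
        )
    if channel.imag_freq is not None and channel.imag_freq < 0:
        out.append(
            Violation("imag_freq", "stored as a positive magnitude in cm^-1", "error")
        )
    if channel.ring_opening and not (
        channel.mechanism is Mechanism.RAF and channel.site == "5a"
    ):
        out.append(
            Violation(
                "ring_opening",
                "ring opening only occurs for RAF at the 5a junction",
                "error",
            )
        )
    if channel.site not in KNOWN_SITES:
        out.append(
            Violation(
                "site",
                f"unknown site label {channel.site!r} (not in scaffold set)",
                "warning",
            )
        )
    return out


def validation_errors(channel: ReactionChannel) -> list[Violation]:
    """Error-severity subset of :func:`validate_channel`."""
    return [v for v in validate_channel(channel) if v.severity == "error"]


class ChannelSet(BaseModel):
    """A channel table together with its species and media registries."""

    channels: list[ReactionChannel]
    species: dict[str, SpeciesSpec]
    media: dict[str, MediumSpec]

    def medium_for(self, channel: ReactionChannel) -> MediumSpec:
        try:
            return self.media[channel.medium]
        except KeyError:
            raise KeyError(f"medium {channel.medium!r} not in registry") from None

    def species_pair(
        self, channel: ReactionChannel
    ) -> tuple[Optional[SpeciesSpec], Optional[SpeciesSpec]]:
        """(radical, antioxidant) specs; ``None`` where unregistered."""
        return (
            self.species.get(channel.radical),
            self.species.get(channel.antioxidant),
        )

    def kinetic_channels(self) -> list[ReactionChannel]:
        """Channels that can enter rate evaluation: a barrier is available
        directly or derivable from Marcus theory."""
        return [
            c
            for c in self.channels
            if c.dG_act is not None
            or (c.mechanism is Mechanism.SET and c.lambda_reorg is not None)
        ]


class RateResult(BaseModel):
    """Per-channel derived kinetic quantities.

    ``k_thermal`` is the (degeneracy- and tunneling-weighted, depending on
    configuration) TST rate constant, ``k_D`` the Smoluchowski diffusion
    limit (``inf`` for unimolecular channels) and ``k_app`` their
    Collins-Kimball coupling.  ``diffusion_limited`` is set when
    ``k_thermal >= threshold * k_D``.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    channel: ReactionChannel
    dG_act_corrected: float
    kappa: float
    k_thermal: float
    k_D: float
    k_app: float
    diffusion_limited: bool
    marcus_region: MarcusRegion = MarcusRegion.na
    barrier_clamped: bool = False
    sigma_in_thermal: bool = True

    @model_validator(mode="after")
    def _bounds(self) -> "RateResult":
        if self.kappa < 1.0:
            raise ValueError("transmission coefficient must be >= 1")
        if self.k_app < 0 or (
            math.isfinite(self.k_D)
            and self.k_app > self.k_D * (1.0 + 1e-12)
        ):
            raise ValueError("k_app must satisfy 0 <= k_app <= k_D")
        return self
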