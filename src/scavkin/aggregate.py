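"""Mechanism-level sums, branching ratios and overall scavenging activity.

For one (antioxidant, radical, medium) context the apparent rate constants
of all channels of a mechanism are summed (with path degeneracy applied
according to the configured convention), the branching ratio of mechanism i
is ``Gamma_i = 100 * k_i / sum_j k_j`` and the overall activity is the plain
sum over mechanisms.  Direct chalcogen oxidation (OX) channels are computed
but excluded from branching and overall sums by default, mirroring how
scavenging summaries are conventionally reported; ``include_ox`` opts them
in.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel

from .config import RunConfig
from .model import MarcusRegion, Mechanism, RateResult


def round_percent(x: float) -> int:
    """Round half away from zero to integer percent (the reporting style of
    the reference tables)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


class MechanismSummary(BaseModel):
    mechanism: Mechanism
    k_app_sum: float
    gamma: Optional[float] = None  # percent, exact (un-rounded)
    diffusion_limited_any: bool = False
    n_channels: int = 0


class ScavengingReport(BaseModel):
    """Per-(antioxidant, radical, medium) mechanism breakdown."""

    antioxidant: str
    radical: str
    medium: str
    mechanisms: list[MechanismSummary]
    k_overall: float

    def gamma_of(self, mechanism: Mechanism) -> Optional[float]:
        for m in self.mechanisms:
            if m.mechanism is mechanism:
                return m.gamma
        return None

    def k_of(self, mechanism: Mechanism) -> float:
        for m in self.mechanisms:
            if m.mechanism is mechanism:
                return m.k_app_sum
        return 0.0


def _contribution(result: RateResult, sigma_convention: str) -> float:
    if sigma_convention == "post" and not result.sigma_in_thermal:
        return result.channel.sigma * result.k_app
    return result.k_app


def sum_mechanism(
    results: Sequence[RateResult],
    mechanism: Mechanism,
    *,
    sigma_convention: str = "thermal",
    include_ring_opening: bool = True,
    diffusion_threshold: float = 1.0,
) -> MechanismSummary:
    """Degeneracy-weighted sum of apparent rate constants for one mechanism.

    All results must share one (antioxidant, radical, medium) context.  The
    mechanism counts as diffusion-controlled when any member channel is, or
    when the *summed* thermal rate reaches the shared encounter rate — a
    multi-site mechanism can saturate diffusion collectively even if no
    single site does.
    """
    contexts = {r.channel.context() for r in results}
    if len(contexts) > 1:
        raise ValueError(f"mixed contexts in mechanism sum: {sorted(contexts)}")
    members = [
        r
        for r in results
        if r.channel.mechanism is mechanism
        and (include_ring_opening or not r.channel.ring_opening)
    ]
    k_sum = sum(_contribution(r, sigma_convention) for r in members)
    diffusion_limited = any(r.diffusion_limited for r in members)
    if members and not diffusion_limited:
        k_D_min = min(r.k_D for r in members)
        if math.isfinite(k_D_min):
            thermal_sum = sum(r.k_thermal for r in members)
            diffusion_limited = thermal_sum >= diffusion_threshold * k_D_min
    return MechanismSummary(
        mechanism=mechanism,
        k_app_sum=k_sum,
        diffusion_limited_any=diffusion_limited,
        n_channels=len(members),
    )


def branching_ratios(
    summaries: Sequence[MechanismSummary],
) -> dict[Mechanism, float]:
    """Percent contribution of each mechanism to the summed activity.

    Exact values are returned; reports round half away from zero to
    integers.  An all-zero input has no defined branching and is rejected.
    """
    total = sum(s.k_app_sum for s in summaries)
    if not summaries or total <= 0.0:
        raise ValueError("branching ratios need at least one non-zero mechanism")
    return {s.mechanism: 100.0 * s.k_app_sum / total for s in summaries}


def overall_activity(summaries: Iterable[MechanismSummary]) -> float:
    """Overall scavenging rate constant: the sum of the mechanism-level
    apparent rate constants."""
    return sum(s.k_app_sum for s in summaries)


def build_reports(
    results: Sequence[RateResult], config: Optional[RunConfig] = None
) -> list[ScavengingReport]:
    """Group per-channel results by context and assemble full reports."""
    config = config or RunConfig()
    by_context: dict[tuple[str, str, str], list[RateResult]] = {}
    for r in results:
        by_context.setdefault(r.channel.context(), []).append(r)

    reports = []
    for (antioxidant, radical, medium), members in sorted(by_context.items()):
        mechanisms_present = sorted(
            {r.channel.mechanism for r in members}, key=lambda m: m.value
        )
        if not config.include_ox:
            mechanisms_present = [
                m for m in mechanisms_present if m is not Mechanism.OX
            ]
        summaries = [
            sum_mechanism(
                members,
                mech,
                sigma_convention=config.sigma_convention,
                include_ring_opening=config.include_ring_opening,
                diffusion_threshold=config.diffusion_threshold,
            )
            for mech in mechanisms_present
        ]
        total = overall_activity(summaries)
        if total > 0:
            gammas = branching_ratios(summaries)
            summaries = [
                s.model_copy(update={"gamma": gammas[s.mechanism]})
                for s in summaries
            ]
        reports.append(
            ScavengingReport(
                antioxidant=antioxidant,
                radical=radical,
                medium=medium,
                mechanisms=summaries,
                k_overall=total,
            )
        )
    return reports
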