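"""Readers and writers for the channel-table, config and report formats.

The channel table is comma-delimited with a "." decimal separator and one
header row; scientific notation is accepted on input.  Columns, exactly:

    antioxidant, radical, mechanism, site, medium, dG_act_kcal,
    dG_rxn_kcal, lambda_kcal, imag_freq_cm, sigma, molecularity,
    ring_opening

An empty cell is an absent optional.  Species and media travel in a YAML
config document (radii in Angstrom, viscosities in Pa s).  Reports are
emitted either as a delimited table (rates at 3 significant figures,
reference-table style) or as JSON at full double precision; neither format
embeds timestamps, so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import pandas as pd
import yaml

from .aggregate import ScavengingReport, round_percent
from .model import (
    ChannelSet,
    Chalcogen,
    MediumSpec,
    Mechanism,
    Polarity,
    ReactionChannel,
    Role,
    SpeciesSpec,
)

CHANNEL_COLUMNS = [
    "antioxidant",
    "radical",
    "mechanism",
    "site",
    "medium",
    "dG_act_kcal",
    "dG_rxn_kcal",
    "lambda_kcal",
    "imag_freq_cm",
    "sigma",
    "molecularity",
    "ring_opening",
]

PathLike = Union[str, Path]


class ChannelTableError(ValueError):
    """Malformed channel table; carries row/column diagnostics."""


def _opt_float(cell: str, row: int, col: str):
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ChannelTableError(
            f"row {row}, column {col!r}: cannot parse {cell!r} as a number"
        ) from None


def read_channel_table(path: PathLike) -> list[ReactionChannel]:
    """Parse a channel table; raises :class:`ChannelTableError` with row and
    column diagnostics on malformed content."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ChannelTableError(f"cannot read channel table {path}: {exc}")
    if list(frame.columns) != CHANNEL_COLUMNS:
        raise ChannelTableError(
            f"bad header: expected {CHANNEL_COLUMNS}, got {list(frame.columns)}"
        )
    channels = []
    for i, rec in enumerate(frame.to_dict("records"), start=2):
        try:
            mechanism = Mechanism(rec["mechanism"])
        except ValueError:
            raise ChannelTableError(
                f"row {i}, column 'mechanism': unknown mechanism "
                f"{rec['mechanism']!r}"
            ) from None
        dG_rxn = _opt_float(rec["dG_rxn_kcal"], i, "dG_rxn_kcal")
        if dG_rxn is None:
            raise ChannelTableError(f"row {i}: dG_rxn_kcal is required")
        sigma_cell = rec["sigma"]
        try:
            sigma = int(sigma_cell) if sigma_cell != "" else None
        except ValueError:
            raise ChannelTableError(
                f"row {i}, column 'sigma': cannot parse {sigma_cell!r}"
            ) from None
        ring_cell = rec["ring_opening"].strip().lower()
        if ring_cell not in ("", "true", "false"):
            raise ChannelTableError(
                f"row {i}, column 'ring_opening': expected true/false, "
                f"got {rec['ring_opening']!r}"
            )
        channels.append(
            ReactionChannel(
                antioxidant=rec["antioxidant"],
                radical=rec["radical"],
                mechanism=mechanism,
                site=rec["site"] if rec["site"] != "" else "none",
                medium=rec["medium"],
                dG_act=_opt_float(rec["dG_act_kcal"], i, "dG_act_kcal"),
                dG_rxn=dG_rxn,
                lambda_reorg=_opt_float(rec["lambda_kcal"], i, "lambda_kcal"),
                imag_freq=_opt_float(rec["imag_freq_cm"], i, "imag_freq_cm"),
                sigma=sigma,
                molecularity=(
                    int(rec["molecularity"]) if rec["molecularity"] != "" else 2
                ),
                ring_opening=ring_cell == "true",
            )
        )
    return channels


def _fmt_opt(value) -> str:
    if value is None:
        return ""
    return repr(value)


def write_channel_table(
    channels: Iterable[ReactionChannel], path: PathLike
) -> None:
    """Write channels in the standard table format (full float precision, so
    a read -> write -> read round trip is field-for-field identical)."""
    rows = []
    for c in channels:
        rows.append(
            {
                "antioxidant": c.antioxidant,
                "radical": c.radical,
                "mechanism": c.mechanism.value,
                "site": c.site,
                "medium": c.medium,
                "dG_act_kcal": _fmt_opt(c.dG_act),
                "dG_rxn_kcal": repr(c.dG_rxn),
                "lambda_kcal": _fmt_opt(c.lambda_reorg),
                "imag_freq_cm": _fmt_opt(c.imag_freq),
                "sigma": c.sigma,
                "molecularity": c.molecularity,
                "ring_opening": "true" if c.ring_opening else "false",
            }
        )
    pd.DataFrame(rows, columns=CHANNEL_COLUMNS).to_csv(path, index=False)


def read_run_inputs(
    path: PathLike,
) -> tuple[dict[str, SpeciesSpec], dict[str, MediumSpec]]:
    """Load species and media registries from a YAML config document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    species = {}
    for name, spec in (doc.get("species") or {}).items():
        radius_A = spec.get("stokes_radius_angstrom")
        species[name] = SpeciesSpec(
            name=name,
            role=Role(spec["role"]),
            stokes_radius=None if radius_A is None else radius_A * 1e-10,
            chalcogen=Chalcogen(spec.get("chalcogen", "none")),
        )
    media = {}
    for name, spec in (doc.get("media") or {}).items():
        media[name] = MediumSpec(
            name=name,
            temperature=spec.get("temperature", 298.15),
            viscosity=spec["viscosity_pa_s"],
            polarity_class=Polarity(spec["polarity_class"]),
            molar_volume=spec.get("molar_volume_L"),
        )
    return species, media


def load_channel_set(
    table_path: PathLike, config_path: PathLike
) -> ChannelSet:
    species, media = read_run_inputs(config_path)
    return ChannelSet(
        channels=read_channel_table(table_path), species=species, media=media
    )


def sig_round(x: float, sig_figs: int = 3) -> float:
    """Round to a number of significant figures (reference-table style)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig_figs - 1 - int(math.floor(math.log10(abs(x)))))


def _sig_str(x: float, sig_figs: int) -> str:
    return f"{x:.{sig_figs - 1}e}"


def write_report_delimited(
    reports: Sequence[ScavengingReport],
    dest: Union[PathLike, TextIO],
    sig_figs: int = 3,
) -> None:
    """Mechanism x context table mirroring the reference-table layout:
    rate (3 significant figures), integer branching ratio, diffusion flag."""
    rows = []
    for rep in reports:
        for summary in rep.mechanisms:
            rows.append(
                {
                    "medium": rep.medium,
                    "antioxidant": rep.antioxidant,
                    "radical": rep.radical,
                    "mechanism": summary.mechanism.value,
                    "k_app": _sig_str(summary.k_app_sum, sig_figs),
                    "gamma_percent": (
                        "" if summary.gamma is None else round_percent(summary.gamma)
                    ),
                    "diffusion_controlled": (
                        "true" if summary.diffusion_limited_any else "false"
                    ),
                }
            )
        rows.append(
            {
                "medium": rep.medium,
                "antioxidant": rep.antioxidant,
                "radical": rep.radical,
                "mechanism": "overall",
                "k_app": _sig_str(rep.k_overall, sig_figs),
                "gamma_percent": "",
                "diffusion_controlled": (
                    "true"
                    if any(m.diffusion_limited_any for m in rep.mechanisms)
                    else "false"
                ),
            }
        )
    frame = pd.DataFrame(rows)
    if hasattr(dest, "write"):
        frame.to_csv(dest, index=False)
    else:
        frame.to_csv(dest, index=False)


def write_report_json(
    reports: Sequence[ScavengingReport], dest: Union[PathLike, TextIO]
) -> None:
    """Machine-readable report at full double precision."""
    payload = [rep.model_dump(mode="json") for rep in reports]
    text = json.dumps(payload, indent=2, sort_keys=True)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
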