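"""Cross-species translation of an estimated drug effect.

The single-channel block parameter eps = 1/IC50 describes the drug's action
on one channel protein, and the same protein carries the current in every
species, so eps estimated in a source species applies verbatim to a target
species.  The target is simulated with its own shipped conductances - the
source's adjustment factors lambda describe that individual animal's cell,
not the channel protein, and are deliberately *not* transferred - and the
drug enters only through the block factors 1/(1 + eps*D).  Predicted
biomarker changes are reported against the target's own control simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .apmodel import SolverConfig, SpeciesParams
from .biomarkers import BiomarkerSet, percent_change
from .engine import BiomarkerSimulator
from .inversion import InversionResult
from .pharmacology import scale_factor

__all__ = ["TranslationReport", "translate_drug", "summarize_table"]

log = logging.getLogger(__name__)


@dataclass
class TranslationReport:
    """Predicted target-species biomarkers per dose, control included."""

    source_species: str
    target_species: str
    dose_unit: str
    epsilon: dict[str, float]  # verbatim from the source inversion
    doses: tuple[float, ...]
    control: BiomarkerSet
    predicted: dict[float, BiomarkerSet]  # dose -> biomarkers
    percent_changes: dict[float, dict[str, float]]  # dose -> biomarker -> %
    provenance: dict = field(default_factory=dict)


def translate_drug(
    source_result: InversionResult,
    target: SpeciesParams,
    doses: Sequence[float],
    simulator: BiomarkerSimulator | None = None,
) -> TranslationReport:
    """Predict the drug's effect on the target species from a source fit.

    The epsilon map is taken bitwise from ``source_result``; the target's
    shipped parameterization is paced at each dose with block factors
    ``1/(1 + eps*D)`` and percent changes are computed against the dose-0
    simulation of the same model.
    """
    eps = dict(source_result.epsilon_hat)
    for ch in eps:
        if target.magnitude(ch) == 0:
            log.warning(
                "channel %s has zero conductance in target species %s: "
                "the translated block has no observable effect there",
                ch,
                target.species_name,
            )
    sim = simulator or BiomarkerSimulator(target)
    control = sim.biomarkers()

    predicted: dict[float, BiomarkerSet] = {}
    changes: dict[float, dict[str, float]] = {}
    names = [f"apd{p}" for p in sorted(control.apd)] + ["v_max", "v_min"]
    if control.dvdt_max is not None:
        names.append("dvdt_max")
    for dose in doses:
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        blocks = {ch: scale_factor(e, float(dose)) for ch, e in eps.items()}
        bm = sim.biomarkers(blocks=blocks)
        predicted[float(dose)] = bm
        changes[float(dose)] = {
            name: percent_change(control.value(name), bm.value(name))
            for name in names
        }

    return TranslationReport(
        source_species=source_result.species_name,
        target_species=target.species_name,
        dose_unit=source_result.dose_unit,
        epsilon=eps,
        doses=tuple(float(d) for d in doses),
        control=control,
        predicted=predicted,
        percent_changes=changes,
        provenance={
            "source_seed": source_result.rng_seed,
            "source_final_cost": source_result.final_cost,
            "source_config": source_result.config,
        },
    )


def summarize_table(
    report: TranslationReport,
    biomarkers: Sequence[str] = ("apd50", "apd90"),
) -> pd.DataFrame:
    """Tabular view: one row per biomarker, control value plus percent
    change per dose (formatted to one decimal, with sign)."""
    unit = {"apd": "ms", "v_m": "mV", "dvd": "mV/ms"}
    rows = []
    index = []
    for name in biomarkers:
        row = {"control": f"{report.control.value(name):.1f}"}
        for dose in report.doses:
            col = f"{dose:g} {report.dose_unit}"
            row[col] = f"{report.percent_changes[dose][name]:+.1f}%"
        rows.append(row)
        index.append(f"{name} ({unit.get(name[:3], '')})")
    return pd.DataFrame(rows, index=index)
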