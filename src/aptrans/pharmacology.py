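"""Dose-dependent conductance block.

A blocker at dose D multiplies the targeted channel's maximal conductance by
``1 / (1 + eps * D)`` with ``eps = 1 / IC50`` and Hill coefficient fixed at
one.  At D = IC50 the factor is exactly 1/2; untargeted channels are
untouched.  Because the factor depends only on ``eps`` and the dose, the same
drug specification produces identical factor maps for every species - this
species-independence of single-channel block is what makes cross-species
translation possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .apmodel import CHANNELS, SpeciesParams, _check_channel

__all__ = [
    "ChannelBlock",
    "DrugSpec",
    "epsilon_from_ic50",
    "ic50_from_epsilon",
    "scale_factor",
    "apply_blocks",
]

log = logging.getLogger(__name__)


def epsilon_from_ic50(ic50: float) -> float:
    """eps = 1 / IC50 (per dose unit)."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be > 0, got {ic50}")
    return 1.0 / ic50


def ic50_from_epsilon(epsilon: float) -> float:
    """Exact inverse of :func:`epsilon_from_ic50`."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    return 1.0 / epsilon


def scale_factor(epsilon: float, dose: float) -> float:
    """Remaining conductance fraction 1 / (1 + eps * D), in (0, 1]."""
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return 1.0 / (1.0 + epsilon * dose)


@dataclass(frozen=True)
class ChannelBlock:
    """Block of one channel: eps in 1/(dose unit); Hill coefficient fixed."""

    channel_id: str
    epsilon: float
    hill: int = 1

    def __post_init__(self):
        _check_channel(self.channel_id)
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.hill != 1:
            raise ValueError("Hill coefficient is fixed at 1 in this model")

    @property
    def ic50(self) -> float:
        return ic50_from_epsilon(self.epsilon)


@dataclass(frozen=True)
class DrugSpec:
    """A named drug: which channels it blocks, and in what dose unit."""

    drug_name: str
    blocks: tuple[ChannelBlock, ...]
    dose_unit: str = "uM"

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))
        ids = [b.channel_id for b in self.blocks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate channel ids in drug spec: {ids}")

    @property
    def epsilons(self) -> dict[str, float]:
        return {b.channel_id: b.epsilon for b in self.blocks}

    @classmethod
    def from_epsilons(
        cls, drug_name: str, epsilons: Mapping[str, float], dose_unit: str = "uM"
    ) -> "DrugSpec":
        return cls(
            drug_name=drug_name,
            blocks=tuple(ChannelBlock(ch, e) for ch, e in epsilons.items()),
            dose_unit=dose_unit,
        )


def apply_blocks(
    params: SpeciesParams, drug: DrugSpec, dose: float
) -> dict[str, float]:
    """Block-factor map over all channels at one dose.

    Untargeted channels map to exactly 1.0; targeted channels to
    ``scale_factor(eps, dose)``.  The species parameters are never mutated -
    they are only consulted to warn when a targeted channel has zero
    conductance in this species (the drug effect is then unobservable there).
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    factors = {ch: 1.0 for ch in CHANNELS}
    for b in drug.blocks:
        if params.magnitude(b.channel_id) == 0:
            log.warning(
                "drug %s targets %s, which has zero conductance in species %s: "
                "the block has no observable effect there",
                drug.drug_name,
                b.channel_id,
                params.species_name,
            )
        factors[b.channel_id] = scale_factor(b.epsilon, dose)
    return factors
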