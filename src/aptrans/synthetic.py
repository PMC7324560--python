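"""Ground-truthed synthetic dose-response datasets.

The generated-data study design: take a source species, multiply a few of
its conductances by known "individual" adjustment factors (the hidden
lambda*), apply a drug with known per-channel epsilon* at each dose, pace to
the steady-state beat, and record the biomarkers.  The ground truth
(lambda*, epsilon*, noiseless biomarkers) is returned alongside, so the
inversion and translation stages can be validated end to end without any
experimental data.  Observation noise (multiplicative Gaussian per
biomarker) is optional and off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .apmodel import SpeciesParams
from .biomarkers import BiomarkerSet
from .engine import BiomarkerSimulator
from .inversion import DoseRecord, DoseResponseDataset
from .pharmacology import DrugSpec, apply_blocks

__all__ = ["SyntheticDesign", "GroundTruth", "generate_dataset", "drug_for_block"]


def drug_for_block(
    drug_name: str,
    channel_fractions: Mapping[str, float],
    dose: float,
    dose_unit: str = "uM",
) -> DrugSpec:
    """Drug giving a stated fractional block at a stated dose.

    A block fraction b at dose D corresponds to eps = (1/(1-b) - 1)/D, i.e.
    50% block at D gives eps = 1/D (IC50 = D).
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    eps = {}
    for ch, b in channel_fractions.items():
        if not 0 <= b < 1:
            raise ValueError(f"block fraction must be in [0, 1), got {b} for {ch}")
        eps[ch] = (1.0 / (1.0 - b) - 1.0) / dose
    return DrugSpec.from_epsilons(drug_name, eps, dose_unit=dose_unit)


@dataclass(frozen=True)
class SyntheticDesign:
    """Specification of one generated-data experiment."""

    base_species: SpeciesParams
    true_drug: DrugSpec
    doses: tuple[float, ...]
    perturbation: Mapping[str, float] = field(default_factory=dict)  # lambda*
    noise_sd: Mapping[str, float] = field(default_factory=dict)  # relative s.d.
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        if 0.0 not in self.doses:
            raise ValueError("doses must include 0 (the control case)")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("doses must be distinct")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if any(f <= 0 for f in self.perturbation.values()):
            raise ValueError("perturbation factors must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually used: hidden truth for recovery tests."""

    lambdas: dict[str, float]
    epsilons: dict[str, float]
    noiseless: dict[float, BiomarkerSet]  # dose -> exact biomarkers
    rng_seed: int


def _apply_noise(
    bm: BiomarkerSet, noise_sd: Mapping[str, float], rng: np.random.Generator
) -> BiomarkerSet:
    def factor(key: str) -> float:
        sd = noise_sd.get(key, 0.0)
        if sd == 0.0:
            return 1.0
        # truncate at +-4 s.d. and keep the factor positive so APDs stay
        # positive and v_max/v_min keep their signs
        z = float(np.clip(rng.standard_normal(), -4.0, 4.0))
        return max(1.0 + sd * z, 0.05)

    apd = {p: bm.apd[p] * factor(f"apd{p}") for p in bm.apd}
    v_max = bm.v_max * factor("v_max")
    v_min = bm.v_min * factor("v_min")
    if v_max <= v_min:  # degenerate draw; keep the noiseless extremes
        v_max, v_min = bm.v_max, bm.v_min
    dvdt = None if bm.dvdt_max is None else bm.dvdt_max * factor("dvdt_max")
    return BiomarkerSet(apd=apd, v_max=v_max, v_min=v_min, dvdt_max=dvdt)


def generate_dataset(
    design: SyntheticDesign,
    simulator: BiomarkerSimulator | None = None,
) -> tuple[DoseResponseDataset, GroundTruth]:
    """Simulate the design and return (dataset, ground truth).

    The dataset biomarkers are noiseless unless ``design.noise_sd`` is set;
    the ground truth always stores the exact noiseless values.  Noise with
    all-zero standard deviations reproduces the noiseless dataset bitwise.
    """
    sim = simulator or BiomarkerSimulator(design.base_species)
    rng = np.random.default_rng(design.rng_seed)
    any_noise = any(sd != 0.0 for sd in design.noise_sd.values())

    records = []
    noiseless: dict[float, BiomarkerSet] = {}
    for dose in design.doses:
        blocks = apply_blocks(design.base_species, design.true_drug, dose)
        try:
            bm = sim.biomarkers(lambdas=design.perturbation, blocks=blocks)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(
                f"simulation failed at dose {dose} {design.true_drug.dose_unit}: {exc}"
            ) from exc
        noiseless[dose] = bm
        records.append(
            DoseRecord(
                dose=dose,
                biomarkers=_apply_noise(bm, design.noise_sd, rng) if any_noise else bm,
            )
        )

    dataset = DoseResponseDataset(
        species_name=design.base_species.species_name,
        dose_unit=design.true_drug.dose_unit,
        records=tuple(records),
    )
    truth = GroundTruth(
        lambdas=dict(design.perturbation),
        epsilons=dict(design.true_drug.epsilons),
        noiseless=noiseless,
        rng_seed=design.rng_seed,
    )
    return dataset, truth
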