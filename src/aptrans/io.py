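"""File formats and configuration loading.

Formats (all plain text, UTF-8, '.' decimal separator):

* voltage trace: CSV with header ``time_ms,v_mV`` plus a JSON sidecar
  (``<stem>.meta.json``) carrying species, protocol and solver metadata;
* dose-response dataset: JSON ``{"species": ..., "dose_unit": ...,
  "records": [{"dose": 0, "biomarkers": {...}}, ...]}``;
* inversion result and translation report: JSON with config echo and seed;
* drug, species and synthetic-design specifications: YAML.

Validation happens at load time with errors naming the offending field, so
nothing fails halfway through an optimization.  Doses are never converted
between units implicitly; :func:`convert_dose` is the explicit converter.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .apmodel import (
    PacedTrace,
    SpeciesParams,
    species_defaults,
    species_from_dict,
    species_to_dict,
    shipped_species,
)
from .biomarkers import BiomarkerSet
from .inversion import (
    DoseRecord,
    DoseResponseDataset,
    InversionConfig,
    InversionResult,
)
from .pharmacology import ChannelBlock, DrugSpec, epsilon_from_ic50
from .synthetic import GroundTruth, SyntheticDesign
from .translation import TranslationReport

__all__ = [
    "convert_dose",
    "read_trace",
    "write_trace",
    "read_dataset",
    "write_dataset",
    "read_result",
    "write_result",
    "write_report",
    "read_drug_spec",
    "read_species",
    "read_design",
    "read_inversion_config",
    "write_ground_truth",
]

_MOLAR_FACTORS = {"pM": 1e-12, "nM": 1e-9, "uM": 1e-6, "mM": 1e-3, "M": 1.0}


class SchemaError(ValueError):
    """A file did not match its expected schema."""


def convert_dose(value: float, from_unit: str, to_unit: str) -> float:
    """Explicit molar-unit conversion (pM/nM/uM/mM/M)."""
    try:
        return value * _MOLAR_FACTORS[from_unit] / _MOLAR_FACTORS[to_unit]
    except KeyError as exc:
        raise SchemaError(
            f"unknown dose unit {exc.args[0]!r}; known: {sorted(_MOLAR_FACTORS)}"
        ) from None


# --------------------------------------------------------------------- trace


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_trace(trace: PacedTrace, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "v_mV"])
        for t, v in zip(trace.time, trace.voltage):
            w.writerow([repr(float(t)), repr(float(v))])
    _sidecar(path).write_text(
        json.dumps(trace.metadata, indent=1, default=float), encoding="utf-8"
    )


def read_trace(path: str | Path) -> PacedTrace:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SchemaError(f"{path}: empty file (expected header time_ms,v_mV)")
    if rows[0] != ["time_ms", "v_mV"]:
        raise SchemaError(
            f"{path}: line 1: expected header 'time_ms,v_mV', got {rows[0]!r}"
        )
    time, volt = [], []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise SchemaError(f"{path}: line {i}: expected 2 columns, got {len(row)}")
        try:
            time.append(float(row[0]))
            volt.append(float(row[1]))
        except ValueError:
            raise SchemaError(f"{path}: line {i}: non-numeric value {row!r}") from None
    meta_path = _sidecar(path)
    metadata = (
        json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
    )
    return PacedTrace(np.array(time), np.array(volt), metadata)


# ------------------------------------------------------------------- dataset


def write_dataset(dataset: DoseResponseDataset, path: str | Path) -> None:
    doc = {
        "species": dataset.species_name,
        "dose_unit": dataset.dose_unit,
        "records": [
            {"dose": float(r.dose), "biomarkers": r.biomarkers.as_dict()}
            for r in dataset.records
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_dataset(path: str | Path) -> DoseResponseDataset:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from None
    for key in ("species", "dose_unit", "records"):
        if key not in doc:
            raise SchemaError(f"{path}: missing key {key!r}")
    try:
        records = tuple(
            DoseRecord(
                dose=float(r["dose"]),
                biomarkers=BiomarkerSet.from_dict(r["biomarkers"]),
            )
            for r in doc["records"]
        )
        return DoseResponseDataset(
            species_name=doc["species"],
            dose_unit=doc["dose_unit"],
            records=records,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from None


# -------------------------------------------------------------------- result


def write_result(result: InversionResult, path: str | Path) -> None:
    doc = {
        "species": result.species_name,
        "dose_unit": result.dose_unit,
        "lambda_hat": result.lambda_hat,
        "epsilon_hat": result.epsilon_hat,
        "ic50_hat": {
            ch: (None if np.isinf(v) else v) for ch, v in result.ic50_hat.items()
        },
        "final_cost": result.final_cost,
        "cost_trace": result.cost_trace,
        "residuals": {repr(d): terms for d, terms in result.residuals.items()},
        "config": result.config,
        "rng_seed": result.rng_seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_result(path: str | Path) -> InversionResult:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from None
    try:
        return InversionResult(
            species_name=doc["species"],
            dose_unit=doc["dose_unit"],
            lambda_hat={k: float(v) for k, v in doc["lambda_hat"].items()},
            epsilon_hat={k: float(v) for k, v in doc["epsilon_hat"].items()},
            final_cost=float(doc["final_cost"]),
            cost_trace=[float(c) for c in doc["cost_trace"]],
            residuals={
                float(d): {k: float(v) for k, v in terms.items()}
                for d, terms in doc["residuals"].items()
            },
            config=doc["config"],
            rng_seed=int(doc["rng_seed"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from None


# -------------------------------------------------------------------- report


def write_report(report: TranslationReport, path: str | Path) -> None:
    doc = {
        "source_species": report.source_species,
        "target_species": report.target_species,
        "dose_unit": report.dose_unit,
        "epsilon": report.epsilon,
        "doses": list(report.doses),
        "control": report.control.as_dict(),
        "predicted": {repr(d): bm.as_dict() for d, bm in report.predicted.items()},
        "percent_changes": {
            repr(d): ch for d, ch in report.percent_changes.items()
        },
        "provenance": report.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_report(path: str | Path) -> TranslationReport:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return TranslationReport(
        source_species=doc["source_species"],
        target_species=doc["target_species"],
        dose_unit=doc["dose_unit"],
        epsilon={k: float(v) for k, v in doc["epsilon"].items()},
        doses=tuple(float(d) for d in doc["doses"]),
        control=BiomarkerSet.from_dict(doc["control"]),
        predicted={
            float(d): BiomarkerSet.from_dict(bm) for d, bm in doc["predicted"].items()
        },
        percent_changes={
            float(d): {k: float(v) for k, v in ch.items()}
            for d, ch in doc["percent_changes"].items()
        },
        provenance=doc.get("provenance", {}),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "lambdas": truth.lambdas,
        "epsilons": truth.epsilons,
        "noiseless": {repr(d): bm.as_dict() for d, bm in truth.noiseless.items()},
        "rng_seed": truth.rng_seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------- YAML


def _load_yaml(path: str | Path) -> dict:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML ({exc})") from None
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a YAML mapping, got {type(doc).__name__}")
    return doc


def read_drug_spec(path: str | Path) -> DrugSpec:
    """Drug YAML: drug_name, dose_unit, blocks (channel + ic50 xor epsilon)."""
    doc = _load_yaml(path)
    for key in ("drug_name", "blocks"):
        if key not in doc:
            raise SchemaError(f"{path}: missing key {key!r}")
    blocks = []
    for i, b in enumerate(doc["blocks"]):
        if "channel" not in b:
            raise SchemaError(f"{path}: blocks[{i}]: missing 'channel'")
        has_ic50, has_eps = "ic50" in b, "epsilon" in b
        if has_ic50 == has_eps:
            raise SchemaError(
                f"{path}: blocks[{i}]: exactly one of 'ic50'/'epsilon' required"
            )
        eps = epsilon_from_ic50(float(b["ic50"])) if has_ic50 else float(b["epsilon"])
        try:
            blocks.append(ChannelBlock(channel_id=b["channel"], epsilon=eps))
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: blocks[{i}]: {exc}") from None
    return DrugSpec(
        drug_name=str(doc["drug_name"]),
        blocks=tuple(blocks),
        dose_unit=str(doc.get("dose_unit", "uM")),
    )


def read_species(name_or_path: str) -> SpeciesParams:
    """A shipped species name, or a path to a species YAML file."""
    if name_or_path in shipped_species():
        return species_defaults(name_or_path)
    path = Path(name_or_path)
    if not path.exists():
        raise SchemaError(
            f"unknown species {name_or_path!r} (shipped: "
            f"{', '.join(shipped_species())}) and no such file"
        )
    try:
        return species_from_dict(_load_yaml(path))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_species(params: SpeciesParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(species_to_dict(params)), encoding="utf-8")


def read_design(path: str | Path) -> SyntheticDesign:
    """Synthetic-design YAML: base_species, drug (inline or path), doses,
    optional perturbation, noise_sd, rng_seed."""
    doc = _load_yaml(path)
    for key in ("base_species", "drug", "doses"):
        if key not in doc:
            raise SchemaError(f"{path}: missing key {key!r}")
    base = read_species(str(doc["base_species"]))
    drug_doc = doc["drug"]
    if isinstance(drug_doc, str):
        drug = read_drug_spec(Path(path).parent / drug_doc)
    else:
        blocks = tuple(
            ChannelBlock(
                channel_id=b["channel"],
                epsilon=(
                    epsilon_from_ic50(float(b["ic50"]))
                    if "ic50" in b
                    else float(b["epsilon"])
                ),
            )
            for b in drug_doc["blocks"]
        )
        drug = DrugSpec(
            drug_name=str(drug_doc.get("drug_name", "synthetic-drug")),
            blocks=blocks,
            dose_unit=str(drug_doc.get("dose_unit", "uM")),
        )
    try:
        return SyntheticDesign(
            base_species=base,
            true_drug=drug,
            doses=tuple(float(d) for d in doc["doses"]),
            perturbation={
                str(k): float(v) for k, v in (doc.get("perturbation") or {}).items()
            },
            noise_sd={
                str(k): float(v) for k, v in (doc.get("noise_sd") or {}).items()
            },
            rng_seed=int(doc.get("rng_seed", 0)),
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def read_inversion_config(path: str | Path) -> InversionConfig:
    doc = _load_yaml(path)
    if "free_epsilons" not in doc:
        raise SchemaError(f"{path}: missing key 'free_epsilons'")
    kwargs = {}
    for key in (
        "continuation_iterations",
        "guesses_per_iteration",
        "nm_iterations",
        "rng_seed",
        "eval_beats",
        "warm_beats",
    ):
        if key in doc:
            kwargs[key] = int(doc[key])
    for key in ("lambda_jitter", "epsilon_range_factor"):
        if key in doc:
            kwargs[key] = float(doc[key])
    if "include_dvdt_term" in doc:
        kwargs["include_dvdt_term"] = bool(doc["include_dvdt_term"])
    if doc.get("free_lambdas") is not None:
        kwargs["free_lambdas"] = tuple(doc["free_lambdas"])
    if doc.get("weights") is not None:
        kwargs["weights"] = {str(k): float(v) for k, v in doc["weights"].items()}
    try:
        return InversionConfig(
            free_epsilons=tuple(doc["free_epsilons"]), **kwargs
        )
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from None
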